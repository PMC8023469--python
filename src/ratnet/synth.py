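"""Synthetic association networks and RAT problems.

The generator emulates the statistical signature of large free-association
norms so every pipeline stage runs without external data: Poisson-like
out-degree (set by the number of responses collected per cue), a
power-law in-degree tail with exponent ``gamma ~ 3`` (heavy-tailed word
"attractiveness"), and edge weights that are response fractions on a
``1/m`` grid with per-cue out-weight sums of at most one.

RAT problems are *planted* into a generated network.  Easy plants insert
one strong direct stimulus->response link per stimulus; hard plants
forbid direct links and wire each stimulus to the response through a
two-step path of moderately weak links; medium plants mix one weak direct
link with two-step paths.  Reference hardness is then defined as the
attraction-search model accuracy under a reference configuration with an
independent seed stream, which gives recovery experiments a ground truth
of exactly the kind the analysis assumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._rng import spawn_seed
from .network import AssociationNetwork
from .problems import RATProblem, categorize_hardness
from .search import SearchConfig, estimate_accuracy

__all__ = [
    "NetworkGenSpec",
    "PlantSpec",
    "generate_network",
    "plant_rat",
    "reference_hardness",
    "generate_study",
    "make_reference_problem_bank",
]

#: mean latent candidate-pool size per cue (Poisson-distributed, capped at n - 1)
_POOL_MEAN = 40


@dataclass(frozen=True)
class NetworkGenSpec:
    """Generator parameters.

    ``responses_per_cue`` (m) sets the weight granularity ``1/m``;
    ``attractiveness_exponent`` is the Pareto tail index of node
    attractiveness (index ``a`` gives an in-degree density exponent
    ``gamma = a + 1``, so the default 2.0 targets ``gamma ~ 3``);
    ``concentration`` is the symmetric Dirichlet parameter of the per-cue
    latent preference over its candidate pool and controls the mean
    out-degree (smaller -> sparser).
    """

    n_nodes: int
    responses_per_cue: int = 100
    attractiveness_exponent: float = 2.0
    concentration: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.responses_per_cue < 10:
            raise ValueError("responses_per_cue must be >= 10")
        if self.attractiveness_exponent <= 1.0:
            raise ValueError("attractiveness_exponent must be > 1")
        if self.concentration <= 0.0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class PlantSpec:
    """How to wire a problem of a given category into the network."""

    category: str
    direct_weight_range: tuple[float, float] = (0.2, 0.5)
    path_weight_range: tuple[float, float] = (0.02, 0.06)

    def __post_init__(self):
        if self.category not in ("easy", "medium", "hard"):
            raise ValueError(f"unknown category {self.category!r}")
        for lo, hi in (self.direct_weight_range, self.path_weight_range):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("weight ranges must satisfy 0 < lo <= hi <= 1")


def _word_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"w{i:0{width}d}" for i in range(n)]


def generate_network(
    spec: NetworkGenSpec, rng: np.random.Generator | None = None
) -> AssociationNetwork:
    """Draw a synthetic free-association network.

    Per cue: a latent candidate pool is sampled with probability
    proportional to heavy-tailed node attractiveness, weighted by a
    symmetric Dirichlet, and ``m`` i.i.d. responses are drawn from it;
    the edge weight is the response count divided by ``m`` (zero counts
    and self-responses dropped), so out-weight sums are at most one by
    construction and every weight is a multiple of ``1/m``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    m = spec.responses_per_cue
    # classical Pareto with x_m = 1: density exponent = tail index + 1
    attractiveness = 1.0 + rng.pareto(spec.attractiveness_exponent, size=n)
    cdf = np.cumsum(attractiveness)
    cdf /= cdf[-1]
    pools = np.minimum(np.maximum(rng.poisson(_POOL_MEAN, size=n), 2), n - 1)
    # candidate pools for all cues at once: inverse-CDF sampling
    draws = np.searchsorted(cdf, rng.random((n, int(pools.max()))), side="right")
    rows: list[dict[int, float]] = []
    for i in range(n):
        candidates = np.unique(draws[i][: pools[i]])
        candidates = candidates[candidates != i]
        if candidates.size == 0:
            rows.append({})
            continue
        pref = rng.gamma(spec.concentration, size=candidates.size)
        total = pref.sum()
        if total <= 0.0:  # all-zero gamma draws at tiny concentration
            pref = np.ones(candidates.size)
            total = float(candidates.size)
        counts = rng.multinomial(m, pref / total)
        nz = counts > 0
        rows.append(
            {int(j): c / m for j, c in zip(candidates[nz], counts[nz])}
        )
    return AssociationNetwork.from_row_dicts(_word_labels(n), rows)


def _insert_edge(
    rows: list[dict[int, float]], source: int, target: int, weight: float
) -> None:
    """Insert an edge, rescaling the source's existing out-weights.

    Existing weights are multiplied by ``1 - weight`` so the row sum stays
    at most one without deleting structure.
    """
    row = rows[source]
    row.pop(target, None)
    for j in list(row):
        row[j] *= 1.0 - weight
    row[target] = weight


def plant_rat(
    net: AssociationNetwork,
    plant: PlantSpec,
    rng: np.random.Generator,
    *,
    problem_id: str | None = None,
    words: Sequence[int] | None = None,
) -> tuple[AssociationNetwork, RATProblem]:
    """Wire one RAT problem into the network; returns (new network, problem).

    Easy: strong direct ``s -> r`` links.  Hard: any direct links removed
    and each stimulus routed through its own two-step
    ``s -> k -> r`` path of moderately weak links.  Medium: one weak
    direct link (between the two regimes) plus the two-step paths.
    ``words`` optionally pins the node indices used (response, stimuli,
    intermediates) so studies can plant on disjoint word sets.
    """
    need = 4 if plant.category == "easy" else 7
    if net.n_nodes < need + 2:
        raise ValueError(f"need at least {need + 2} nodes to plant {plant.category}")
    if words is None:
        words = rng.choice(net.n_nodes, size=need, replace=False)
    words = [int(w) for w in words]
    if len(words) != need or len(set(words)) != need:
        raise ValueError(f"{plant.category} plant needs {need} distinct words")
    r, s1, s2, s3 = words[:4]
    stimuli = (s1, s2, s3)
    rows = net.to_row_dicts()
    d_lo, d_hi = plant.direct_weight_range
    p_lo, p_hi = plant.path_weight_range
    if plant.category == "easy":
        for s in stimuli:
            _insert_edge(rows, s, r, float(rng.uniform(d_lo, d_hi)))
    else:
        mids = words[4:]
        for s in stimuli:
            rows[s].pop(r, None)  # no direct association allowed
        for s, k in zip(stimuli, mids):
            _insert_edge(rows, s, k, float(rng.uniform(p_lo, p_hi)))
            _insert_edge(rows, k, r, float(rng.uniform(p_lo, p_hi)))
        if plant.category == "medium":
            # one direct weak link, between the hard and easy weight regimes
            lo, hi = min(p_hi, d_lo), max(p_hi, d_lo)
            _insert_edge(rows, s1, r, float(rng.uniform(lo, hi)))
    new_net = AssociationNetwork.from_row_dicts(net.words, rows)
    problem = RATProblem(
        id=problem_id or f"{plant.category}-{r}",
        stimuli=tuple(net.words[s] for s in stimuli),
        response=net.words[r],
    )
    return new_net, problem


#: reference configuration defining synthetic ground-truth hardness
REFERENCE_CONFIG = SearchConfig(t_max=20, n_runs=10_000, tau=0.0, w_max=1.0)


def reference_hardness(
    net: AssociationNetwork,
    problem: RATProblem,
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    noise_sd: float = 0.0,
) -> float:
    """Ground-truth hardness: reference-model accuracy plus optional noise.

    Identifies hardness with the attraction-search model accuracy under
    the reference configuration (an independent seed stream should be
    supplied via ``config.seed`` by the caller); observation noise, when
    requested, is Gaussian and clipped to [0, 1].
    """
    cfg = config or REFERENCE_CONFIG
    h = estimate_accuracy(net, problem, cfg).accuracy
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng(spawn_seed(cfg.seed, "hardness-noise"))
        h = float(np.clip(h + rng.normal(0.0, noise_sd), 0.0, 1.0))
    return h


def generate_study(
    spec: NetworkGenSpec,
    n_easy: int,
    n_medium: int,
    n_hard: int,
    rng: np.random.Generator | None = None,
    *,
    plant_specs: dict[str, PlantSpec] | None = None,
    reference_config: SearchConfig | None = None,
    noise_sd: float = 0.0,
) -> tuple[AssociationNetwork, list[RATProblem]]:
    """One synthetic network plus planted problems with reference hardness.

    Problems are planted on disjoint word sets so later plants do not
    disturb earlier ones; hardness is attached after all planting, from
    the reference simulator with a seed stream independent of generation.
    """
    if min(n_easy, n_medium, n_hard) < 0:
        raise ValueError("problem counts must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    net = generate_network(spec, rng)
    counts = {"easy": n_easy, "medium": n_medium, "hard": n_hard}
    plants = plant_specs or {}
    need = sum(c * (4 if cat == "easy" else 7) for cat, c in counts.items())
    if need > net.n_nodes:
        raise ValueError(
            f"{need} distinct plant words needed but network has {net.n_nodes} nodes"
        )
    reserved = iter(rng.choice(net.n_nodes, size=need, replace=False).tolist())
    problems: list[RATProblem] = []
    for cat, count in counts.items():
        plant = plants.get(cat, PlantSpec(category=cat))
        for j in range(count):
            k = 4 if cat == "easy" else 7
            words = list(itertools.islice(reserved, k))
            net, problem = plant_rat(
                net, plant, rng, problem_id=f"{cat}-{j}", words=words
            )
            problems.append(problem)
    ref_cfg = reference_config or replace(
        REFERENCE_CONFIG, seed=spawn_seed(spec.seed, "reference-hardness")
    )
    noise_rng = np.random.default_rng(spawn_seed(ref_cfg.seed, "hardness-noise"))
    problems = [
        replace(
            p,
            hardness=reference_hardness(
                net, p, ref_cfg, noise_rng, noise_sd=noise_sd
            ),
        )
        for p in problems
    ]
    return net, problems


def make_reference_problem_bank(seed: int = 138) -> list[RATProblem]:
    """Synthetic stand-in for the published 138-problem hardness table.

    The real normative table (138 three-stimulus problems with the
    fraction of subjects solving each within 15 seconds) ships as a PDF
    supplement and is not redistributable here; this synthetic bank
    reproduces its published marginal structure — 138 problems of which
    15 are easy, 38 medium and 85 hard — with opaque word labels and
    hardness values drawn uniformly inside each category band.
    """
    rng = np.random.default_rng(seed)
    counts = {"easy": 15, "medium": 38, "hard": 85}
    bands = {"easy": (0.645, 0.995), "medium": (0.325, 0.635), "hard": (0.005, 0.315)}
    problems = []
    idx = 0
    words = iter(_word_labels(4 * sum(counts.values())))
    for cat, count in counts.items():
        lo, hi = bands[cat]
        for _ in range(count):
            idx += 1
            h = float(rng.uniform(lo, hi))
            assert categorize_hardness(h) == cat
            s1, s2, s3, r = (next(words) for _ in range(4))
            problems.append(
                RATProblem(id=str(idx), stimuli=(s1, s2, s3), response=r, hardness=h)
            )
    return problems
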