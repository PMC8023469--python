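"""Spreading-activation search with attraction to the stimuli.

The three stimulus words stay permanently active.  At every attempt one
candidate word is activated with probability proportional to the summed
link weight it receives from the active set (the three stimuli plus the
current floating guess).  A wrong guess is deactivated on the next
activation and marked as checked, never to be activated again, so after
``t`` attempts exactly ``t`` candidate responses have been checked.  The
search succeeds when the response word is activated and fails when the
attempt budget ``t_max`` is exhausted or no candidate is activatable.

Two weak-link manipulations are studied on top of this process: a dynamic
activation threshold ``tau`` (a candidate needs summed input of at least
``tau`` to be activatable) and a static strong-link cutoff ``w_max``
(edges heavier than ``w_max`` are removed before searching).  By default
the threshold model renormalizes over the candidates that pass ``tau`` so
exactly one word activates per attempt; the as-printed variant that
leaves sub-threshold probability mass unassigned is available via
``SearchConfig(renormalize=False)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernel import simulate_batch
from ._rng import derive_run_seeds, problem_key
from .network import AssociationNetwork, apply_weight_window
from .problems import RATProblem, categorize_hardness

__all__ = [
    "SearchConfig",
    "TrajectoryRecord",
    "SimulationSummary",
    "candidate_distribution",
    "run_search",
    "estimate_accuracy",
    "simulate_success_attempts",
    "accuracy_vs_tmax",
    "threshold_sweep",
    "cutoff_experiment",
    "exact_success_probability",
]


@dataclass(frozen=True)
class SearchConfig:
    """Simulator parameters.

    ``t_max`` is the attempt budget per run, ``n_runs`` the number of
    Monte-Carlo replicates, ``tau`` the activation threshold on summed
    input weight, ``w_max`` the static strong-link cutoff applied before
    searching (1 disables it), ``seed`` the master seed of the per-run
    counter-based streams.
    """

    t_max: int = 20
    n_runs: int = 10_000
    tau: float = 0.0
    w_max: float = 1.0
    seed: int = 0
    renormalize: bool = True

    def __post_init__(self):
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0.0 < self.w_max <= 1.0):
            raise ValueError("w_max must lie in (0, 1]")


@dataclass(frozen=True)
class TrajectoryRecord:
    """One run's ordered activation sequence."""

    checked: tuple[str, ...]
    success: bool
    steps: int

    def __post_init__(self):
        if len(set(self.checked)) != len(self.checked):
            raise ValueError("checked words must be distinct")
        if self.steps != len(self.checked):
            raise ValueError("steps must equal the number of checked words")


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregate outcome of ``n_runs`` replicates of one problem."""

    accuracy: float
    accuracy_stderr: float
    mean_solving_length: float  # NaN when no run succeeded
    n_runs: int
    n_success: int
    config: SearchConfig


def _prepare(net: AssociationNetwork, config: SearchConfig) -> AssociationNetwork:
    if config.w_max < 1.0:
        return apply_weight_window(net, 0.0, config.w_max)
    return net


def candidate_distribution(
    net: AssociationNetwork,
    active: Iterable[str],
    checked: Iterable[str],
    tau: float,
    *,
    renormalize: bool = True,
) -> dict[str, float]:
    """Activation probabilities over the current candidate set.

    Candidates are the out-neighbours of the active words, minus active
    and checked words; the activation score of candidate ``x`` is the sum
    of link weights from active words into ``x``.  Candidates scoring
    below ``tau`` are removed.  With ``renormalize`` the surviving scores
    are scaled to sum to one; otherwise they are divided by the total
    score of *all* candidates, leaving the sub-threshold mass unassigned.
    An empty mapping is a valid return (dead end).
    """
    active = list(active)
    checked_set = set(checked)
    if not active:
        raise ValueError("active set must be nonempty")
    active_set = set(active)
    if active_set & checked_set:
        raise ValueError("active and checked sets must be disjoint")
    scores: dict[str, float] = {}
    for a in active:
        for target, w in net.successors(a):
            if target in active_set or target in checked_set:
                continue
            scores[target] = scores.get(target, 0.0) + w
    total_all = sum(scores.values())
    passing = {x: s for x, s in scores.items() if s >= tau}
    if not passing:
        return {}
    denom = sum(passing.values()) if renormalize else total_all
    return {x: s / denom for x, s in passing.items()}


def run_search(
    net: AssociationNetwork,
    problem: RATProblem,
    config: SearchConfig,
    rng=None,
    *,
    run_index: int = 0,
) -> TrajectoryRecord:
    """Simulate a single search trajectory (pure-Python reference path).

    Mirrors the compiled batch kernel operation-for-operation (same
    candidate scan order, same accumulation order, one uniform per
    attempt), so given the per-run seed it reproduces the kernel's
    trajectory exactly.  ``rng`` may be any object with ``.random()``
    drawing uniforms; by default the run's counter-based
    ``numpy.random.RandomState`` stream is used.
    """
    net = _prepare(net, config)
    if rng is None:
        seed = derive_run_seeds(
            config.seed, problem_key(problem.id), 1, start=run_index
        )[0]
        rng = np.random.RandomState(int(seed))
    m = net.matrix
    n = net.n_nodes
    stim = [net.index(s) for s in problem.stimuli]
    resp = net.index(problem.response)
    base = np.zeros(n)
    blk = np.zeros(n, dtype=bool)
    for si in stim:
        blk[si] = True
        for e in range(m.indptr[si], m.indptr[si + 1]):
            base[m.indices[e]] += m.data[e]
    checked: list[str] = []
    guess = -1
    success = False
    for _t in range(1, config.t_max + 1):
        score = base.copy()
        if guess >= 0:
            for e in range(m.indptr[guess], m.indptr[guess + 1]):
                score[m.indices[e]] += m.data[e]
        eligible = (~blk) & (score > 0.0)
        passing = eligible & (score >= config.tau)
        total_pass = float(score[passing].sum())
        if total_pass <= 0.0:
            break
        x = -1
        if config.renormalize:
            u = rng.random() * total_pass
            acc = 0.0
            for i in np.flatnonzero(passing):
                acc += score[i]
                if acc > u:
                    x = int(i)
                    break
            if x == -1:
                x = int(np.flatnonzero(passing)[-1])
        else:
            total_all = float(score[eligible].sum())
            u = rng.random() * total_all
            acc = 0.0
            for i in np.flatnonzero(eligible):
                acc += score[i]
                if acc > u:
                    if score[i] >= config.tau:
                        x = int(i)
                    break
        if x == -1:
            continue
        blk[x] = True
        checked.append(net.words[x])
        if x == resp:
            success = True
            break
        guess = x
    return TrajectoryRecord(tuple(checked), success, len(checked))


def simulate_success_attempts(
    net: AssociationNetwork, problem: RATProblem, config: SearchConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-run outcomes: success attempt (0 = failure) and activations."""
    net = _prepare(net, config)
    m = net.matrix
    stim = np.array([net.index(s) for s in problem.stimuli], dtype=np.int64)
    resp = net.index(problem.response)
    seeds = derive_run_seeds(config.seed, problem_key(problem.id), config.n_runs)
    return simulate_batch(
        m.indptr.astype(np.int64),
        m.indices.astype(np.int64),
        m.data,
        net.n_nodes,
        stim,
        resp,
        float(config.tau),
        int(config.t_max),
        seeds,
        config.renormalize,
    )


def _summarize(
    success_attempt: np.ndarray, config: SearchConfig
) -> SimulationSummary:
    n = success_attempt.shape[0]
    wins = success_attempt > 0
    n_success = int(wins.sum())
    acc = n_success / n
    stderr = math.sqrt(acc * (1.0 - acc) / n)
    mean_len = float(success_attempt[wins].mean()) if n_success else float("nan")
    return SimulationSummary(acc, stderr, mean_len, n, n_success, config)


def estimate_accuracy(
    net: AssociationNetwork, problem: RATProblem, config: SearchConfig
) -> SimulationSummary:
    """Monte-Carlo model accuracy and mean solving-trajectory length.

    Deterministic given ``config`` (per-run counter-based seeding); the
    mean length averages over successful runs only.
    """
    success_attempt, _ = simulate_success_attempts(net, problem, config)
    return _summarize(success_attempt, config)


def accuracy_vs_tmax(
    net: AssociationNetwork,
    problems: Sequence[RATProblem],
    t_grid: Sequence[int],
    config: SearchConfig,
) -> pd.DataFrame:
    """Per-problem accuracy at each attempt budget, CRN-coupled.

    Every budget reuses the same replicate streams (a run that succeeds by
    attempt ``t`` succeeds for every larger budget), so accuracy is
    exactly non-decreasing in ``t_max`` for each problem.
    """
    t_grid = [int(t) for t in t_grid]
    if any(b <= a for a, b in zip(t_grid, t_grid[1:])):
        raise ValueError("t_grid must be strictly ascending")
    cfg = replace(config, t_max=max(t_grid))
    rows = []
    for problem in problems:
        success_attempt, _ = simulate_success_attempts(net, problem, cfg)
        for t in t_grid:
            acc = float(
                ((success_attempt > 0) & (success_attempt <= t)).mean()
            )
            rows.append({"id": problem.id, "t_max": t, "accuracy": acc})
    return pd.DataFrame(rows)


def threshold_sweep(
    net: AssociationNetwork,
    problems: Sequence[RATProblem],
    tau_grid: Sequence[float],
    config: SearchConfig,
) -> pd.DataFrame:
    """Mean accuracy and solving length per threshold and hardness category.

    For each ``tau`` every problem is simulated with the same per-run seed
    streams (so ``tau = 0`` reproduces the base simulation bit-identically)
    and results are averaged within each empirical-hardness category;
    solving lengths are pooled over successful trajectories.
    """
    tau_grid = [float(t) for t in tau_grid]
    if any(b < a for a, b in zip(tau_grid, tau_grid[1:])):
        raise ValueError("tau_grid must be ascending")
    for p in problems:
        if p.hardness is None:
            raise ValueError(f"problem {p.id!r} has no hardness")
    rows = []
    for tau in tau_grid:
        cfg = replace(config, tau=tau)
        per_cat: dict[str, dict[str, float]] = {}
        for problem in problems:
            summary = estimate_accuracy(net, problem, cfg)
            cat = categorize_hardness(problem.hardness)
            agg = per_cat.setdefault(
                cat, {"acc": 0.0, "n": 0, "len_sum": 0.0, "n_success": 0}
            )
            agg["acc"] += summary.accuracy
            agg["n"] += 1
            if summary.n_success:
                agg["len_sum"] += summary.mean_solving_length * summary.n_success
                agg["n_success"] += summary.n_success
        for cat, agg in per_cat.items():
            rows.append(
                {
                    "tau": tau,
                    "category": cat,
                    "accuracy": agg["acc"] / agg["n"],
                    "mean_solving_length": (
                        agg["len_sum"] / agg["n_success"]
                        if agg["n_success"]
                        else float("nan")
                    ),
                    "n_problems": agg["n"],
                    "n_success": agg["n_success"],
                }
            )
    return pd.DataFrame(rows)


def cutoff_experiment(
    net: AssociationNetwork,
    problems: Sequence[RATProblem],
    tau_grid: Sequence[float],
    w_max: float,
    config: SearchConfig,
) -> pd.DataFrame:
    """Threshold sweep on the strong-link-censored network.

    Edges heavier than ``w_max`` are removed statically before searching;
    ``w_max = 1`` reproduces the null model bit-identically under shared
    seeds.
    """
    if not (0.0 < w_max <= 1.0):
        raise ValueError("w_max must lie in (0, 1]")
    reduced = apply_weight_window(net, 0.0, w_max)
    return threshold_sweep(reduced, problems, tau_grid, config)


def exact_success_probability(
    net: AssociationNetwork,
    problem: RATProblem,
    t_max: int,
    tau: float,
    *,
    renormalize: bool = True,
    max_states: int = 1 << 14,
) -> float:
    """Exact success probability by dynamic programming over search states.

    The state is the pair (current guess, set of checked words); the
    transition law is :func:`candidate_distribution`, including dead-end
    termination, so the value matches the Monte-Carlo process exactly.
    Intended as a verification oracle for small networks; aborts beyond
    ``max_states`` distinct reachable states.
    """
    for w in problem.words:
        net.index(w)
    stimuli = problem.stimuli
    resp = problem.response
    seen_states: set[tuple[int, frozenset]] = set()
    memo: dict[tuple[int, frozenset, int], float] = {}

    def prob(guess: str | None, checked: frozenset, t_left: int) -> float:
        if t_left == 0:
            return 0.0
        key = (guess, checked, t_left)
        if key in memo:
            return memo[key]
        seen_states.add((guess, checked))
        if len(seen_states) > max_states:
            raise RuntimeError(f"state space exceeds {max_states} states")
        active = stimuli if guess is None else (*stimuli, guess)
        dist = candidate_distribution(
            net, active, checked, tau, renormalize=renormalize
        )
        value = dist.get(resp, 0.0)
        next_checked = checked if guess is None else checked | {guess}
        for x, p in dist.items():
            if x == resp:
                continue
            value += p * prob(x, next_checked, t_left - 1)
        if not renormalize:
            leftover = 1.0 - sum(dist.values())
            if leftover > 1e-15:
                value += leftover * prob(guess, checked, t_left - 1)
        memo[key] = value
        return value

    return prob(None, frozenset(), int(t_max))
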