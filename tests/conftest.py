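"""Shared fixtures: small handcrafted networks and a cached synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from ratnet import (
    AssociationNetwork,
    NetworkGenSpec,
    RATProblem,
    SearchConfig,
    generate_study,
)
from ratnet._rng import spawn_seed
from ratnet.synth import REFERENCE_CONFIG


def random_small_network(
    rng: np.random.Generator,
    n: int = 8,
    out_degree: int = 2,
    row_sum: float = 0.75,
) -> AssociationNetwork:
    """A small random sub-stochastic network for oracle comparisons.

    Every node gets ``out_degree`` distinct targets with Dirichlet weights
    scaled so each out-weight sum is at most ``row_sum`` (keeping walk
    enumeration bounds tight).
    """
    words = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        targets = rng.choice([j for j in range(n) if j != i], size=out_degree,
                             replace=False)
        raw = rng.dirichlet(np.ones(out_degree)) * row_sum * rng.uniform(0.5, 1.0)
        for j, w in zip(targets, raw):
            if w > 1e-9:
                edges.append((words[i], words[int(j)], float(w)))
    return AssociationNetwork.from_edges(edges, words=words)


@pytest.fixture
def dp_fixture():
    """Six-node network with a hand-expandable search tree.

    Reachable routes to the response: direct (via s2's weak link), through
    k, and through the distractor d (a dead end that redirects the search).
    """
    net = AssociationNetwork.from_edges(
        [("s1", "k", 0.2), ("s1", "d", 0.2), ("s2", "r", 0.1), ("k", "r", 0.3)],
        words=["s1", "s2", "s3", "k", "d", "r"],
    )
    problem = RATProblem(id="dp-fixture", stimuli=("s1", "s2", "s3"), response="r")
    return net, problem


@pytest.fixture
def seven_node_fixture():
    """Seven-node network with cycles and grid weights, for MC/DP checks."""
    net = AssociationNetwork.from_edges(
        [
            ("s1", "a", 0.30), ("s1", "b", 0.20),
            ("s2", "b", 0.25), ("s2", "r", 0.05),
            ("s3", "c", 0.40),
            ("a", "r", 0.15), ("a", "c", 0.10),
            ("b", "r", 0.20), ("b", "a", 0.05),
            ("c", "r", 0.10), ("c", "a", 0.20),
        ],
        words=["s1", "s2", "s3", "a", "b", "c", "r"],
    )
    problem = RATProblem(id="seven-fix", stimuli=("s1", "s2", "s3"), response="r")
    return net, problem


@pytest.fixture
def forced_success_fixture():
    """The sole out-neighbour of every stimulus is the response."""
    net = AssociationNetwork.from_edges(
        [("s1", "r", 0.5), ("s2", "r", 0.3), ("s3", "r", 0.2)],
        words=["s1", "s2", "s3", "r"],
    )
    problem = RATProblem(id="forced", stimuli=("s1", "s2", "s3"), response="r")
    return net, problem


@pytest.fixture(scope="session")
def small_study():
    """Cached synthetic study: 400-node network, (3, 3, 6) planted problems."""
    spec = NetworkGenSpec(n_nodes=400, seed=5)
    ref = SearchConfig(
        t_max=20, n_runs=2000, seed=spawn_seed(spec.seed, "reference-hardness")
    )
    net, problems = generate_study(spec, 3, 3, 6, reference_config=ref)
    return net, problems
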