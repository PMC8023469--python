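"""Association-network container, I/O and topology measurements."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratnet import (
    AssociationNetwork,
    apply_weight_window,
    collapse_cutoff,
    degree_distribution,
    edge_fraction_below,
    in_degree_tail_exponent,
    largest_strongly_connected_component,
    load_edge_list,
    percolation_curve,
    summarize_topology,
)
from ratnet.network import PercolationCurve, tail_exponent_mle

from conftest import random_small_network


# -- loading -----------------------------------------------------------


def test_single_row_weight_dialect(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("cat\tdog\t0.5\n")
    net = load_edge_list(path)
    assert net.n_nodes == 2 and net.n_edges == 1
    assert net.weight("cat", "dog") == 0.5


def test_self_loop_rows_dropped_with_warning(tmp_path, caplog):
    path = tmp_path / "e.tsv"
    path.write_text("cat\tcat\t0.2\ncat\tdog\t0.3\n")
    with caplog.at_level(logging.WARNING, logger="ratnet.network"):
        net = load_edge_list(path)
    assert net.n_edges == 1
    assert any("self-loop" in rec.message for rec in caplog.records)


def test_count_dialect_normalizes_and_sums_duplicates(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("a\tb\t30\t100\na\tc\t50\t100\na\tc\t20\t100\n")
    net = load_edge_list(path, dialect="count")
    assert net.weight("a", "b") == pytest.approx(0.3)
    assert net.weight("a", "c") == pytest.approx(0.7)
    assert net.out_strength()[net.index("a")] == pytest.approx(1.0)


def test_labels_lowercased_and_stripped(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("  Cat\tDOG \t0.5\n")
    net = load_edge_list(path)
    assert net.weight("cat", "dog") == 0.5


@pytest.mark.parametrize(
    "content, match",
    [
        ("a\tb\t0.5\na\tb\t0.2\n", "duplicate edge"),
        ("a\tb\n", "expected 3"),
        ("a\tb\t1.5\n", "outside"),
        ("a\tb\tnope\n", "malformed"),
        ("a\tb\t0.8\na\tc\t0.7\n", "out-weight sum"),
    ],
)
def test_malformed_inputs_rejected(tmp_path, content, match):
    path = tmp_path / "e.tsv"
    path.write_text(content)
    with pytest.raises(ValueError, match=match):
        load_edge_list(path)


def test_comments_blank_lines_and_header_skipped(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("cue\tresponse\tweight\n# comment\n\na\tb\t0.4\n")
    net = load_edge_list(path, header=True)
    assert net.n_edges == 1


@st.composite
def _grid_networks(draw):
    """Random networks with weights on a 1/20 grid and row sums <= 1."""
    n = draw(st.integers(2, 7))
    words = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        budget = 20
        targets = draw(
            st.lists(st.integers(0, n - 1).filter(lambda j: j != i),
                     unique=True, max_size=3)
        )
        for j in targets:
            c = draw(st.integers(1, max(1, budget // 2)))
            budget -= c
            edges.append((words[i], words[j], c / 20))
    return AssociationNetwork.from_edges(edges, words=words)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(net=_grid_networks())
def test_edge_list_round_trip(net, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "edges.tsv"
    net.write_edge_list(path)
    if net.n_edges == 0:
        return  # an empty file is not a loadable network
    back = load_edge_list(path)
    orig = {(u, v): w for u, v, w in net.edges()}
    new = {(u, v): w for u, v, w in back.edges()}
    assert orig.keys() == new.keys()
    assert all(abs(orig[k] - new[k]) < 1e-12 for k in orig)


# -- SCC and weight window --------------------------------------------


def test_scc_of_cycle_keeps_all_nodes():
    net = AssociationNetwork.from_edges(
        [("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5)]
    )
    assert set(largest_strongly_connected_component(net).words) == {"a", "b", "c"}


def test_scc_of_chain_breaks_tie_lexicographically():
    net = AssociationNetwork.from_edges([("a", "b", 0.5), ("b", "c", 0.5)])
    scc = largest_strongly_connected_component(net)
    assert scc.words == ("a",)


def test_scc_prefers_larger_of_two_cycles():
    net = AssociationNetwork.from_edges(
        [("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5),
         ("x", "y", 0.5), ("y", "x", 0.5)]
    )
    assert set(largest_strongly_connected_component(net).words) == {"a", "b", "c"}


def test_scc_is_idempotent():
    rng = np.random.default_rng(3)
    net = random_small_network(rng, n=10)
    once = largest_strongly_connected_component(net)
    twice = largest_strongly_connected_component(once)
    assert once.words == twice.words
    assert (once.matrix != twice.matrix).nnz == 0


def test_weight_window_identity_and_filtering():
    net = AssociationNetwork.from_edges(
        [("a", "b", 0.01), ("a", "c", 0.04), ("b", "c", 0.2)]
    )
    same = apply_weight_window(net, 0.0, 1.0)
    assert {e for e in same.edges()} == {e for e in net.edges()}
    mid = apply_weight_window(net, 0.02, 0.05)
    assert [(u, v) for u, v, _ in mid.edges()] == [("a", "c")]
    assert mid.words == net.words  # isolated nodes retained


def test_weight_window_bounds_inclusive():
    net = AssociationNetwork.from_edges([("a", "b", 0.05)])
    assert apply_weight_window(net, 0.05, 0.05).n_edges == 1
    with pytest.raises(ValueError):
        apply_weight_window(net, 0.6, 0.4)


# -- topology summaries ------------------------------------------------


def test_topology_of_complete_triad():
    pairs = [("a", "b"), ("b", "a"), ("a", "c"), ("c", "a"), ("b", "c"), ("c", "b")]
    net = AssociationNetwork.from_edges([(u, v, 0.3) for u, v in pairs])
    s = summarize_topology(net)
    assert s.diameter == 1 and s.transitivity == 1.0
    assert s.mean_in_out_degree == 2.0
    assert s.mean_link_weight == pytest.approx(0.3)


def test_topology_of_directed_three_cycle():
    net = AssociationNetwork.from_edges(
        [("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5)]
    )
    s = summarize_topology(net)
    assert s.diameter == 2
    assert s.transitivity == 1.0  # undirected projection is a triangle


def test_mean_degree_identity_holds_exactly():
    rng = np.random.default_rng(8)
    net = random_small_network(rng, n=9)
    s = summarize_topology(net)
    assert s.mean_in_out_degree * s.n_nodes == s.n_edges


@pytest.mark.parametrize("direction, expected", [
    ("in", {3: 1, 0: 3}),
    ("out", {1: 3, 0: 1}),
])
def test_degree_distribution_of_inward_star(direction, expected):
    net = AssociationNetwork.from_edges(
        [("l1", "hub", 0.2), ("l2", "hub", 0.2), ("l3", "hub", 0.2)]
    )
    assert degree_distribution(net, direction) == expected


def test_degree_distribution_counts_isolated_nodes():
    net = AssociationNetwork(["a", "b", "c", "d"], np.zeros((4, 4)))
    assert degree_distribution(net, "in") == {0: 4}
    net3 = AssociationNetwork.from_edges(
        [("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5)]
    )
    assert degree_distribution(net3, "in") == {1: 3}
    assert degree_distribution(net3, "out") == {1: 3}


# -- tail exponent -----------------------------------------------------


def test_tail_exponent_recovers_power_law_sample():
    # continuous MLE on 10^4 draws from a tail-index-2 law (density exp. 3)
    rng = np.random.default_rng(42)
    degrees = np.floor(10.0 * (1.0 + rng.pareto(2.0, size=10_000)))
    gamma = tail_exponent_mle(degrees, k_min=10)
    assert 2.8 <= gamma <= 3.2


def test_tail_exponent_requires_enough_tail_nodes():
    net = AssociationNetwork.from_edges([("a", "b", 0.5), ("b", "a", 0.5)])
    with pytest.raises(ValueError, match="at least 10"):
        in_degree_tail_exponent(net, k_min=5)


def test_tail_exponent_warns_on_degenerate_tail():
    degrees = np.full(20, 7.0)
    with pytest.warns(UserWarning, match="unreliable"):
        gamma = tail_exponent_mle(degrees, k_min=7)
    assert np.isfinite(gamma)


# -- percolation -------------------------------------------------------


def test_percolation_zero_cutoff_matches_base_scc():
    rng = np.random.default_rng(12)
    net = random_small_network(rng, n=10, out_degree=3)
    base_frac = largest_strongly_connected_component(net).n_nodes / net.n_nodes
    curve = percolation_curve(net, [0.0])
    assert curve.scc_fraction[0] == pytest.approx(base_frac)


def test_percolation_above_max_weight_gives_singletons():
    net = AssociationNetwork.from_edges(
        [("a", "b", 0.5), ("b", "a", 0.5), ("a", "c", 0.1), ("c", "a", 0.1)]
    )
    curve = percolation_curve(net, [0.9])
    assert curve.scc_fraction[0] == pytest.approx(1 / 3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_percolation_fraction_monotone_in_cutoff(seed):
    rng = np.random.default_rng(seed)
    net = random_small_network(rng, n=12, out_degree=3)
    curve = percolation_curve(net, np.linspace(0, 0.6, 13))
    assert all(
        f2 <= f1 + 1e-12
        for f1, f2 in zip(curve.scc_fraction, curve.scc_fraction[1:])
    )


def test_percolation_rejects_unsorted_cutoffs():
    net = AssociationNetwork.from_edges([("a", "b", 0.5), ("b", "a", 0.5)])
    with pytest.raises(ValueError, match="ascending"):
        percolation_curve(net, [0.2, 0.1])


def test_collapse_cutoff_finds_steepest_drop():
    curve = PercolationCurve((0.0, 0.05, 0.1, 0.15), (0.9, 0.85, 0.2, 0.15))
    assert collapse_cutoff(curve) == 0.1


@pytest.mark.parametrize(
    "w_cut, expected", [(0.0, 0.0), (1.1, 1.0), (0.08, 0.5)]
)
def test_edge_fraction_below(w_cut, expected):
    net = AssociationNetwork.from_edges(
        [("a", "b", 0.01), ("b", "c", 0.02), ("c", "d", 0.5), ("d", "a", 0.9)]
    )
    assert edge_fraction_below(net, w_cut) == pytest.approx(expected)


# -- container invariants ----------------------------------------------


@pytest.mark.parametrize(
    "edges, match",
    [
        ([("a", "a", 0.5)], "self-loop"),
        ([("a", "b", -0.2)], "positive"),
        ([("a", "b", 1.2)], "<= 1"),
        ([("a", "b", 0.7), ("a", "c", 0.6)], "out-weight"),
    ],
)
def test_container_rejects_invariant_violations(edges, match):
    with pytest.raises(ValueError, match=match):
        AssociationNetwork.from_edges(edges)
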