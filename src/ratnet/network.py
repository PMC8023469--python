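"""Weighted directed free-association networks: data model, I/O, topology.

An association network is built from cued-response experiments: each
directed edge ``cue -> response`` carries the fraction of participants who
produced that response to that cue, i.e. the conditional probability of the
response given the cue.  Weights therefore lie in ``(0, 1]`` and the
out-weights of every cue sum to at most one (the adjacency matrix is
sub-stochastic).  This module holds the container plus the descriptive
measurements used to characterise such networks: degree distributions, the
in-degree tail exponent, global topology summaries and weight-threshold
percolation of the strongly connected component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "OUT_SUM_TOL",
    "AssociationNetwork",
    "NetworkSummary",
    "PercolationCurve",
    "normalize_word",
    "load_edge_list",
    "largest_strongly_connected_component",
    "apply_weight_window",
    "summarize_topology",
    "degree_distribution",
    "in_degree_tail_exponent",
    "tail_exponent_mle",
    "percolation_curve",
    "collapse_cutoff",
    "edge_fraction_below",
]

logger = logging.getLogger(__name__)

#: slack allowed on per-cue out-weight sums (rounding in published norms)
OUT_SUM_TOL = 1e-9


def normalize_word(word: str) -> str:
    """Canonical word form used for all joins: stripped and lowercased."""
    return word.strip().lower()


class AssociationNetwork:
    """A vocabulary plus a sparse sub-stochastic weighted adjacency matrix.

    Parameters
    ----------
    words
        Ordered vocabulary; node ``i`` of ``matrix`` is ``words[i]``.
    matrix
        ``(n, n)`` sparse matrix of edge weights; entry ``(i, j)`` is the
        weight of the directed association ``words[i] -> words[j]``.
    validate
        Check all container invariants (positive weights <= 1, no
        self-loops, out-sums <= 1). Only disable for trusted internal
        construction paths.
    """

    __slots__ = ("words", "matrix", "_index")

    def __init__(self, words: Sequence[str], matrix, *, validate: bool = True):
        self.words: tuple[str, ...] = tuple(words)
        m = sp.csr_matrix(matrix, dtype=np.float64, copy=True)
        m.sum_duplicates()
        m.eliminate_zeros()
        self.matrix: sp.csr_matrix = m
        self._index = {w: i for i, w in enumerate(self.words)}
        if validate:
            self._validate()

    # -- construction --------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        words: Sequence[str] | None = None,
    ) -> "AssociationNetwork":
        """Build a network from ``(source, target, weight)`` triples.

        Endpoint words not listed in ``words`` are appended in order of
        first appearance.
        """
        vocab: dict[str, int] = {}
        if words is not None:
            for w in words:
                vocab.setdefault(w, len(vocab))
        rows, cols, vals = [], [], []
        for u, v, w in edges:
            iu = vocab.setdefault(u, len(vocab))
            iv = vocab.setdefault(v, len(vocab))
            rows.append(iu)
            cols.append(iv)
            vals.append(float(w))
        n = len(vocab)
        m = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n, n), dtype=np.float64
        )
        return cls(list(vocab), m)

    @classmethod
    def from_row_dicts(
        cls, words: Sequence[str], rows: Sequence[dict[int, float]]
    ) -> "AssociationNetwork":
        """Build from per-source ``{target index: weight}`` dictionaries."""
        indptr = [0]
        indices: list[int] = []
        data: list[float] = []
        for row in rows:
            for j in sorted(row):
                indices.append(j)
                data.append(row[j])
            indptr.append(len(indices))
        n = len(words)
        m = sp.csr_matrix(
            (np.asarray(data, dtype=np.float64), np.asarray(indices), np.asarray(indptr)),
            shape=(n, n),
        )
        return cls(words, m)

    def _validate(self) -> None:
        n = len(self.words)
        if n == 0:
            raise ValueError("network must have at least one word")
        if len(self._index) != n:
            raise ValueError("vocabulary contains duplicate words")
        if any(not isinstance(w, str) or not w for w in self.words):
            raise ValueError("words must be nonempty strings")
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match vocabulary size {n}"
            )
        data = self.matrix.data
        if data.size:
            if float(data.min()) <= 0.0:
                raise ValueError("edge weights must be strictly positive")
            if float(data.max()) > 1.0 + 1e-12:
                raise ValueError("edge weights must be <= 1")
        if np.any(self.matrix.diagonal() != 0.0):
            raise ValueError("self-loop edges are not allowed")
        out = np.asarray(self.matrix.sum(axis=1)).ravel()
        bad = np.flatnonzero(out > 1.0 + OUT_SUM_TOL)
        if bad.size:
            w = self.words[int(bad[0])]
            raise ValueError(
                f"out-weight sum of {w!r} is {out[bad[0]]:.12f} > 1"
            )

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.words)

    @property
    def n_edges(self) -> int:
        return int(self.matrix.nnz)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise KeyError(f"word {word!r} is not in the network vocabulary") from None

    def weight(self, source: str, target: str) -> float:
        """Weight of ``source -> target``; 0.0 when the edge is absent."""
        return float(self.matrix[self.index(source), self.index(target)])

    def successors(self, source: str) -> list[tuple[str, float]]:
        i = self.index(source)
        lo, hi = self.matrix.indptr[i], self.matrix.indptr[i + 1]
        return [
            (self.words[j], float(w))
            for j, w in zip(self.matrix.indices[lo:hi], self.matrix.data[lo:hi])
        ]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        coo = self.matrix.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.words[i], self.words[j], float(w)

    def out_strength(self) -> np.ndarray:
        """Per-node sum of outgoing weights."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_row_dicts(self) -> list[dict[int, float]]:
        m = self.matrix
        return [
            dict(zip(m.indices[m.indptr[i]: m.indptr[i + 1]].tolist(),
                     m.data[m.indptr[i]: m.indptr[i + 1]].tolist()))
            for i in range(self.n_nodes)
        ]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.words)
        g.add_weighted_edges_from(self.edges())
        return g

    def subnetwork(self, keep: Iterable[str]) -> "AssociationNetwork":
        """Node-induced subgraph, preserving the original word order."""
        keep_set = set(keep)
        idx = [i for i, w in enumerate(self.words) if w in keep_set]
        missing = keep_set - {self.words[i] for i in idx}
        if missing:
            raise KeyError(f"words not in vocabulary: {sorted(missing)[:5]}")
        sub = self.matrix[idx, :][:, idx]
        return AssociationNetwork([self.words[i] for i in idx], sub, validate=False)

    def write_edge_list(self, path, *, header: bool = False) -> None:
        """Write the network as a TSV edge list (weight dialect, UTF-8)."""
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("cue\tresponse\tweight\n")
            for u, v, w in self.edges():
                fh.write(f"{u}\t{v}\t{w:.17g}\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AssociationNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class NetworkSummary:
    """Scalar topology description of an association network."""

    n_nodes: int
    n_edges: int
    mean_in_out_degree: float
    mean_link_weight: float
    diameter: int
    transitivity: float


@dataclass(frozen=True)
class PercolationCurve:
    """Largest-SCC fraction as a function of the link-weight cutoff."""

    cutoffs: tuple[float, ...]
    scc_fraction: tuple[float, ...]

    def __post_init__(self):
        if len(self.cutoffs) != len(self.scc_fraction):
            raise ValueError("cutoffs and scc_fraction must have equal length")
        if any(b < a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be ascending")
        if any(f2 > f1 + 1e-12 for f1, f2 in zip(self.scc_fraction, self.scc_fraction[1:])):
            raise ValueError("scc_fraction must be monotone non-increasing")
        if any(not (0.0 < f <= 1.0) for f in self.scc_fraction):
            raise ValueError("scc_fraction values must lie in (0, 1]")


# -- I/O ---------------------------------------------------------------


def load_edge_list(path, dialect: str = "weight", *, header: bool = False) -> AssociationNetwork:
    """Load a TSV edge list into an :class:`AssociationNetwork`.

    Two dialects are supported. ``"weight"`` rows are
    ``cue<TAB>response<TAB>weight``; duplicate (cue, response) rows are an
    error because their meaning is ambiguous.  ``"count"`` rows are
    ``cue<TAB>response<TAB>count<TAB>total`` with weight ``count/total``;
    duplicates are summed, preserving the fraction-of-participants
    semantics.  Self-loop rows are dropped with a warning, labels are
    lowercased and stripped, lines starting with ``#`` and blank lines are
    ignored.
    """
    if dialect not in ("weight", "count"):
        raise ValueError(f"unknown dialect {dialect!r}")
    vocab: dict[str, int] = {}
    weights: dict[tuple[int, int], float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and header:
                continue
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            want = 3 if dialect == "weight" else 4
            if len(parts) != want:
                raise ValueError(
                    f"{path}:{lineno}: expected {want} tab-separated fields, got {len(parts)}"
                )
            cue = normalize_word(parts[0])
            resp = normalize_word(parts[1])
            if not cue or not resp:
                raise ValueError(f"{path}:{lineno}: empty word label")
            try:
                if dialect == "weight":
                    w = float(parts[2])
                else:
                    count = float(parts[2])
                    total = float(parts[3])
                    if total <= 0 or count < 0:
                        raise ValueError
                    w = count / total
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from None
            if cue == resp:
                logger.warning("%s:%d: dropping self-loop row %r", path, lineno, cue)
                continue
            if not (0.0 < w <= 1.0 + 1e-12):
                raise ValueError(f"{path}:{lineno}: weight {w} outside (0, 1]")
            iu = vocab.setdefault(cue, len(vocab))
            iv = vocab.setdefault(resp, len(vocab))
            key = (iu, iv)
            if key in weights:
                if dialect == "weight":
                    raise ValueError(
                        f"{path}:{lineno}: duplicate edge {cue!r} -> {resp!r} in weight dialect"
                    )
                weights[key] += w
            else:
                weights[key] = w
    if not vocab:
        raise ValueError(f"{path}: no edges found")
    n = len(vocab)
    keys = np.array(list(weights), dtype=np.int64).reshape(-1, 2)
    m = sp.csr_matrix(
        (np.array(list(weights.values())), (keys[:, 0], keys[:, 1])),
        shape=(n, n),
    )
    return AssociationNetwork(list(vocab), m)


# -- structural operations --------------------------------------------


def _scc_node_sets(net: AssociationNetwork) -> list[set[str]]:
    return [set(c) for c in nx.strongly_connected_components(net.to_networkx())]


def largest_strongly_connected_component(net: AssociationNetwork) -> AssociationNetwork:
    """Node-induced subgraph on the largest SCC.

    Ties between equal-size components are broken in favour of the
    component containing the lexicographically smallest word.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    comps = _scc_node_sets(net)
    best_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == best_size), key=min)
    return net.subnetwork(best)


def apply_weight_window(
    net: AssociationNetwork, w_min: float, w_max: float
) -> AssociationNetwork:
    """Keep exactly the edges with ``w_min <= w <= w_max`` (inclusive bounds).

    The vocabulary is unchanged, so nodes may become isolated.
    """
    if not (0.0 <= w_min <= w_max <= 1.0):
        raise ValueError(f"invalid weight window [{w_min}, {w_max}]")
    m = net.matrix.copy()
    mask = (m.data < w_min) | (m.data > w_max)
    m.data[mask] = 0.0
    m.eliminate_zeros()
    return AssociationNetwork(net.words, m, validate=False)


def summarize_topology(net: AssociationNetwork) -> NetworkSummary:
    """Global topology summary.

    The diameter is the longest directed unweighted shortest path inside
    the largest SCC; transitivity is the global clustering coefficient of
    the undirected unweighted projection.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    scc = largest_strongly_connected_component(net)
    g_scc = scc.to_networkx()
    diameter = 0 if scc.n_nodes == 1 else int(nx.diameter(g_scc))
    transitivity = float(nx.transitivity(net.to_networkx().to_undirected()))
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_in_out_degree=net.n_edges / net.n_nodes,
        mean_link_weight=float(net.matrix.data.mean()) if net.n_edges else 0.0,
        diameter=diameter,
        transitivity=transitivity,
    )


def degree_distribution(net: AssociationNetwork, direction: str) -> dict[int, int]:
    """Histogram ``degree -> node count`` over all vocabulary nodes."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    # getnnz(axis=0) counts per column (in-degree), axis=1 per row (out-degree)
    degrees = net.matrix.getnnz(axis=0) if direction == "in" else net.matrix.getnnz(axis=1)
    counts = np.bincount(np.asarray(degrees, dtype=np.int64))
    return {int(k): int(c) for k, c in enumerate(counts) if c > 0}


def tail_exponent_mle(degrees: np.ndarray, k_min: int) -> float:
    """Continuous maximum-likelihood tail exponent of a degree sample.

    Uses the Hill-type estimator with the half-integer offset
    ``gamma_hat = 1 + n / sum(log(k_i / (k_min - 0.5)))`` over the tail
    ``k_i >= k_min``.
    """
    degrees = np.asarray(degrees, dtype=np.float64)
    tail = degrees[degrees >= k_min]
    if tail.size < 10:
        raise ValueError(
            f"need at least 10 tail nodes with degree >= {k_min}, got {tail.size}"
        )
    denom = float(np.log(tail / (k_min - 0.5)).sum())
    if np.allclose(tail, k_min):
        warnings.warn(
            "all tail degrees equal k_min; the tail-exponent estimate is unreliable",
            stacklevel=2,
        )
    if denom <= 0.0:
        warnings.warn("degenerate tail: estimate diverges", stacklevel=2)
        return float("inf")
    return 1.0 + tail.size / denom


def in_degree_tail_exponent(net: AssociationNetwork, k_min: int) -> float:
    """MLE of the power-law in-degree tail exponent ``gamma``."""
    degrees = np.asarray(net.matrix.getnnz(axis=0), dtype=np.int64)
    return tail_exponent_mle(degrees, k_min)


def percolation_curve(
    net: AssociationNetwork, cutoffs: Sequence[float]
) -> PercolationCurve:
    """Largest-SCC node fraction after thresholding at each weight cutoff.

    For each ``w_cut`` the window ``[w_cut, 1]`` is applied and the largest
    SCC is recomputed; fractions are relative to the original node count.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(b < a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted ascending")
    if any(not (0.0 <= c <= 1.0) for c in cutoffs):
        raise ValueError("cutoffs must lie in [0, 1]")
    n0 = net.n_nodes
    fractions = []
    for c in cutoffs:
        windowed = apply_weight_window(net, c, 1.0)
        comps = _scc_node_sets(windowed)
        fractions.append(max(len(s) for s in comps) / n0)
    return PercolationCurve(tuple(cutoffs), tuple(fractions))


def collapse_cutoff(curve: PercolationCurve) -> float:
    """Cutoff of steepest fractional SCC drop on the evaluated grid.

    This operationalises the visually-read percolation threshold: the grid
    point where the largest-SCC fraction falls fastest.
    """
    if len(curve.cutoffs) < 2:
        raise ValueError("need at least two cutoffs")
    drops = np.diff(curve.scc_fraction)
    return float(curve.cutoffs[int(np.argmin(drops)) + 1])


def edge_fraction_below(net: AssociationNetwork, w_cut: float) -> float:
    """Fraction of edges with weight strictly below ``w_cut``."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    return float((net.matrix.data < w_cut).mean())
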