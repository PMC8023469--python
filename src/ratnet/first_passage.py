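"""First-passage solution probabilities for RAT problems.

The search for a RAT response is modelled as a Markov chain on the
association network with jump probabilities equal to the link weights.
Zeroing the response word's outgoing row turns the response into an
absorbing state, so the matrix series

    pi_{s,r} = w_{s,r} + sum_k w_{s,k} w_{k,r} + ...
             = [W- (I - W-)^(-1)]_{s,r}

counts exactly the walks that reach the response for the first time.  A
resetting weight ``lambda`` (the per-step probability of continuing the
search instead of stopping and restarting) discounts an N-step walk by
``lambda**(N-1)``:

    pi_{s,r}(lambda) = [W- (I - lambda W-)^(-1)]_{s,r}

``lambda = 0`` recovers the one-step strategy (just the direct association
weight), ``lambda = 1`` the unlimited walk.  Per problem, probabilities
are averaged over the three stimuli as starting points.  A brute-force
walk-enumeration oracle with an explicit truncation remainder bound is
provided for verification on small networks.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import MatrixRankWarning, spsolve
import warnings

from .network import AssociationNetwork
from .problems import RATProblem

__all__ = [
    "TransitionStructure",
    "SingularTransitionError",
    "make_absorbing",
    "one_step_probability",
    "first_passage_probability",
    "rat_first_passage",
    "path_sum_oracle",
    "reverse_weight_statistic",
]


class SingularTransitionError(RuntimeError):
    """The linear system (I - lambda W-) is numerically singular."""


class TransitionStructure:
    """An association network with one designated absorbing response word.

    Holds the modified adjacency matrix ``W-`` in which every outgoing
    weight of the response is zero and every other entry equals the base
    network's.  The base network is never mutated.
    """

    __slots__ = ("base", "response", "matrix")

    def __init__(self, base: AssociationNetwork, response: str):
        self.base = base
        self.response = response
        r = base.index(response)
        m = base.matrix.copy()
        m.data[m.indptr[r]: m.indptr[r + 1]] = 0.0
        m.eliminate_zeros()
        self.matrix: sp.csr_matrix = m

    @property
    def response_index(self) -> int:
        return self.base.index(self.response)


def make_absorbing(net: AssociationNetwork, response: str) -> TransitionStructure:
    """Zero the response word's outgoing row (first-passage bookkeeping)."""
    return TransitionStructure(net, response)


def one_step_probability(net: AssociationNetwork, problem: RATProblem) -> float:
    """Mean direct association weight from the stimuli to the response.

    The probability of solving by picking a stimulus uniformly and making
    a single weighted jump; absent edges contribute zero.
    """
    r = net.index(problem.response)
    total = 0.0
    for s in problem.stimuli:
        total += float(net.matrix[net.index(s), r])
    return total / 3.0


def reverse_weight_statistic(net: AssociationNetwork, problem: RATProblem) -> float:
    """Mean association weight from the response back to the stimuli.

    Used to probe whether *recognising* an already-found response limits
    solving; weak correlation of this statistic with hardness supports the
    first-passage reading of the task.
    """
    r = net.index(problem.response)
    total = 0.0
    for s in problem.stimuli:
        total += float(net.matrix[r, net.index(s)])
    return total / 3.0


def _first_passage_vector(ts: TransitionStructure, lam: float) -> np.ndarray:
    """``pi(lambda)`` from every source word to the response.

    Solves the single sparse system ``(I - lambda W-) x = e_r`` and returns
    ``W- x``; entry ``s`` is the discounted first-passage probability from
    source ``s``.  Raises :class:`SingularTransitionError` when the solve
    is numerically singular (possible only if a closed recurrent class has
    exact unit row sums at ``lambda = 1``).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda {lam} outside [0, 1]")
    n = ts.base.n_nodes
    r = ts.response_index
    b = np.zeros(n)
    b[r] = 1.0
    if lam == 0.0:
        x = b
    else:
        a = (sp.identity(n, format="csc") - lam * ts.matrix.tocsc()).tocsc()
        with warnings.catch_warnings():
            warnings.simplefilter("error", MatrixRankWarning)
            try:
                x = spsolve(a, b)
            except (MatrixRankWarning, RuntimeError) as exc:
                raise SingularTransitionError(
                    f"(I - {lam} W-) is numerically singular for response "
                    f"{ts.response!r}"
                ) from exc
        x = np.asarray(x).ravel()
        if not np.all(np.isfinite(x)):
            raise SingularTransitionError(
                f"non-finite solve for response {ts.response!r} at lambda={lam}"
            )
        residual = float(np.linalg.norm(a @ x - b))
        if residual > 1e-10:
            raise SingularTransitionError(
                f"linear solve residual {residual:.3e} exceeds 1e-10"
            )
    pi = ts.matrix @ x
    return np.clip(pi, 0.0, 1.0)


def first_passage_probability(
    ts: TransitionStructure, stimulus: str, lam: float
) -> float:
    """Discounted first-passage probability from one stimulus.

    ``[W- (I - lambda W-)^(-1)]_{s, r}`` computed by one sparse linear
    solve.  At ``lam = 0`` this equals the direct weight ``w(s -> r)``.
    """
    s = ts.base.index(stimulus)
    return float(_first_passage_vector(ts, lam)[s])


def rat_first_passage(
    net: AssociationNetwork, problem: RATProblem, lam: float
) -> float:
    """Problem-level solution probability ``p_lambda``: the mean of the
    per-stimulus first-passage probabilities with the response absorbing."""
    ts = make_absorbing(net, problem.response)
    pi = _first_passage_vector(ts, lam)
    return float(np.mean([pi[net.index(s)] for s in problem.stimuli]))


def path_sum_oracle(
    ts: TransitionStructure,
    stimulus: str,
    lam: float,
    max_len: int,
    *,
    max_visits: int = 10_000_000,
) -> tuple[float, float]:
    """Truncated first-passage series by exhaustive walk enumeration.

    Sums ``lambda**(N-1) * (walk weight)`` over every directed walk
    ``s -> ... -> r`` of length ``N <= max_len`` whose interior never
    visits the response.  Independent of the linear-system route; intended
    for small networks only (enumeration aborts beyond ``max_visits``
    partial walks).

    Returns ``(truncated_probability, remainder_bound)`` where the bound
    covers all omitted longer walks:
    ``lam**L * s_max**L / (1 - lam * s_max)`` with ``s_max`` the maximum
    row sum of ``W-`` (infinity sentinel when ``lam * s_max >= 1``).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    base = ts.base
    s0 = base.index(stimulus)
    r = ts.response_index
    m = ts.matrix
    succ: list[list[tuple[int, float]]] = [
        list(
            zip(
                m.indices[m.indptr[i]: m.indptr[i + 1]].tolist(),
                m.data[m.indptr[i]: m.indptr[i + 1]].tolist(),
            )
        )
        for i in range(base.n_nodes)
    ]
    visits = 0
    total = 0.0

    def walk(node: int, depth: int, weight: float) -> None:
        nonlocal visits, total
        for target, w in succ[node]:
            visits += 1
            if visits > max_visits:
                raise RuntimeError(
                    f"walk enumeration exceeded {max_visits} partial walks"
                )
            if target == r:
                total += (lam ** depth) * weight * w
            elif depth + 1 < max_len and lam > 0.0:
                walk(target, depth + 1, weight * w)

    walk(s0, 0, 1.0)
    row_sums = np.asarray(m.sum(axis=1)).ravel()
    s_max = float(row_sums.max()) if row_sums.size else 0.0
    if lam * s_max < 1.0:
        bound = (lam ** max_len) * (s_max ** max_len) / (1.0 - lam * s_max)
    else:
        bound = float("inf")
    return total, bound
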