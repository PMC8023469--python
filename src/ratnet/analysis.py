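"""Correlating model predictors of RAT hardness with empirical hardness.

Assembles the experiment tables: per problem, the one-step probability
``p_0``, the discounted first-passage probabilities ``p_lambda``, the
reverse-weight statistic ``w_alpha`` and the simulated model accuracy,
each correlated (Pearson, with an ordinary least-squares line) against
the empirical hardness ``H``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .first_passage import (
    make_absorbing,
    one_step_probability,
    rat_first_passage,
    reverse_weight_statistic,
)
from .network import AssociationNetwork
from .problems import (
    HARDNESS_BOUNDARIES,
    HardnessCategory,
    RATProblem,
    categorize_hardness,
    read_rat_table,
    write_rat_table,
)
from .search import SearchConfig, estimate_accuracy

__all__ = [
    "CorrelationReport",
    "ConstantSeriesError",
    "pearson_with_fit",
    "filter_resolvable",
    "predictor_experiment",
    "simulator_correlation",
    # re-exports: problem table handling lives with the RATProblem type
    "RATProblem",
    "HardnessCategory",
    "HARDNESS_BOUNDARIES",
    "categorize_hardness",
    "read_rat_table",
    "write_rat_table",
]

logger = logging.getLogger(__name__)


class ConstantSeriesError(ValueError):
    """Pearson correlation is undefined for a constant series."""


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation plus the least-squares line of y on x."""

    rho: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need n >= 3 points")
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


def pearson_with_fit(xs: Sequence[float], ys: Sequence[float]) -> CorrelationReport:
    """Pearson rho and OLS slope/intercept of ``ys`` on ``xs``."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape:
        raise ValueError("series must have equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    rho = float(stats.pearsonr(xs, ys).statistic)
    fit = stats.linregress(xs, ys)
    return CorrelationReport(rho=rho, slope=float(fit.slope),
                             intercept=float(fit.intercept), n=int(xs.size))


def filter_resolvable(
    net: AssociationNetwork, problems: Sequence[RATProblem]
) -> list[RATProblem]:
    """Keep problems whose four words are all in the network vocabulary.

    Mirrors the restriction of the empirical study to problems fully
    inside the network's strongly connected component; exclusions are
    logged.
    """
    kept = []
    for p in problems:
        missing = [w for w in p.words if w not in net]
        if missing:
            logger.warning(
                "excluding problem %r: words not in network: %s", p.id, missing
            )
        else:
            kept.append(p)
    return kept


def predictor_experiment(
    net: AssociationNetwork,
    problems: Sequence[RATProblem],
    lambdas: Sequence[float] = (0.5, 1.0),
) -> tuple[pd.DataFrame, dict[str, CorrelationReport]]:
    """Closed-form predictors per problem, each correlated against ``H``.

    Computes ``p0`` (one-step), ``p_lambda`` for every requested resetting
    weight and the reverse-weight statistic ``w_alpha``; returns the
    scatter table and one :class:`CorrelationReport` per predictor.
    """
    problems = filter_resolvable(net, problems)
    if any(p.hardness is None for p in problems):
        raise ValueError("all problems need empirical hardness")
    rows = []
    for p in problems:
        row = {"id": p.id, "H": p.hardness, "p0": one_step_probability(net, p)}
        for lam in lambdas:
            row[f"p_{lam:g}"] = rat_first_passage(net, p, lam)
        row["w_alpha"] = reverse_weight_statistic(net, p)
        rows.append(row)
    table = pd.DataFrame(rows)
    h = table["H"].to_numpy()
    if np.ptp(h) == 0.0:
        raise ConstantSeriesError("empirical hardness is constant")
    predictors = [c for c in table.columns if c not in ("id", "H")]
    reports: dict[str, CorrelationReport | None] = {}
    for name in predictors:
        try:
            reports[name] = pearson_with_fit(table[name].to_numpy(), h)
        except ConstantSeriesError:
            # e.g. w_alpha identically zero: correlation undefined
            logger.warning("predictor %r is constant; correlation undefined", name)
            reports[name] = None
    return table, reports


def simulator_correlation(
    net: AssociationNetwork,
    problems: Sequence[RATProblem],
    config: SearchConfig,
) -> tuple[CorrelationReport, pd.DataFrame]:
    """Correlate simulated model accuracy against empirical hardness."""
    problems = filter_resolvable(net, problems)
    if len(problems) < 3:
        raise ValueError("need at least 3 resolvable problems")
    if any(p.hardness is None for p in problems):
        raise ValueError("all problems need empirical hardness")
    rows = []
    for p in problems:
        summary = estimate_accuracy(net, p, config)
        rows.append(
            {
                "id": p.id,
                "H": p.hardness,
                "model_accuracy": summary.accuracy,
                "accuracy_stderr": summary.accuracy_stderr,
                "mean_solving_length": summary.mean_solving_length,
                "category": categorize_hardness(p.hardness),
            }
        )
    table = pd.DataFrame(rows)
    report = pearson_with_fit(
        table["model_accuracy"].to_numpy(), table["H"].to_numpy()
    )
    return report, table
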