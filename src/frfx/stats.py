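"""Cohort-level statistics.

Mann-Whitney U (exact by enumeration for small samples, tie-corrected normal
approximation otherwise) and the ROC/AUC machinery are implemented here
because their conventions (mid-rank ties, U/AUC identity, orientation) are
load-bearing for the outcome analyses; chi-square, Spearman and Shapiro-Wilk
delegate to scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "chi_square",
    "spearman_rho",
    "shapiro_wilk",
    "RocCurve",
    "roc_auc",
    "EXACT_ENUMERATION_LIMIT",
]

#: Exact Mann-Whitney enumeration is used when n1 + n2 does not exceed this.
EXACT_ENUMERATION_LIMIT = 12


def _rankdata_mid(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U for x (mid-rank ties) with a two-sided p-value.

    Exact p by enumerating all group assignments when n1 + n2 <= 12;
    otherwise the tie-corrected normal approximation with continuity
    correction. Two-sided p = 2 * min(P(U' <= U), P(U' >= U)), capped at 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata_mid(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        base = n1 * (n1 + 1) / 2.0
        us = np.array(
            [
                sum(ranks[list(c)]) - base
                for c in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        total = us.size
        p_le = np.sum(us <= u + 1e-9) / total
        p_ge = np.sum(us >= u - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, float(p)

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0
    mu_u = n1 * n2 / 2.0
    z = (u - mu_u - math.copysign(0.5, u - mu_u)) / math.sqrt(var_u) if u != mu_u else 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return u, float(min(1.0, p))


def chi_square(contingency_table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(contingency_table, dtype=np.float64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (screening report only; gates nothing)."""
    x = np.asarray(x, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.unique(x).size < 2:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocCurve:
    """ROC evaluation of a score against a binary outcome.

    ``auc`` is the trapezoidal area, identical to U_pos / (n_pos * n_neg)
    under the half-credit tie convention.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    direction: str


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "higher",
) -> RocCurve:
    """ROC curve and AUC from a threshold sweep over the unique scores.

    ``direction='higher'`` treats larger scores as more outcome-positive;
    ``'lower'`` the opposite (volumetric predictors of liver failure score
    positive at *low* values). Tied scores contribute half-credit, so the
    AUC equals the Mann-Whitney U of positives over negatives divided by
    (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    if direction == "lower":
        s = -s
    elif direction != "higher":
        raise ValueError("direction must be 'higher' or 'lower'")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    uniq = np.concatenate([[True], np.diff(s_sorted) != 0])
    cut = np.flatnonzero(np.concatenate([uniq[1:], [True]]))  # last idx per value
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(~y_sorted)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    return RocCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        direction=direction,
    )
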