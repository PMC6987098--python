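"""Positional comparison statistics.

The comparison suite used on per-game exposure measures: a tie-corrected
Kruskal-Wallis omnibus test across positions, Dunn's rank-based post-hoc
pairwise comparisons with Bonferroni adjustment, and a Pearson chi-square
contingency analysis with per-cell adjusted standardized residuals (also
Bonferroni-corrected, conservatively over all cells).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RankTestResult",
    "PairwiseResult",
    "ContingencyResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "contingency_residuals",
    "format_p",
]

ALPHA_DEFAULT = 0.05


def format_p(p: float) -> str:
    """Report a p-value to 3 decimals with a '<0.001' display floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class RankTestResult:
    H: float
    df: int
    p: float
    group_mean_ranks: list
    labels: list


@dataclass
class PairwiseResult:
    pair: tuple
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float
    residuals: np.ndarray  # adjusted standardized residual per cell
    significant: np.ndarray  # per-cell flags, Bonferroni over all cells
    row_labels: list
    col_labels: list


def _mean_ranks(groups: Sequence[Sequence[float]]):
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(pooled)
    mean_ranks, start = [], 0
    for g in groups:
        n = len(g)
        mean_ranks.append(float(np.mean(ranks[start : start + n])))
        start += n
    return ranks, mean_ranks


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups.

    Returns the H statistic, chi-square degrees of freedom (k - 1), the
    p-value and per-group mean ranks.  All-identical data gives H = 0,
    p = 1 (no evidence of any difference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis groups must all be non-empty")
    labels = list(labels) if labels is not None else [f"group{i+1}" for i in range(len(groups))]
    _, mean_ranks = _mean_ranks(groups)
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return RankTestResult(H=0.0, df=df, p=1.0, group_mean_ranks=mean_ranks, labels=labels)
    H, p = sps.kruskal(*groups)
    return RankTestResult(H=float(H), df=df, p=float(p), group_mean_ranks=mean_ranks, labels=labels)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = ALPHA_DEFAULT,
    labels: Optional[Sequence[str]] = None,
) -> list:
    """Dunn's pairwise post-hoc comparisons with Bonferroni adjustment.

    For each of the k(k-1)/2 pairs, z is the mean-rank difference divided by
    its tie-corrected standard error sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal
    p-values are multiplied by the number of comparisons (capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("dunn_posthoc groups must all be non-empty")
    labels = list(labels) if labels is not None else [f"group{i+1}" for i in range(len(groups))]
    ranks, mean_ranks = _mean_ranks(groups)
    N = sum(len(g) for g in groups)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0.0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                z=float(z),
                p_raw=float(p_raw),
                p_adjusted=float(p_adj),
                significant=bool(p_adj < alpha),
            )
        )
    return out


def contingency_residuals(
    table,
    alpha: float = ALPHA_DEFAULT,
    row_labels: Optional[Sequence[str]] = None,
    col_labels: Optional[Sequence[str]] = None,
) -> ContingencyResult:
    """Pearson chi-square with per-cell adjusted standardized residuals.

    Residual z = (O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N)),
    which behaves as a standard normal under independence.  Cell-level
    significance applies a Bonferroni correction over all r x c cells (the
    conservative family).  Rows or columns with a zero marginal are dropped
    with a warning; degenerate 1 x c / r x 1 tables have all-zero residuals.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("contingency table total must be positive")
    row_labels = list(row_labels) if row_labels is not None else [f"r{i}" for i in range(obs.shape[0])]
    col_labels = list(col_labels) if col_labels is not None else [f"c{j}" for j in range(obs.shape[1])]
    keep_rows = obs.sum(axis=1) > 0
    keep_cols = obs.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        dropped = [row_labels[i] for i in np.flatnonzero(~keep_rows)] + [
            col_labels[j] for j in np.flatnonzero(~keep_cols)
        ]
        logger.warning("dropping zero-marginal rows/columns: %s", dropped)
        obs = obs[keep_rows][:, keep_cols]
        row_labels = [l for l, k in zip(row_labels, keep_rows) if k]
        col_labels = [l for l, k in zip(col_labels, keep_cols) if k]
    r, c = obs.shape
    N = obs.sum()
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    expected = row_tot @ col_tot / N
    if r == 1 or c == 1:
        resid = np.zeros_like(obs)
        chi2, p, df = 0.0, 1.0, 0
    else:
        chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
        denom = np.sqrt(expected * (1.0 - row_tot / N) * (1.0 - col_tot / N))
        resid = (obs - expected) / denom
    n_cells = resid.size
    p_cells = 2.0 * sps.norm.sf(np.abs(resid))
    significant = np.minimum(1.0, p_cells * n_cells) < alpha
    return ContingencyResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        residuals=resid,
        significant=significant,
        row_labels=row_labels,
        col_labels=col_labels,
    )
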