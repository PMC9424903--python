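"""Target-gene transcriptomic screen on a bulk expression matrix.

The screen has three steps:

1. ``preprocess`` — shift every value by +1 (so fold changes are defined
   at zero expression) and drop genes expressed below a minimum
   threshold (raw value < 1.5) in more than half of the samples.
2. ``rank_correlates`` — rank all other genes by Spearman correlation
   with the target gene.
3. ``differential_expression`` — split samples at the target gene's
   median expression (ties go to the low group), compute per-gene
   log2 fold change as log2 of the ratio of group means on shifted
   values, a two-sided Wilcoxon rank-sum p-value, and Benjamini-Hochberg
   q-values over all tested genes.

``screen`` chains the three steps into one result table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess",
    "rank_correlates",
    "bh_qvalues",
    "differential_expression",
    "screen",
]


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (adjusted p-values)."""
    _, q, _, _ = multipletests(np.asarray(p, dtype=float), method="fdr_bh")
    return q


def preprocess(
    matrix: pd.DataFrame,
    min_expression: float = 1.5,
    max_low_fraction: float = 0.5,
    shift: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Shift and low-expression-filter a raw genes x samples matrix.

    A gene is removed when strictly more than ``max_low_fraction`` of its
    samples have raw value below ``min_expression`` (a gene at exactly
    the boundary fraction is retained). Returns the +``shift``-ed
    filtered matrix and the list of removed genes.
    """
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    low_fraction = (matrix < min_expression).mean(axis=1)
    removed = matrix.index[low_fraction > max_low_fraction].tolist()
    kept = matrix.drop(index=removed)
    return kept + shift, removed


def _spearman_with_target(matrix: pd.DataFrame, target: str) -> pd.Series:
    """Spearman rho of every gene with the target gene (vectorized via
    rank transform + Pearson on ranks, average ranks for ties)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix.to_numpy())
    t = ranks[matrix.index.get_loc(target)]
    t_c = t - t.mean()
    r_c = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((r_c**2).sum(axis=1) * (t_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (r_c @ t_c) / denom
    return pd.Series(rho, index=matrix.index, name="rho")


def rank_correlates(matrix: pd.DataFrame, target: str) -> pd.DataFrame:
    """Genes ranked by Spearman correlation with the target gene.

    The target itself is excluded from the ranking. Returns a table with
    columns ``gene``, ``rho`` and ``rho_rank`` (1 = most correlated),
    sorted by descending rho.
    """
    if target not in matrix.index:
        raise ValueError(f"target gene {target!r} not present (filtered out?)")
    rho = _spearman_with_target(matrix, target).drop(index=target)
    out = (
        rho.rename_axis("gene")
        .reset_index()
        .sort_values("rho", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    out["rho_rank"] = np.arange(1, len(out) + 1)
    return out


def differential_expression(matrix: pd.DataFrame, target: str) -> pd.DataFrame:
    """Median-split differential expression against the target gene.

    Samples at or below the target's median form the low group. Per gene:
    ``log2fc = log2(mean_high / mean_low)`` on the (shifted) values, a
    two-sided Wilcoxon rank-sum p, and BH q over all tested genes.
    Returns a table sorted by descending log2fc with ``fc_rank``.
    """
    if target not in matrix.index:
        raise ValueError(f"target gene {target!r} not present (filtered out?)")
    target_vals = matrix.loc[target]
    median = target_vals.median()
    high = target_vals > median
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("degenerate median split: fewer than 2 samples in a group")

    others = matrix.drop(index=target)
    hi = others.loc[:, high].to_numpy()
    lo = others.loc[:, ~high].to_numpy()
    log2fc = np.log2(hi.mean(axis=1) / lo.mean(axis=1))
    _, p = stats.mannwhitneyu(hi, lo, axis=1, alternative="two-sided")
    q = bh_qvalues(p)

    out = pd.DataFrame(
        {"gene": others.index, "log2fc": log2fc, "p": p, "q": q}
    ).sort_values("log2fc", ascending=False, kind="mergesort").reset_index(drop=True)
    out["fc_rank"] = np.arange(1, len(out) + 1)
    return out


def screen(
    matrix_raw: pd.DataFrame,
    target: str,
    min_expression: float = 1.5,
    max_low_fraction: float = 0.5,
) -> pd.DataFrame:
    """Full target-gene screen on a raw matrix.

    Preprocesses, then merges the correlation ranking and the
    differential-expression results into one table with columns
    ``gene, rho, rho_rank, log2fc, p, q, fc_rank``.
    """
    shifted, _ = preprocess(matrix_raw, min_expression, max_low_fraction)
    corr = rank_correlates(shifted, target)
    de = differential_expression(shifted, target)
    return corr.merge(de, on="gene")
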