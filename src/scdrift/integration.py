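"""Per-cell methylation/expression coupling and cross-layer heterogeneity.

Two questions are asked of matched methylome + transcriptome data:

1. Within each cell, is promoter methylation negatively associated with the
   expression of the gene it drives?  One Pearson correlation is computed
   per cell across its genes with both measurements.
2. Do promoters whose methylation heterogeneity increases with age drive
   genes whose transcriptional heterogeneity also increases?  Per-gene
   changes in mean distance-to-the-median are normalised with the same
   sliding-window Z-score used for the methylation contrast, promoters are
   stratified at a methylation-heterogeneity-change threshold, and the two
   strata are contrasted with a rank-sum test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._rolling import sliding_zscore

__all__ = [
    "per_cell_association",
    "group_contrast",
    "delta_layer_comparison",
]


def per_cell_association(
    promoter_meth: pd.DataFrame,
    expression: pd.DataFrame,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Pearson correlation between promoter methylation and expression, per cell.

    Both inputs are genes x cells frames (promoter methylation fractions and
    log-scale expression) sharing gene and cell labels; NaN marks a gene
    unmeasured in that cell in that layer.  Cells with fewer than
    ``min_genes`` doubly measured genes are reported with ``r`` = NaN and a
    reason.  Returns a per-cell table (r, n_genes_used, reason).
    """
    genes = promoter_meth.index.intersection(expression.index)
    cells = promoter_meth.columns.intersection(expression.columns)
    if len(genes) == 0 or len(cells) == 0:
        raise ValueError("no shared genes/cells between the two layers")
    meth = promoter_meth.loc[genes, cells]
    expr = expression.loc[genes, cells]

    rows = []
    for cell in cells:
        m = meth[cell].to_numpy(dtype=float)
        e = expr[cell].to_numpy(dtype=float)
        both = np.isfinite(m) & np.isfinite(e)
        n = int(both.sum())
        if n < min_genes:
            rows.append({"cell_id": cell, "r": np.nan, "n_genes_used": n,
                         "reason": "too_few_genes"})
            continue
        if np.std(m[both]) == 0 or np.std(e[both]) == 0:
            rows.append({"cell_id": cell, "r": np.nan, "n_genes_used": n,
                         "reason": "constant_layer"})
            continue
        r = float(stats.pearsonr(m[both], e[both]).statistic)
        rows.append({"cell_id": cell, "r": r, "n_genes_used": n, "reason": ""})
    return pd.DataFrame(rows).set_index("cell_id")


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney p by enumerating all C(n, n1) group assignments.

    Mid-ranks handle ties, so the enumeration remains exact for tied data
    (unlike the classical exact tables).  Returns (U of x, p).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    n = pooled.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    n_extreme = 0
    eps = 1e-9
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if alternative == "greater":
            extreme = u >= u_obs - eps
        elif alternative == "less":
            extreme = u <= u_obs + eps
        else:
            extreme = abs(u - mu) >= abs(u_obs - mu) - eps
        n_extreme += extreme
    return float(u_obs), n_extreme / comb(n, n1)


def group_contrast(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon rank-sum contrast between two groups.

    Ties are handled by mid-ranks.  With ``method='auto'`` the p-value is
    computed by exhaustive permutation enumeration when the pooled size is
    <= 12 (exact even under ties) and by the scipy normal approximation with
    tie correction otherwise.  Returns (U statistic of ``x``, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    exact = method == "exact" or (method == "auto" and x.size + y.size <= 12)
    if exact:
        return _exact_rank_sum_p(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def delta_layer_comparison(
    delta_h_z: pd.Series,
    dm_young: pd.Series,
    dm_old: pd.Series,
    promoter_to_gene: pd.Series,
    threshold: float = 0.3,
    window: int = 100,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Contrast transcriptional heterogeneity change across methylation strata.

    ``delta_h_z`` is the windowed Z-score of the promoter methylation
    heterogeneity change (old - young); ``dm_young`` / ``dm_old`` are
    per-gene mean distance-to-the-median values per age; ``promoter_to_gene``
    maps promoter ids to gene ids.  The per-gene DM change is normalised
    with the same sliding-window Z-score (ordered by the mean of the two DM
    values), promoters are stratified at ``delta_h_z > threshold``, and the
    high stratum is contrasted against the rest with a rank-sum test.
    Returns (per-promoter table, (U, p)).
    """
    genes = dm_young.index.intersection(dm_old.index)
    if len(genes) < 2:
        raise ValueError("need at least two genes with DM in both ages")
    d = (dm_old.loc[genes] - dm_young.loc[genes]).to_numpy(dtype=float)
    centre = ((dm_young.loc[genes] + dm_old.loc[genes]) / 2.0).to_numpy(dtype=float)
    delta_txn = pd.Series(sliding_zscore(d, centre, window=window), index=genes)

    table = pd.DataFrame({"gene_id": promoter_to_gene})
    table["delta_H_z"] = delta_h_z
    table = table.dropna(subset=["gene_id", "delta_H_z"])
    table["delta_txn_het"] = table["gene_id"].map(delta_txn)
    table = table.dropna(subset=["delta_txn_het"])
    table["high_meth_het"] = table["delta_H_z"] > threshold

    high = table.loc[table["high_meth_het"], "delta_txn_het"].to_numpy()
    rest = table.loc[~table["high_meth_het"], "delta_txn_het"].to_numpy()
    if high.size == 0 or rest.size == 0:
        raise ValueError(
            f"empty stratum at threshold {threshold} "
            f"(high={high.size}, rest={rest.size})"
        )
    contrast = group_contrast(high, rest, alternative=alternative)
    return table, contrast
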