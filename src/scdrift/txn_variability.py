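"""Transcriptional variability statistics and the similarity-to-young ranking.

Expression is normalised to reads per million of reads mapped to the
transcriptome (RPM).  Variability per gene is measured by the *distance to
the median* (DM): the squared coefficient of variation (CV^2 = var/mean^2)
on log scale minus a centred rolling average of log CV^2 across genes
ordered by mean expression — an expression-level-normalised dispersion.
Cell-to-cell coherence within a sample is summarised by pairwise Spearman
correlations over the most variable genes, optionally averaged over random
cohorts of cells.  Old cells are ranked by their Spearman similarity to the
mean young transcriptome, and per-gene association with that ranking
identifies the genes driving it.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rolling import rolling_centered
from .core_io import ExpressionMatrix

__all__ = [
    "normalise_rpm",
    "distance_to_median",
    "expression_frequency",
    "top_variable_genes",
    "cell_correlation_analysis",
    "similarity_to_young",
    "SimilarityResult",
]


def normalise_rpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads-per-million normalisation: count * 1e6 / mapped_total per cell."""
    totals = matrix.mapped_total
    if (totals <= 0).any():
        raise ValueError("mapped_total must be positive for every cell")
    return matrix.counts * (1e6 / totals)


def distance_to_median(
    normalised: pd.DataFrame,
    min_mean: float = 10.0,
    window: int = 100,
) -> pd.DataFrame:
    """Distance to the median: expression-level-normalised variability.

    Genes with mean RPM below ``min_mean`` are excluded; the rest are sorted
    by mean and ``dm = log2(cv2) - rolling_mean(log2(cv2), window)`` with a
    centred window.  Genes with zero variance cannot be placed on log scale
    and are dropped with a warning.  Returns a per-gene table with columns
    mean_rpm, cv2, dm.
    """
    mean = normalised.mean(axis=1)
    keep = mean >= min_mean
    if int(keep.sum()) < window:
        raise ValueError(
            f"only {int(keep.sum())} genes pass mean >= {min_mean}; "
            f"need at least the window size ({window})"
        )
    sub = normalised.loc[keep]
    mean = mean[keep]
    var = sub.var(axis=1, ddof=1)
    cv2 = var / mean**2
    zero = cv2 <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant genes dropped from DM", stacklevel=2
        )
        cv2, mean = cv2[~zero], mean[~zero]
    order = np.argsort(mean.to_numpy(), kind="stable")
    log_cv2 = np.log2(cv2.to_numpy())[order]
    trend = rolling_centered(log_cv2, window, np.mean)
    dm = np.empty(log_cv2.size)
    dm[order] = log_cv2 - trend
    return pd.DataFrame(
        {"mean_rpm": mean, "cv2": cv2, "dm": dm}, index=mean.index
    ).rename_axis("gene_id")


def expression_frequency(
    matrix: ExpressionMatrix,
    group_labels: pd.Series,
    flag_threshold: float = 0.15,
) -> pd.DataFrame:
    """Per-gene expression frequency by age group and the young-old drop.

    ``freq`` is the fraction of cells in a group with a non-zero count.
    ``delta_freq = freq_young - freq_old``; genes with a drop above
    ``flag_threshold`` (15%) are flagged as gaining variability with age.
    """
    group_labels = group_labels.reindex(matrix.cell_ids)
    out = {}
    for group in ("young", "old"):
        cells = group_labels.index[group_labels == group]
        if len(cells) == 0:
            raise ValueError(f"no cells labelled {group!r}")
        out[f"freq_{group}"] = (matrix.counts[cells] > 0).mean(axis=1)
    frame = pd.DataFrame(out)
    frame["delta_freq"] = frame["freq_young"] - frame["freq_old"]
    frame["flagged"] = frame["delta_freq"] > flag_threshold
    return frame.rename_axis("gene_id")


def top_variable_genes(stats_frame: pd.DataFrame, n: int) -> list[str]:
    """Top ``n`` genes by DM; ties broken by gene id for determinism."""
    frame = stats_frame.reset_index() if "gene_id" not in stats_frame.columns else stats_frame
    ranked = frame.sort_values(
        ["dm", "gene_id"], ascending=[False, True], kind="stable"
    ).set_index("gene_id")
    if n > len(ranked):
        warnings.warn(
            f"requested {n} genes but only {len(ranked)} available", stacklevel=2
        )
        n = len(ranked)
    return list(ranked.index[:n])


def _pairwise_spearman(profiles: pd.DataFrame) -> pd.DataFrame:
    """Cells x cells Spearman correlation matrix (genes are rows)."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least two genes for rank correlations")
    rho = profiles.corr(method="spearman")
    return rho


def cell_correlation_analysis(
    normalised: pd.DataFrame,
    gene_set: Sequence[str],
    groups: pd.Series | None = None,
    cohort_size: int | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Within-sample cell-cell Spearman correlations on a gene set.

    Returns a long table of all within-group cell pairs (cell_i, cell_j,
    group, rho).  With ``cohort_size`` set, additionally draws ``n_iter``
    random cohorts per group (cells without replacement within a cohort) and
    returns each cohort's mean pairwise rho — the cohort-level summary used
    to compare coherence between ages.  Constant cell profiles have
    undefined rank correlations; their pairs are excluded (rho = NaN in the
    long table, ignored in cohort means).
    """
    if groups is None:
        groups = pd.Series("all", index=normalised.columns)
    groups = groups.reindex(normalised.columns)
    rng = np.random.default_rng(seed)
    sub = normalised.loc[list(gene_set)]

    pair_rows = []
    cohort_rows = []
    for group in pd.unique(groups.dropna()):
        cells = list(groups.index[groups == group])
        rho = _pairwise_spearman(sub[cells])
        arr = rho.to_numpy()
        n = len(cells)
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            pair_rows.append(
                {"group": group, "cell_i": cells[i], "cell_j": cells[j],
                 "rho": arr[i, j]}
            )
        if cohort_size is not None:
            if cohort_size > n:
                raise ValueError(
                    f"cohort_size {cohort_size} exceeds {n} cells in {group!r}"
                )
            for it in range(n_iter):
                idx = rng.choice(n, size=cohort_size, replace=False)
                block = arr[np.ix_(idx, idx)]
                vals = block[np.triu_indices(cohort_size, k=1)]
                cohort_rows.append(
                    {"group": group, "iteration": it,
                     "mean_rho": float(np.nanmean(vals))}
                )
    pairs = pd.DataFrame(pair_rows)
    cohorts = pd.DataFrame(cohort_rows) if cohort_size is not None else None
    return pairs, cohorts


@dataclass
class SimilarityResult:
    """Similarity-to-young ranking and the genes associated with it."""

    records: pd.DataFrame  # old cell_id -> rho, rank (1 = most similar)
    gene_correlations: pd.Series  # per-gene Spearman with the similarity score
    top_correlated: list[str]
    top_anticorrelated: list[str]


def similarity_to_young(
    normalised: pd.DataFrame,
    young_cells: Sequence[str],
    old_cells: Sequence[str],
    min_cells: int = 5,
    top_n: int = 200,
) -> SimilarityResult:
    """Rank old cells by Spearman similarity to the mean young transcriptome.

    The young reference is the per-gene mean of log2(RPM + 1) over young
    cells.  Genes expressed (RPM > 0) in fewer than ``min_cells`` cells are
    excluded.  Each old cell's log profile is Spearman-correlated with the
    reference; cells are ranked by decreasing rho.  Per-gene Spearman
    correlation of expression with the per-cell similarity score identifies
    the ``top_n`` correlated and anticorrelated genes.
    """
    young_cells, old_cells = list(young_cells), list(old_cells)
    if not young_cells or len(old_cells) < 2:
        raise ValueError("need >=1 young and >=2 old cells")
    used = normalised[young_cells + old_cells]
    expressed_in = (used > 0).sum(axis=1)
    genes = used.index[expressed_in >= min_cells]
    if len(genes) < 2:
        raise ValueError("min_cells filter left fewer than 2 genes")
    log_expr = np.log2(used.loc[genes] + 1.0)
    reference = log_expr[young_cells].mean(axis=1)

    rho = {
        cell: stats.spearmanr(log_expr[cell], reference).statistic
        for cell in old_cells
    }
    records = pd.DataFrame({"rho": pd.Series(rho)}).rename_axis("cell_id")
    records = records.sort_values("rho", ascending=False, kind="stable")
    records["rank"] = np.arange(1, len(records) + 1)

    score = records["rho"].reindex(old_cells)
    old_log = log_expr[old_cells]
    varying = old_log.index[old_log.nunique(axis=1) > 1]
    gene_corr = old_log.loc[varying].apply(
        lambda row: stats.spearmanr(row.to_numpy(), score.to_numpy()).statistic,
        axis=1,
    )
    gene_corr = gene_corr.dropna()
    ordered = gene_corr.sort_values(ascending=False, kind="stable")
    top_corr = list(ordered.index[:top_n])
    top_anti = list(ordered.index[::-1][:top_n])
    return SimilarityResult(records, gene_corr, top_corr, top_anti)
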