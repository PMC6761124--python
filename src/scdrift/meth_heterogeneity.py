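"""Cell-to-cell DNA methylation heterogeneity scoring and normalisation.

The per-region heterogeneity score is built from all pairs of cells with
enough shared CpG coverage.  For a pair sharing ``k`` covered sites:

* ``D`` — normalised Hamming distance: fraction of the k sites where the two
  binary states disagree (in [0, 1]);
* ``S`` — joint Shannon entropy in bits of the ordered two-cell pattern
  (0,0) / (0,1) / (1,0) / (1,1) over the k sites (in [0, 2]);
* ``w = k`` — the pair weight.

The region score is the product of the coverage-weighted means,

    H = (sum w_c D_c / sum w_c) * (sum w_c S_c / sum w_c),

so H is in [0, 2], is zero when all shared patterns are identical, and is
insensitive both to population substructure (pairwise, not mean-based) and
to missingness (pairs use only jointly covered sites, weighted by k).

Because raw H depends on the region's mean methylation (entropy peaks at
intermediate methylation), H is normalised by subtracting a rolling median
of H across regions ordered by mean methylation, and young/old differences
are further standardised with a sliding-window Z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rolling import rolling_centered, sliding_zscore
from .core_io import RegionCallMatrix

__all__ = [
    "PairStats",
    "pair_stats",
    "region_heterogeneity",
    "region_mean_methylation",
    "score_regions",
    "filter_regions",
    "normalise_heterogeneity",
    "delta_het_zscore",
]

#: minimum number of jointly covered CpGs for a cell pair to count
DEFAULT_MIN_SHARED_SITES = 4


@dataclass(frozen=True)
class PairStats:
    """Statistics of one qualifying cell pair within a region."""

    cell_i: int
    cell_j: int
    k: int  # shared covered CpGs
    D: float  # normalised Hamming distance in [0, 1]
    S: float  # joint Shannon entropy in bits, in [0, 2]

    @property
    def w(self) -> int:
        return self.k


def pair_stats(
    row_i: np.ndarray,
    row_j: np.ndarray,
    min_shared_sites: int = DEFAULT_MIN_SHARED_SITES,
) -> PairStats | None:
    """Compute D, S and the weight for one pair of cell rows.

    Rows are {0, 1, NaN} vectors over the same site columns.  Only sites
    covered in *both* cells contribute; pairs with fewer than
    ``min_shared_sites`` such sites are dropped (returns ``None``).
    """
    row_i = np.asarray(row_i, dtype=float)
    row_j = np.asarray(row_j, dtype=float)
    if row_i.shape != row_j.shape:
        raise ValueError("rows must cover the same site columns")
    shared = np.isfinite(row_i) & np.isfinite(row_j)
    k = int(shared.sum())
    if k < min_shared_sites:
        return None
    a = row_i[shared]
    b = row_j[shared]
    D = float(np.sum(a != b)) / k
    # joint entropy over ordered per-site patterns (0,0),(0,1),(1,0),(1,1)
    pattern = (2 * a + b).astype(int)
    counts = np.bincount(pattern, minlength=4)
    p = counts[counts > 0] / k
    S = float(-(p * np.log2(p)).sum())
    return PairStats(cell_i=0, cell_j=1, k=k, D=D, S=S)


def _pairwise_pattern_counts(states: np.ndarray):
    """Counts of the four ordered patterns and shared coverage, all pairs.

    Returns (n00, n01, n10, n11, k) as n_cells x n_cells matrices; entry
    [i, j] refers to ordered pair (row i, row j) over jointly covered sites.
    """
    obs = np.isfinite(states)
    X = np.where(obs, states, 0.0)
    O = obs.astype(float)
    U = O - X  # indicator of an observed unmethylated state
    n11 = X @ X.T
    n10 = X @ U.T
    n01 = U @ X.T
    n00 = U @ U.T
    k = O @ O.T
    return n00, n01, n10, n11, k


def region_heterogeneity(
    matrix: RegionCallMatrix | np.ndarray,
    min_shared_sites: int = DEFAULT_MIN_SHARED_SITES,
) -> tuple[float | None, list[PairStats]]:
    """Weighted heterogeneity score H of a region and its qualifying pairs.

    H = (weighted mean D) x (weighted mean S) over all cell pairs with at
    least ``min_shared_sites`` jointly covered CpGs, weights w = k.  If no
    pair qualifies H is undefined and ``(None, [])`` is returned.
    """
    states = matrix.states if isinstance(matrix, RegionCallMatrix) else np.asarray(matrix, float)
    n_cells = states.shape[0]
    if n_cells < 2:
        raise ValueError("region_heterogeneity needs at least 2 cells")

    n00, n01, n10, n11, k = _pairwise_pattern_counts(states)
    iu, ju = np.triu_indices(n_cells, k=1)
    kk = k[iu, ju]
    qual = kk >= min_shared_sites
    if not qual.any():
        return None, []
    iu, ju, kk = iu[qual], ju[qual], kk[qual]
    counts = np.stack([m[iu, ju] for m in (n00, n01, n10, n11)], axis=1)
    D = (counts[:, 1] + counts[:, 2]) / kk
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / kk[:, None]
        plogp = np.where(counts > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    S = -plogp.sum(axis=1)
    w = kk
    H = float((w @ D) / w.sum() * (w @ S) / w.sum())
    pairs = [
        PairStats(int(i), int(j), int(ki), float(di), float(si))
        for i, j, ki, di, si in zip(iu, ju, kk, D, S)
    ]
    return H, pairs


def region_mean_methylation(matrix: RegionCallMatrix | np.ndarray) -> float | None:
    """Coverage-weighted mean methylation of a region.

    Each cell's within-region mean is weighted by its number of covered
    sites, which equals the grand mean over all non-missing entries.
    Returns ``None`` for an all-missing matrix (record skipped upstream).
    """
    states = matrix.states if isinstance(matrix, RegionCallMatrix) else np.asarray(matrix, float)
    if not np.isfinite(states).any():
        return None
    return float(np.nanmean(states))


def score_regions(
    matrices: Iterable[RegionCallMatrix],
    min_shared_sites: int = DEFAULT_MIN_SHARED_SITES,
) -> pd.DataFrame:
    """Score a collection of regions into the per-region record table.

    Columns: H, mean_meth, n_cpg_total, mean_cpg_per_cell, n_pairs, n_cells.
    Regions with undefined H or mean methylation are skipped.
    """
    rows = {}
    for m in matrices:
        H, pairs = region_heterogeneity(m, min_shared_sites)
        mean_meth = region_mean_methylation(m)
        if H is None or mean_meth is None:
            continue
        covered_per_cell = np.isfinite(m.states).sum(axis=1)
        rows[m.region_id] = {
            "H": H,
            "mean_meth": mean_meth,
            "n_cpg_total": m.n_sites,
            "mean_cpg_per_cell": float(covered_per_cell.mean()),
            "n_pairs": len(pairs),
            "n_cells": m.n_cells,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("region_id")


def filter_regions(
    young: pd.DataFrame,
    old: pd.DataFrame,
    *,
    min_cpg_total: int = 20,
    min_mean_cpg_per_cell: float = 2.0,
    min_pairs: int = 100,
    max_mean_cpg_diff: float = 10.0,
    max_pairs_diff: float = 200.0,
) -> pd.DataFrame:
    """Apply the coverage-based region filters across both age groups.

    A region is kept iff, in *both* ages, it has >= ``min_cpg_total`` CpGs,
    an average of >= ``min_mean_cpg_per_cell`` covered CpGs per cell and
    >= ``min_pairs`` qualifying cell pairs; and the two ages do not differ
    by more than ``max_mean_cpg_diff`` average CpGs per cell or
    ``max_pairs_diff`` pairwise comparisons.  Regions present in one age
    only are excluded.  Returns a table with ``kept`` and ``reasons``.
    """
    all_ids = young.index.union(old.index)
    out = []
    for rid in all_ids:
        reasons: list[str] = []
        if rid not in young.index or rid not in old.index:
            reasons.append("absent_in_one_age")
        else:
            y, o = young.loc[rid], old.loc[rid]
            for label, rec in (("young", y), ("old", o)):
                if rec["n_cpg_total"] < min_cpg_total:
                    reasons.append(f"{label}_few_cpgs")
                if rec["mean_cpg_per_cell"] < min_mean_cpg_per_cell:
                    reasons.append(f"{label}_low_mean_cpg_per_cell")
                if rec["n_pairs"] < min_pairs:
                    reasons.append(f"{label}_few_pairs")
            if abs(o["mean_cpg_per_cell"] - y["mean_cpg_per_cell"]) > max_mean_cpg_diff:
                reasons.append("age_mean_cpg_imbalance")
            if abs(o["n_pairs"] - y["n_pairs"]) > max_pairs_diff:
                reasons.append("age_pairs_imbalance")
        out.append({"region_id": rid, "kept": not reasons, "reasons": ";".join(reasons)})
    return pd.DataFrame(out).set_index("region_id")


def normalise_heterogeneity(
    records: pd.DataFrame,
    window: int = 1000,
    meth_band: tuple[float, float] = (0.05, 0.9),
    min_records: int = 20,
    min_half: int = 50,
) -> pd.DataFrame:
    """Mean-methylation-normalised heterogeneity (``H_norm`` column).

    Records with mean methylation below ``meth_band[0]`` or above
    ``meth_band[1]`` are excluded; the rest are ordered by mean methylation
    and ``H_norm = H - rolling_median(H, window)`` with symmetric edge
    shrinkage (minimum half-width ``min_half``).
    """
    lo, hi = meth_band
    kept = records[(records["mean_meth"] >= lo) & (records["mean_meth"] <= hi)].copy()
    if len(kept) < min_records:
        raise ValueError(
            f"only {len(kept)} records inside the methylation band; "
            "reduce the window or supply more regions"
        )
    order = np.argsort(kept["mean_meth"].to_numpy(), kind="stable")
    H_sorted = kept["H"].to_numpy()[order]
    trend = rolling_centered(H_sorted, window, np.median, min_half=min_half)
    H_norm = np.empty(len(kept))
    H_norm[order] = H_sorted - trend
    kept["H_norm"] = H_norm
    return kept


def delta_het_zscore(
    young_records: pd.DataFrame,
    old_records: pd.DataFrame,
    window: int = 100,
) -> pd.DataFrame:
    """Windowed Z-scores of old-young heterogeneity differences.

    d = H_norm(old) - H_norm(young) per region; regions are ordered by the
    mean of the two H_norm values and each d is standardised against the
    sliding window of ~``window`` neighbouring regions.  Returns a table
    with H_norm_young, H_norm_old, delta_H, mean_H_norm and delta_H_z.
    """
    unmatched = young_records.index.symmetric_difference(old_records.index)
    if len(unmatched):
        raise ValueError(f"unmatched regions between ages: {list(unmatched[:5])} ...")
    idx = young_records.index
    hy = young_records["H_norm"].to_numpy()
    ho = old_records.loc[idx, "H_norm"].to_numpy()
    d = ho - hy
    centre = (hy + ho) / 2.0
    z = sliding_zscore(d, centre, window=window)
    out = pd.DataFrame(
        {
            "H_norm_young": hy,
            "H_norm_old": ho,
            "delta_H": d,
            "mean_H_norm": centre,
            "delta_H_z": z,
        },
        index=idx,
    )
    return out


def _check_entropy_bits(p: Sequence[float]) -> float:  # pragma: no cover
    """Tiny reference used in doctests/debugging; not part of the API."""
    return -sum(x * math.log2(x) for x in p if x > 0)
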