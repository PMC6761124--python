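"""Cell-level quality control and coverage-equalising down-sampling.

Default thresholds: RNA cells need >= 1000 detected genes, >= 1e5 reads
mapped to nuclear genes and < 10% mitochondrial reads; methylome cells need
>= 1e6 paired-end alignments and >= 5e5 covered CpG sites.  Boundary
semantics are strict on the failing side ("less than" fails), so a cell at
exactly the threshold passes.

To remove depth and cohort-size biases before heterogeneity scoring, the
methylomes are down-sampled to a fixed number of read units per cell and a
fixed number of cells per individual.  A "read unit" is one counted read at
one CpG (read-level records are not retained after alignment); units are
drawn without replacement so the expected per-site methylated fraction is
preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import CellMethylome, CpGCall, ExpressionMatrix

__all__ = ["CellQCReport", "rna_cell_qc", "meth_cell_qc", "downsample_cells"]


@dataclass
class CellQCReport:
    """Outcome of the quality rules for one cell in one modality."""

    cell_id: str
    modality: str  # "rna" | "meth"
    metrics: dict[str, float] = field(default_factory=dict)
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def rna_cell_qc(
    matrix: ExpressionMatrix,
    min_genes: int = 1000,
    min_reads: float = 1e5,
    max_mito: float = 0.10,
) -> list[CellQCReport]:
    """Apply the RNA cell filters.

    A cell passes iff it detects >= ``min_genes`` genes, has >= ``min_reads``
    reads mapped to nuclear genes and < ``max_mito`` mitochondrial fraction.
    If the mitochondrial fraction is absent that rule is skipped with a
    warning recorded in the report metrics.
    """
    reports = []
    for cell in matrix.cell_ids:
        n_genes = int(matrix.n_genes_detected[cell])
        mapped = float(matrix.mapped_total[cell])
        metrics = {"n_genes_detected": n_genes, "mapped_total": mapped}
        reasons = []
        if n_genes < min_genes:
            reasons.append("few_genes")
        if mapped < min_reads:
            reasons.append("few_reads")
        if matrix.mito_fraction is None or np.isnan(matrix.mito_fraction[cell]):
            metrics["mito_rule_skipped"] = 1.0
            warnings.warn(
                f"{cell}: mito_fraction missing, mitochondrial rule skipped",
                stacklevel=2,
            )
        else:
            mito = float(matrix.mito_fraction[cell])
            metrics["mito_fraction"] = mito
            if not mito < max_mito:
                reasons.append("high_mito")
        reports.append(CellQCReport(cell, "rna", metrics, reasons))
    return reports


def meth_cell_qc(
    cells: Sequence[CellMethylome],
    min_alignments: float = 1e6,
    min_cpg: float = 5e5,
) -> list[CellQCReport]:
    """Apply the methylome cell filters (alignments and covered CpGs)."""
    reports = []
    for cell in cells:
        metrics = {
            "n_alignments": float(cell.n_alignments),
            "n_cpg_covered": float(cell.n_sites),
        }
        reasons = []
        if cell.n_alignments < min_alignments:
            reasons.append("few_alignments")
        if cell.n_sites < min_cpg:
            reasons.append("few_cpgs")
        reports.append(CellQCReport(cell.cell_id, "meth", metrics, reasons))
    return reports


def _subsample_cell(
    cell: CellMethylome, n_reads: int, rng: np.random.Generator
) -> CellMethylome:
    """Draw ``n_reads`` read units without replacement from one cell."""
    meth = np.array([c.n_meth for c in cell.calls], dtype=np.int64)
    unmeth = np.array([c.n_unmeth for c in cell.calls], dtype=np.int64)
    total = int(meth.sum() + unmeth.sum())
    if total < n_reads:
        raise ValueError(
            f"{cell.cell_id}: only {total} read units, cannot subsample {n_reads}"
        )
    if total == n_reads:
        return cell
    colors = np.concatenate([meth, unmeth])
    drawn = rng.multivariate_hypergeometric(colors, n_reads)
    new_meth = drawn[: meth.size]
    new_unmeth = drawn[meth.size:]
    calls = [
        CpGCall(c.chrom, c.pos, int(m), int(u))
        for c, m, u in zip(cell.calls, new_meth, new_unmeth)
        if m + u > 0
    ]
    return replace(cell, calls=calls)


def downsample_cells(
    cells: Sequence[CellMethylome],
    n_reads: int,
    n_cells: int,
    seed: int = 0,
) -> list[CellMethylome]:
    """Equalise coverage: ``n_reads`` units per cell, ``n_cells`` per individual.

    Cells are grouped by individual; ``n_cells`` are chosen at random per
    individual and each is down-sampled to exactly ``n_reads`` read units.
    Deterministic given ``seed``.  Raises if any individual has fewer than
    ``n_cells`` cells.
    """
    rng = np.random.default_rng(seed)
    by_individual: dict[str, list[CellMethylome]] = {}
    for cell in cells:
        by_individual.setdefault(cell.individual_id, []).append(cell)

    short = {
        ind: len(group)
        for ind, group in by_individual.items()
        if len(group) < n_cells
    }
    if short:
        raise ValueError(
            f"individuals with fewer than {n_cells} cells: {short}"
        )

    out: list[CellMethylome] = []
    for ind in sorted(by_individual):
        group = sorted(by_individual[ind], key=lambda c: c.cell_id)
        chosen = rng.choice(len(group), size=n_cells, replace=False)
        for i in sorted(chosen):
            out.append(_subsample_cell(group[i], n_reads, rng))
    return out
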