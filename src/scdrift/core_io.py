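"""Core containers and I/O: methylation call files, regions, count matrices.

Coordinate conventions
----------------------
Per-cell CpG call files follow the Bismark ``.cov`` dialect: 1-based CpG
positions, one line per site with methylated / unmethylated read counts
(an optional percent column between position and counts is tolerated).
Region files are BED-style, 0-based half-open.  The two conventions meet
only inside :func:`build_region_matrix`, which converts positions once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGCall",
    "CellMethylome",
    "Region",
    "RegionCallMatrix",
    "ExpressionMatrix",
    "read_cell_coverage",
    "write_cell_coverage",
    "read_regions_bed",
    "read_sample_sheet",
    "read_counts_tsv",
    "build_region_matrix",
    "pseudobulk",
]


@dataclass(frozen=True)
class CpGCall:
    """Methylation read counts observed at a single CpG position in one cell."""

    chrom: str
    pos: int  # 1-based
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"CpG position must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative methylation call counts")
        if self.n_meth + self.n_unmeth < 1:
            raise ValueError("a CpG call needs at least one observed read")

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def meth_fraction(self) -> float:
        return self.n_meth / self.depth


@dataclass
class CellMethylome:
    """All CpG calls for one cell (or a pseudobulk of cells) plus metadata.

    ``calls`` are kept sorted by (chrom, pos); duplicate positions are merged
    by summing counts at construction time by the readers, not here.
    """

    cell_id: str
    individual_id: str
    age_group: str  # "young" | "old"
    age_weeks: float
    calls: list[CpGCall] = field(default_factory=list)
    n_alignments: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    @property
    def total_read_units(self) -> int:
        """Total counted reads across all sites (the down-sampling unit)."""
        return sum(c.depth for c in self.calls)

    def sorted(self) -> "CellMethylome":
        return replace(self, calls=sorted(self.calls, key=lambda c: (c.chrom, c.pos)))


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, with a free-form class label."""

    chrom: str
    start: int
    end: int
    region_id: str
    region_class: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")


@dataclass
class RegionCallMatrix:
    """Cells x CpG-sites binary methylation states for one region.

    ``states`` is a float array with entries in {0.0, 1.0, NaN}; NaN marks a
    site not covered in that cell.
    """

    region_id: str
    cell_ids: list[str]
    site_positions: list[int]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.cell_ids), len(self.site_positions)):
            raise ValueError("states shape does not match cell/site labels")
        finite = self.states[np.isfinite(self.states)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("non-missing entries must be 0 or 1")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


@dataclass
class ExpressionMatrix:
    """Genes x cells raw counts with the per-cell totals used for RPM.

    ``mapped_total`` is reads mapped to the transcriptome per cell; it may
    exceed the column sum of ``counts`` (reads assigned outside the gene set).
    """

    counts: pd.DataFrame  # genes x cells, non-negative integers
    mapped_total: pd.Series  # per cell, > 0
    mito_fraction: pd.Series | None = None  # per cell, in [0, 1]
    n_genes_detected: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.mapped_total = self.mapped_total.reindex(self.counts.columns)
        if (self.mapped_total <= 0).any() or self.mapped_total.isna().any():
            raise ValueError("every cell needs a positive mapped-read total")
        if self.n_genes_detected is None:
            self.n_genes_detected = (self.counts > 0).sum(axis=0)
        if self.mito_fraction is not None:
            self.mito_fraction = self.mito_fraction.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cell_coverage(
    path: str | Path,
    *,
    cell_id: str | None = None,
    individual_id: str = "",
    age_group: str = "",
    age_weeks: float = float("nan"),
    n_alignments: int = 0,
    merge_strands: bool = False,
) -> CellMethylome:
    """Read a Bismark-coverage-style TSV into a :class:`CellMethylome`.

    Accepts 4 columns (chrom, pos, n_meth, n_unmeth) or 5 with a percent
    column in third place.  Lines for the same position are merged by summing
    counts.  With ``merge_strands=True``, calls at ``pos`` and ``pos + 1``
    are collapsed onto ``pos`` (for inputs where the two strands of a CpG
    were reported separately).
    """
    path = Path(path)
    raw: dict[tuple[str, int], list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                chrom = fields[0]
                pos = int(fields[1])
                if len(fields) >= 5:
                    n_meth, n_unmeth = int(fields[3]), int(fields[4])
                elif len(fields) == 4:
                    n_meth, n_unmeth = int(fields[2]), int(fields[3])
                else:
                    raise ValueError("expected 4 or 5 columns")
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed coverage line {lineno}: {line!r}"
                ) from exc
            key = (chrom, pos)
            if key in raw:
                raw[key][0] += n_meth
                raw[key][1] += n_unmeth
            else:
                raw[key] = [n_meth, n_unmeth]

    if merge_strands:
        merged: dict[tuple[str, int], list[int]] = {}
        for (chrom, pos), (m, u) in sorted(raw.items()):
            if (chrom, pos - 1) in merged:
                merged[(chrom, pos - 1)][0] += m
                merged[(chrom, pos - 1)][1] += u
            else:
                merged[(chrom, pos)] = [m, u]
        raw = merged

    calls = [
        CpGCall(chrom, pos, m, u)
        for (chrom, pos), (m, u) in sorted(raw.items())
    ]
    if not calls:
        warnings.warn(f"{path}: empty coverage file", stacklevel=2)
    return CellMethylome(
        cell_id=cell_id or path.stem,
        individual_id=individual_id,
        age_group=age_group,
        age_weeks=age_weeks,
        calls=calls,
        n_alignments=n_alignments,
    )


def write_cell_coverage(methylome: CellMethylome, path: str | Path) -> None:
    """Write calls back out in 5-column Bismark coverage format."""
    with open(path, "w") as fh:
        for c in sorted(methylome.calls, key=lambda c: (c.chrom, c.pos)):
            pct = 100.0 * c.meth_fraction
            fh.write(f"{c.chrom}\t{c.pos}\t{pct:.6g}\t{c.n_meth}\t{c.n_unmeth}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    """Read BED3+ regions; column 4 is the region id, column 5 the class."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: BED line {lineno} has <3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            region_id = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            region_class = fields[4] if len(fields) > 4 else ""
            regions.append(Region(chrom, start, end, region_id, region_class))
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate region ids")
    return regions


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the TSV sample sheet (cell_id, individual, age_group, ...)."""
    sheet = pd.read_csv(path, sep="\t")
    if "cell_id" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet needs a cell_id column")
    return sheet.set_index("cell_id")


def read_counts_tsv(
    counts_path: str | Path, sample_sheet: pd.DataFrame
) -> ExpressionMatrix:
    """Read a genes-x-cells count TSV and join per-cell totals from the sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    missing = [c for c in counts.columns if c not in sample_sheet.index]
    if missing:
        raise ValueError(f"cells absent from sample sheet: {missing[:5]} ...")
    meta = sample_sheet.loc[counts.columns]
    mito = meta["mito_fraction"] if "mito_fraction" in meta.columns else None
    return ExpressionMatrix(
        counts=counts,
        mapped_total=meta["mapped_total"].astype(float),
        mito_fraction=mito,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_region_matrix(
    cells: Sequence[CellMethylome],
    region: Region,
    binarise_threshold: float = 0.5,
) -> RegionCallMatrix:
    """Assemble the cells x CpG-sites binary state matrix for one region.

    A site column exists for every CpG position covered by at least one cell
    whose 0-based coordinate falls in ``[start, end)``.  Per entry the
    methylated read fraction is binarised: 1 if ``fraction >= threshold``
    (round half up at the default 0.5), else 0; uncovered sites are missing.
    """
    if not cells:
        raise ValueError("build_region_matrix needs at least one cell")
    if not 0.0 < binarise_threshold < 1.0:
        raise ValueError("binarise_threshold must be in (0, 1)")

    per_cell: list[dict[int, float]] = []
    site_set: set[int] = set()
    for cell in cells:
        covered: dict[int, float] = {}
        for c in cell.calls:
            # 1-based call position -> 0-based genomic coordinate
            if c.chrom == region.chrom and region.start <= c.pos - 1 < region.end:
                covered[c.pos] = c.meth_fraction
        per_cell.append(covered)
        site_set.update(covered)

    positions = sorted(site_set)
    states = np.full((len(cells), len(positions)), np.nan)
    col = {p: j for j, p in enumerate(positions)}
    for i, covered in enumerate(per_cell):
        for pos, frac in covered.items():
            states[i, col[pos]] = 1.0 if frac >= binarise_threshold else 0.0

    return RegionCallMatrix(
        region_id=region.region_id,
        cell_ids=[c.cell_id for c in cells],
        site_positions=positions,
        states=states,
    )


def pseudobulk(
    cells: Iterable[CellMethylome],
    *,
    sample_id: str | None = None,
    allow_multiple_individuals: bool = False,
) -> CellMethylome:
    """Aggregate cells by summing methylation calls per CpG position.

    The result behaves like one deeply covered sample; age metadata are
    inherited from the (single) individual unless mixing is explicitly
    allowed, in which case they are taken from the first cell.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("pseudobulk needs at least one cell")
    individuals = {c.individual_id for c in cells}
    if len(individuals) > 1 and not allow_multiple_individuals:
        raise ValueError(
            f"cells span individuals {sorted(individuals)}; "
            "pass allow_multiple_individuals=True to override"
        )

    acc: dict[tuple[str, int], list[int]] = {}
    for cell in cells:
        for c in cell.calls:
            key = (c.chrom, c.pos)
            if key in acc:
                acc[key][0] += c.n_meth
                acc[key][1] += c.n_unmeth
            else:
                acc[key] = [c.n_meth, c.n_unmeth]
    calls = [
        CpGCall(chrom, pos, m, u) for (chrom, pos), (m, u) in sorted(acc.items())
    ]
    first = cells[0]
    return CellMethylome(
        cell_id=sample_id or f"pseudobulk_{first.individual_id}",
        individual_id=first.individual_id,
        age_group=first.age_group,
        age_weeks=first.age_weeks,
        calls=calls,
        n_alignments=sum(c.n_alignments for c in cells),
    )
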