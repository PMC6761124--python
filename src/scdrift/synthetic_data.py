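"""Generators for synthetic scM&T-seq-like data.

Every downstream stage of the pipeline is exercisable on data from this
module.  Three generative models are provided:

* **Methylomes** (:func:`simulate_region`, :func:`simulate_cohorts`) — a
  template/stochastic mixture: each region has a shared binary template per
  CpG drawn at the region's mean methylation, and each cell copies the
  template or, with probability ``het_level``, resamples the site
  independently.  ``het_level`` therefore maps monotonically to expected
  pairwise disagreement while the mean methylation stays fixed — the
  property the mean-methylation normalisation assumes.  Missingness is
  MCAR (missing completely at random).
* **Transcriptomes** (:func:`simulate_expression`) — negative-binomial
  counts with per-gene overdispersion (var = mu + phi mu^2) thinned by a
  mean-dependent logistic detection (dropout) model.
* **Clock training sets** (:func:`simulate_clock_data`) — pseudo-bulk
  methylation fractions where a subset of causal sites drifts linearly with
  age, observed through binomial sampling at a fixed coverage depth.

All generators are pure functions of their spec: the same seed yields
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import CellMethylome, CpGCall, Region, RegionCallMatrix

__all__ = [
    "SimMethRegionSpec",
    "SimExprSpec",
    "SimClockSpec",
    "simulate_region",
    "simulate_cohorts",
    "simulate_expression",
    "simulate_clock_data",
]


def _stable_hash(key: object) -> int:
    """Process-independent 31-bit hash of a substream label."""
    return zlib.crc32(repr(key).encode()) % (2**31)


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Named substream of the global seed: independent per (seed, key)."""
    ss = np.random.SeedSequence([seed, *(_stable_hash(k) for k in key)])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimMethRegionSpec:
    """Generative parameters for one simulated methylation region."""

    n_cells: int = 35
    n_cpgs: int = 30
    mean_meth: float = 0.5
    het_level: float = 0.5  # mixing weight of the cell-independent component
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_meth <= 1.0):
            raise ValueError("mean_meth must be in [0, 1]")
        if not (0.0 <= self.het_level <= 1.0):
            raise ValueError("het_level must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_cells < 1 or self.n_cpgs < 1:
            raise ValueError("n_cells and n_cpgs must be positive")


@dataclass(frozen=True)
class SimExprSpec:
    """Generative parameters for a synthetic count matrix.

    ``mean_grid`` supplies the pool of per-gene expected counts; ``dispersion``
    is the NB overdispersion phi (var = mu + phi mu^2), scalar or per gene.
    ``dropout_logit_params`` (a, b) give detection probability
    sigmoid(a + b log(mu)); large ``a`` disables dropout.
    """

    n_genes: int = 2000
    n_cells: int = 200
    mean_grid: tuple[float, ...] = (5.0, 20.0, 80.0, 320.0)
    dispersion: float | tuple[float, ...] = 0.1
    dropout_logit_params: tuple[float, float] = (50.0, 0.0)
    mapped_offset: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp <= 0).any():
            raise ValueError("dispersion must be positive")
        if min(self.mean_grid) <= 0:
            raise ValueError("mean_grid must be positive")


@dataclass(frozen=True)
class SimClockSpec:
    """Generative parameters for a pseudo-bulk clock training corpus."""

    n_samples: int = 140
    ages_weeks: tuple[float, ...] = ()
    n_sites: int = 500
    n_causal: int = 50
    effect_size: float = 0.01  # methylation change per week at causal sites
    noise_sd: float = 0.02
    coverage_depth: int | None = 20  # None -> exact fractions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_sites:
            raise ValueError("n_causal must be <= n_sites")
        if self.ages_weeks and len(self.ages_weeks) != self.n_samples:
            raise ValueError("ages_weeks length must equal n_samples")


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def simulate_region(spec: SimMethRegionSpec, region_id: str = "sim_region") -> RegionCallMatrix:
    """Simulate one region's cells x sites binary state matrix.

    Template/stochastic mixture: a per-site template ~ Bernoulli(mean_meth)
    is shared by all cells; each cell x site entry copies the template or,
    with probability ``het_level``, is resampled ~ Bernoulli(mean_meth)
    independently.  Entries are then masked MCAR at ``missing_rate``.
    """
    rng = _rng(spec.seed, "region", region_id)
    template = rng.random(spec.n_cpgs) < spec.mean_meth
    resample = rng.random((spec.n_cells, spec.n_cpgs)) < spec.het_level
    independent = rng.random((spec.n_cells, spec.n_cpgs)) < spec.mean_meth
    states = np.where(resample, independent, template[None, :]).astype(float)
    if spec.missing_rate > 0:
        mask = rng.random((spec.n_cells, spec.n_cpgs)) < spec.missing_rate
        states[mask] = np.nan
    return RegionCallMatrix(
        region_id=region_id,
        cell_ids=[f"cell_{i:03d}" for i in range(spec.n_cells)],
        site_positions=list(range(1, spec.n_cpgs + 1)),
        states=states,
    )


def _matrix_to_calls(
    matrix: RegionCallMatrix, chrom: str, offset: int, spacing: int = 10
) -> list[list[CpGCall]]:
    """Per-cell call lists for one simulated region placed on a chromosome."""
    per_cell: list[list[CpGCall]] = []
    positions = [offset + spacing * j for j in range(matrix.n_sites)]
    for i in range(matrix.n_cells):
        calls = []
        for j, pos in enumerate(positions):
            s = matrix.states[i, j]
            if np.isnan(s):
                continue
            calls.append(CpGCall(chrom, pos, int(s), 1 - int(s)))
        per_cell.append(calls)
    return per_cell


def simulate_cohorts(
    young_specs: Mapping[str, SimMethRegionSpec],
    old_specs: Mapping[str, SimMethRegionSpec],
    n_regions_per_class: int | Mapping[str, int] = 30,
    *,
    young_age_weeks: float = 6.0,
    old_age_weeks: float = 115.0,
    site_spacing: int = 10,
    region_gap: int = 1000,
) -> tuple[list[CellMethylome], list[CellMethylome], list[Region]]:
    """Build matched young/old single-cell methylome cohorts.

    ``young_specs`` / ``old_specs`` map a region-class label (e.g. a
    LINE-1-like class gaining methylation and losing heterogeneity, or an
    H3K27me3-like class gaining heterogeneity) to the per-region generative
    spec for that age.  The same classes, region counts and cell counts must
    appear in both ages; regions are laid out on one synthetic chromosome.
    """
    if set(young_specs) != set(old_specs):
        raise ValueError("young and old cohorts must share region classes")
    classes = sorted(young_specs)
    n_cells = {young_specs[c].n_cells for c in classes} | {
        old_specs[c].n_cells for c in classes
    }
    if len(n_cells) != 1:
        raise ValueError("all specs within a cohort pair must share n_cells")
    n_cells = n_cells.pop()

    def n_regions(cls: str) -> int:
        if isinstance(n_regions_per_class, Mapping):
            return n_regions_per_class[cls]
        return n_regions_per_class

    chrom = "chrS"
    regions: list[Region] = []
    young_calls: list[list[CpGCall]] = [[] for _ in range(n_cells)]
    old_calls: list[list[CpGCall]] = [[] for _ in range(n_cells)]
    offset = 1
    for cls in classes:
        for r in range(n_regions(cls)):
            rid = f"{cls}_{r:04d}"
            y_spec = replace(young_specs[cls], seed=_derive_seed(young_specs[cls].seed, rid))
            o_spec = replace(old_specs[cls], seed=_derive_seed(old_specs[cls].seed, rid))
            y_mat = simulate_region(y_spec, region_id=rid)
            o_mat = simulate_region(o_spec, region_id=rid)
            n_cpgs = y_mat.n_sites
            start0 = offset - 1  # BED 0-based
            end0 = start0 + site_spacing * n_cpgs
            regions.append(Region(chrom, start0, end0, rid, cls))
            for i, calls in enumerate(_matrix_to_calls(y_mat, chrom, offset, site_spacing)):
                young_calls[i].extend(calls)
            for i, calls in enumerate(_matrix_to_calls(o_mat, chrom, offset, site_spacing)):
                old_calls[i].extend(calls)
            offset = end0 + region_gap + 1

    def cohort(calls_per_cell, group, age, individual):
        return [
            CellMethylome(
                cell_id=f"{group}_{i:03d}",
                individual_id=individual,
                age_group=group,
                age_weeks=age,
                calls=calls,
                n_alignments=len(calls),
            )
            for i, calls in enumerate(calls_per_cell)
        ]

    cells_young = cohort(young_calls, "young", young_age_weeks, "young_1")
    cells_old = cohort(old_calls, "old", old_age_weeks, "old_1")
    return cells_young, cells_old, regions


def _derive_seed(seed: int, key: str) -> int:
    return int(
        np.random.SeedSequence([seed, _stable_hash(key)]).generate_state(1)[0] % (2**31)
    )


# ---------------------------------------------------------------------------
# transcriptomes
# ---------------------------------------------------------------------------

def simulate_expression(spec: SimExprSpec):
    """Simulate a genes x cells count matrix with NB noise and dropout.

    Per-gene expected counts are drawn from ``mean_grid``; counts are
    negative binomial with var = mu + phi mu^2 and are thinned gene-wise by
    Bernoulli detection with probability logistic in log(mu).  The per-cell
    mapped totals are the column sums plus a fixed offset (reads mapped
    outside the gene set).  Returns an :class:`~scdrift.core_io.ExpressionMatrix`.
    """
    from .core_io import ExpressionMatrix

    rng = _rng(spec.seed, "expression")
    means = rng.choice(np.asarray(spec.mean_grid, dtype=float), size=spec.n_genes)
    disp = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.dispersion, dtype=float)), (spec.n_genes,)
    ).copy()

    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    poisson_like = disp < 1e-8
    if poisson_like.any():
        counts[poisson_like] = rng.poisson(
            means[poisson_like, None], size=(poisson_like.sum(), spec.n_cells)
        )
    nb = ~poisson_like
    if nb.any():
        r = 1.0 / disp[nb]
        p = r[:, None] / (r[:, None] + means[nb, None])
        counts[nb] = rng.negative_binomial(
            r[:, None], p, size=(int(nb.sum()), spec.n_cells)
        )

    a, b = spec.dropout_logit_params
    detect_p = expit(a + b * np.log(means))
    detected = rng.random((spec.n_genes, spec.n_cells)) < detect_p[:, None]
    counts = counts * detected

    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    cell_ids = [f"cell_{j:04d}" for j in range(spec.n_cells)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cell_ids)
    mapped_total = counts_df.sum(axis=0).astype(float) + spec.mapped_offset
    mito = pd.Series(0.02, index=cell_ids)
    return ExpressionMatrix(counts=counts_df, mapped_total=mapped_total, mito_fraction=mito)


# ---------------------------------------------------------------------------
# clock training data
# ---------------------------------------------------------------------------

def simulate_clock_data(spec: SimClockSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a pseudo-bulk clock training matrix and sample ages.

    Causal sites: methylation = clip(base + effect_size * age + N(0, noise_sd));
    the remaining sites are age-independent.  With a finite
    ``coverage_depth`` the observed fraction is Binomial(depth, p) / depth.
    Returns (samples x sites DataFrame of observed fractions, ages Series).
    """
    rng = _rng(spec.seed, "clock")
    if spec.ages_weeks:
        ages = np.asarray(spec.ages_weeks, dtype=float)
    else:
        ages = rng.uniform(4.0, 40.0, size=spec.n_samples)

    causal_idx = rng.choice(spec.n_sites, size=spec.n_causal, replace=False)
    base = rng.uniform(0.05, 0.95, size=spec.n_sites)
    signs = rng.choice([-1.0, 1.0], size=spec.n_causal)
    # choose causal baselines so the linear trajectory stays inside [0, 1]
    span = spec.effect_size * float(ages.max())
    lo = np.where(signs > 0, 0.02, min(0.98, 0.02 + span))
    hi = np.where(signs > 0, max(0.02, 0.98 - span), 0.98)
    base[causal_idx] = lo + rng.random(spec.n_causal) * np.maximum(hi - lo, 0.0)

    p = np.tile(base, (spec.n_samples, 1))
    p[:, causal_idx] = base[causal_idx][None, :] + signs[None, :] * (
        spec.effect_size * ages[:, None]
    ) - signs[None, :] * spec.effect_size * float(ages.min())
    if spec.noise_sd > 0:
        p = p + rng.normal(0.0, spec.noise_sd, size=p.shape)
    p = np.clip(p, 0.0, 1.0)

    if spec.coverage_depth is None:
        obs = p
    else:
        obs = rng.binomial(spec.coverage_depth, p) / spec.coverage_depth

    sites = [f"site_{i:05d}" for i in range(spec.n_sites)]
    samples = [f"sample_{i:04d}" for i in range(spec.n_samples)]
    frame = pd.DataFrame(obs, index=samples, columns=sites)
    frame.attrs["causal_sites"] = [sites[i] for i in sorted(causal_idx)]
    return frame, pd.Series(ages, index=samples, name="age_weeks")
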