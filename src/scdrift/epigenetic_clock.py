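"""Binned-methylation epigenetic age predictor with permutation uncertainty.

The clock is a penalised (elastic-net) linear regression of chronological
age in weeks on per-site methylation fractions.  Before modelling, site
fractions are binned to multiples of 20% so that no read-depth information
leaks into the methylation values.  The CpG panel is fixed by a three-stage
coverage filter: sites present in at least 70% of training samples, then
covered at >= 5x in every target pseudobulk, then training samples without
100% coverage of the surviving panel are dropped.

Sensitivity of the prediction to single-cell composition is quantified by
repeatedly dropping a small fraction of cells, re-aggregating, and keeping
only permutations in which every clock site retains >= 4x coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV

from .core_io import CellMethylome, pseudobulk

__all__ = [
    "ClockSitePanel",
    "ClockModel",
    "AgePrediction",
    "methylome_site_table",
    "select_sites",
    "bin_methylation",
    "fit_clock",
    "predict_age",
    "permutation_ages",
]


@dataclass
class ClockSitePanel:
    """The CpG sites a fitted clock reads, with coverage provenance."""

    sites: list[str]  # "chrom:pos" or free-form site labels
    training_coverage: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ClockModel:
    """Linear age model over binned methylation values."""

    panel: ClockSitePanel
    coefficients: pd.Series  # indexed by panel site
    intercept: float
    bin_width: float = 0.2
    n_training_samples: int = 0
    training_ages: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "sites": self.panel.sites,
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "bin_width": self.bin_width,
            "n_training_samples": self.n_training_samples,
            "training_ages": self.training_ages,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        doc = json.loads(Path(path).read_text())
        panel = ClockSitePanel(sites=doc["sites"])
        return cls(
            panel=panel,
            coefficients=pd.Series(doc["coefficients"]).reindex(doc["sites"]),
            intercept=doc["intercept"],
            bin_width=doc["bin_width"],
            n_training_samples=doc["n_training_samples"],
            training_ages=doc["training_ages"],
        )


@dataclass(frozen=True)
class AgePrediction:
    sample_id: str
    predicted_age_weeks: float
    n_sites_used: int


def methylome_site_table(methylome: CellMethylome) -> pd.DataFrame:
    """Site table ("chrom:pos" index) with n_meth, depth and fraction."""
    rows = {
        f"{c.chrom}:{c.pos}": (c.n_meth, c.depth, c.meth_fraction)
        for c in methylome.calls
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_meth", "depth", "fraction"]
    ).rename_axis("site")


def select_sites(
    training: pd.DataFrame,
    target_depths: pd.DataFrame,
    min_sample_frac: float = 0.70,
    min_target_depth: int = 5,
) -> tuple[ClockSitePanel, list[str]]:
    """Three-stage coverage filter fixing the clock site panel.

    ``training`` is samples x sites methylation fractions with NaN for
    uncovered sites; ``target_depths`` is targets x sites read depths.
    Stage 1 keeps sites covered in >= ``min_sample_frac`` of training
    samples; stage 2 removes sites not covered ``min_target_depth``-fold in
    *every* target; stage 3 removes training samples lacking 100% coverage
    of the surviving panel.  Returns the panel and retained sample ids.
    """
    covered = training.notna()
    frac = covered.mean(axis=0)
    stage1 = frac.index[frac >= min_sample_frac]

    depths = target_depths.reindex(columns=stage1).fillna(0)
    deep_everywhere = (depths >= min_target_depth).all(axis=0)
    panel_sites = [s for s in stage1 if deep_everywhere[s]]
    if not panel_sites:
        raise ValueError(
            "no site survives the coverage filters; relax min_sample_frac "
            "or min_target_depth"
        )

    complete = covered[panel_sites].all(axis=1)
    retained = list(training.index[complete])
    if not retained:
        raise ValueError("no training sample fully covers the selected panel")
    provenance = covered[panel_sites].sum(axis=0).astype(int).to_dict()
    return ClockSitePanel(sites=panel_sites, training_coverage=provenance), retained


def bin_methylation(values, bin_width: float = 0.2):
    """Round methylation fractions to the nearest multiple of ``bin_width``.

    Half-way values round up, so the output grid for the default width is
    {0, 0.2, 0.4, 0.6, 0.8, 1}.  Binning discards read-depth information
    from the methylation values.  Accepts scalars or arrays; inputs must be
    in [0, 1].
    """
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("methylation values must be in [0, 1]")
    n_bins = round(1.0 / bin_width)
    # small epsilon makes exact halves (which are not representable in
    # binary floating point for e.g. 0.3 / 0.2) round up deterministically
    binned = np.floor(arr * n_bins + 0.5 + 1e-9) / n_bins
    binned = np.clip(binned, 0.0, 1.0)
    return float(binned) if np.isscalar(values) else binned


def fit_clock(
    training: pd.DataFrame,
    ages: pd.Series,
    penalty_grid: Sequence[float] | None = None,
    l1_ratio: Sequence[float] = (0.1, 0.5, 0.9, 1.0),
    cv_folds: int = 10,
    seed: int = 0,
    bin_width: float = 0.2,
    prebinned: bool = False,
) -> ClockModel:
    """Fit the penalised linear age model on binned training methylation.

    ``training`` is samples x sites (complete, no NaN).  Values are binned
    to ``bin_width`` unless ``prebinned``.  An elastic net is selected by
    cross-validation over ``l1_ratio`` and an automatic (or supplied) alpha
    grid; deterministic given ``seed``.
    """
    ages = ages.reindex(training.index)
    if ages.isna().any():
        raise ValueError("every training sample needs an age")
    if ages.nunique() < 2:
        raise ValueError("training ages are constant; nothing to regress on")
    if training.isna().any().any():
        raise ValueError("training matrix must be complete over the panel")

    X = training.to_numpy(dtype=float)
    if not prebinned:
        X = bin_methylation(X, bin_width)
    y = ages.to_numpy(dtype=float)

    model = ElasticNetCV(
        l1_ratio=list(l1_ratio),
        alphas=100 if penalty_grid is None else list(penalty_grid),
        cv=min(cv_folds, len(y)),
        random_state=seed,
        max_iter=50_000,
    )
    model.fit(X, y)
    panel = ClockSitePanel(sites=list(training.columns))
    return ClockModel(
        panel=panel,
        coefficients=pd.Series(model.coef_, index=training.columns),
        intercept=float(model.intercept_),
        bin_width=bin_width,
        n_training_samples=len(y),
        training_ages=[float(a) for a in y],
    )


def predict_age(
    model: ClockModel,
    sample: pd.Series | CellMethylome,
    sample_id: str | None = None,
) -> AgePrediction:
    """Predict age in weeks for one (pseudobulk) sample.

    ``sample`` is a site -> methylation-fraction Series, or a
    :class:`CellMethylome` whose calls are keyed as "chrom:pos".  Values are
    binned with the model's bin width before the linear score.  Missing
    panel sites raise, naming them.
    """
    if isinstance(sample, CellMethylome):
        table = methylome_site_table(sample)
        sample_id = sample_id or sample.cell_id
        sample = table["fraction"]
    values = sample.reindex(model.panel.sites)
    missing = list(values.index[values.isna()])
    if missing:
        raise ValueError(f"sample lacks panel sites: {missing[:5]} ...")
    binned = bin_methylation(values.to_numpy(dtype=float), model.bin_width)
    age = float(model.intercept + binned @ model.coefficients.to_numpy())
    return AgePrediction(
        sample_id=sample_id or "sample",
        predicted_age_weeks=age,
        n_sites_used=len(model.panel),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def permutation_ages(
    model: ClockModel,
    cells: Sequence[CellMethylome],
    drop_frac: float = 0.05,
    n_perm: int = 100,
    min_site_depth: int = 4,
    seed: int = 0,
) -> list[AgePrediction]:
    """Cell-composition uncertainty of the age prediction.

    Each permutation drops ``round(drop_frac * n_cells)`` cells at random
    (round half up, at least one), pseudobulks the rest, and predicts age;
    permutations in which any panel site falls below ``min_site_depth``
    coverage are discarded, so the result may hold fewer than ``n_perm``
    predictions.  Deterministic given ``seed``.
    """
    cells = list(cells)
    individuals = {c.individual_id for c in cells}
    if len(individuals) != 1:
        raise ValueError("permutation_ages expects cells from one individual")
    n_drop = max(1, _round_half_up(drop_frac * len(cells)))
    if n_drop >= len(cells):
        raise ValueError("drop_frac removes every cell")

    rng = np.random.default_rng(seed)
    predictions: list[AgePrediction] = []
    for perm in range(n_perm):
        keep_idx = np.ones(len(cells), dtype=bool)
        keep_idx[rng.choice(len(cells), size=n_drop, replace=False)] = False
        bulk = pseudobulk(
            [c for c, k in zip(cells, keep_idx) if k],
            sample_id=f"perm_{perm:03d}",
        )
        table = methylome_site_table(bulk)
        depths = table["depth"].reindex(model.panel.sites).fillna(0)
        if (depths < min_site_depth).any():
            continue
        predictions.append(
            predict_age(model, table["fraction"], sample_id=f"perm_{perm:03d}")
        )
    if not predictions:
        raise ValueError(
            "every permutation fell below the per-site depth requirement "
            f"({min_site_depth}x); coverage is too shallow"
        )
    return predictions
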