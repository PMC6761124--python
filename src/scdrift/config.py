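"""Default analysis thresholds and YAML config loading.

Every threshold used by the pipeline stages has a default here and can be
overridden by a YAML file passed to the CLI (top-level keys matching the
names below).
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULTS: dict[str, object] = {
    # qc
    "rna_min_genes": 1000,
    "rna_min_reads": 1e5,
    "rna_max_mito": 0.10,
    "meth_min_alignments": 1e6,
    "meth_min_cpg": 5e5,
    "downsample_reads": 1_000_000,
    "downsample_cells": 35,
    # methylation heterogeneity
    "min_shared_sites": 4,
    "binarise_threshold": 0.5,
    "min_cpg_total": 20,
    "min_mean_cpg_per_cell": 2.0,
    "min_pairs": 100,
    "max_mean_cpg_diff": 10.0,
    "max_pairs_diff": 200.0,
    "het_norm_window": 1000,
    "meth_band": [0.05, 0.9],
    "delta_z_window": 100,
    # expression
    "dm_min_mean": 10.0,
    "dm_window": 100,
    "freq_flag_threshold": 0.15,
    "cohort_size": 10,
    "cohort_iterations": 1000,
    "similarity_min_cells": 5,
    "similarity_top_n": 200,
    # clock
    "clock_min_sample_frac": 0.70,
    "clock_min_target_depth": 5,
    "clock_bin_width": 0.2,
    "clock_drop_frac": 0.05,
    "clock_n_perm": 100,
    "clock_min_site_depth": 4,
    # integration
    "association_min_genes": 10,
    "delta_h_threshold": 0.3,
}


def load_config(path: str | Path | None = None) -> dict[str, object]:
    """Return the defaults, overlaid with a YAML file if given."""
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    return cfg
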