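"""Pipeline configuration: flat, sectioned, YAML round-trippable.

Defaults mirror the study parameters (10 arc-minute cells, Spearman rho
cutoff 0.75, ten equal-interval bias bins, 1,000 null AUC replicates,
cluster counts 2-30 selected on five 1,000-cell subsamples, NMDS with 100
starts, envfit at P < 0.001 with 999 permutations, Gi* on a 2x-coarsened
grid with |z| > 2), with a ``desk`` profile scaled down for minutes-scale
runs on the default synthetic world.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "dump_config", "config_hash",
           "desk_profile"]

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "n_lon": 40, "n_lat": 30, "n_predictors": 8, "n_species": 200,
        "smoothness": 5.0, "niche_breadth": 1.0,
        "prevalence_range": [0.05, 0.25], "k_regions": None,
        "turnover_sharpness": 5.0, "pool_overlap": 0.0, "n_correlated": 0,
        "effort": 5000, "bias_strength": 1.0,
    },
    "grid": {"resolution": 10.0},
    "occurrences": {"min_cells": 5},
    "predictors": {"rho_max": 0.75, "priority": None,
                   "bias_bins": 10, "bias_alpha": 0.05},
    "sdm": {"regularization_multiplier": 1.0, "background": None},
    "null_model": {"n_null": 1000},
    "stack": {"rule": None},
    "drivers": {"alpha_enter": 0.05},
    "regionalization": {"k_min": 2, "k_max": 30, "subsample_size": 1000,
                        "n_repeats": 5, "n_perm": 1000, "level": "species",
                        "criterion": "sum_p"},
    "ret": {"n_starts": 100, "n_perm": 999, "alpha": 0.001,
            "coarsen_factor": 2, "z_threshold": 2.0,
            "nmds_max_cells": 1000},
}


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def desk_profile() -> dict:
    """Scaled-down settings for the default synthetic world."""
    return {
        "null_model": {"n_null": 199},
        "regionalization": {"k_max": 8, "subsample_size": 300,
                            "n_repeats": 2, "n_perm": 99},
        "ret": {"n_starts": 4, "n_perm": 199, "alpha": 0.05,
                "nmds_max_cells": 400},
        "simulate": {"k_regions": 4},
    }


def load_config(path=None, overrides: dict | None = None,
                desk: bool = False) -> dict:
    """Defaults <- optional YAML file <- optional overrides."""
    cfg = DEFAULTS
    if desk:
        cfg = _merge(cfg, desk_profile())
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration (for resume-safety manifests)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
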