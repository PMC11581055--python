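"""Run configuration: nested defaults overridable from YAML.

Every numeric default of the pipeline lives here so that a single YAML file
can reconfigure a run without touching code.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Pipeline-wide defaults. Keys mirror the processing stages.
DEFAULTS: dict[str, Any] = {
    "scale_space": {
        "n_scales": 8,
        "step": 0.15,           # explicit-scheme time step (stable for <= 1/6)
        "steps_per_scale": 1,   # explicit iterations per scale increment
        "conductance_k": None,  # None -> 90th percentile of |grad| per triplet
        "conductance_form": "exponential",
    },
    "detector": {
        "type": "hessian_st",   # {moments, hessian_st, hessian_temporal}
        "kappa": 0.005,
        "sigma_i": 2.0,         # integration scale of the moments detector
        "tau_i": 1.0,
        "sigma": None,          # Hessian differentiation scale;
                                # None -> 0.8 * expected_radius
        "tau": 1.5,
        "min_strength_rel": 1e-4,
        "connectivity": 8,
    },
    "scale_selection": {
        "rule": "elbow_max_d2",
    },
    "motion": {
        "alpha": None,          # None -> (0.05 * intensity range)^2
        "rho": 2.0,
        "n_iters": 200,
        "n_warps": 3,
        "pyramid_levels": 1,
    },
    "segmentation": {
        "bandwidth_rel": 0.5,   # Parzen bandwidth = rel * expected cell radius
        "min_superpixel_px": 5,
        "connectivity": 4,
    },
    "detection": {
        "expected_radius": 6.0,
        "eps_percentile": 15.0,
        "min_pts": 10,
        "epochs": 200,
        "lr": 1e-2,
        "batch": 64,
        "momentum": 0.9,
        "seed": 0,
    },
    "refinement": {
        "n_iters": 50,
        "window": 7.0,
        "nu": None,             # None -> 0.2 * window^2
        "solidity_threshold": 0.85,
        "hmax": 1.0,
        "reinit_every": 1,
        "min_region_px": 9,      # drop post-refinement specks below this
        "area_factor": 1.7,      # cluster screen: area > factor * pi r^2
        "min_piece_px": None,    # merge back split slivers below this;
                                 # None -> 0.15 * pi * expected_radius^2
                                 # (false splits are caught by the valley
                                 # gate; this only sweeps watershed slivers)
        "valley_rel": 0.2,       # required relative intensity dip at a
                                 # split line (cell-cell necks are dark)
    },
    "tracking": {
        "reject_threshold": 0.1,
        "fallback_sigma_rel": 1.0,  # sigma = rel * expected_radius
        "max_daughters": 2,
    },
    "metrics": {
        "weights": {"ns": 5.0, "fn": 10.0, "fp": 1.0, "ed": 1.0, "ea": 1.5, "ec": 1.0},
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict[str, Any]:
    """Return a deep copy of the built-in defaults."""
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config and merge it over the defaults.

    Unknown keys are kept (forward compatible); missing keys fall back to
    :data:`DEFAULTS`. ``path=None`` returns the defaults.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    return _deep_merge(cfg, user)
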