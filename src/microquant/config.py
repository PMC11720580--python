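"""Run configuration: documented defaults, YAML loading, strict key checking.

Unknown keys are rejected (typos fail loudly); a YAML file overrides the
defaults, and CLI flags override the file.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "results",
    "strict": False,
    "synth": {
        "height": 256,
        "width": 256,
        "n_cells": 20,
        "radius_min": 5.0,
        "radius_max": 9.0,
        "peak_min": 400.0,
        "peak_max": 800.0,
        "eccentricity_min": 1.0,
        "eccentricity_max": 2.0,
        "background_base": 100.0,
        "gradient_amplitude": 30.0,
        "smoothness_scale": 64.0,
        "noise": "poisson",
        "noise_param": 0.0,
    },
    "preprocess": {
        "sigma_small": 1.0,
        # null -> derived as 4 x expected_cell_diameter
        "sigma_large": None,
        "expected_cell_diameter": 16.0,
        "background_mode": "mask_excluded",
        "despeckle_method": "gaussian",  # or "median"
        "subtract": False,
    },
    "segment": {
        "window_size": 31,
        "sensitivity": 0.10,
        "connectivity": 8,
        "min_area": 40,
        "max_area": 1500,
    },
    "tune": {
        "window_sizes": [15, 21, 27, 33, 41],
        "sensitivities": [0.02, 0.05, 0.10, 0.15, 0.20],
    },
    "quantify": {
        "variance_window": 31,
    },
    "morphology": {
        # smaller window for tubular structures
        "window_size": 15,
        "sensitivity": 0.10,
        "min_area": 10,
        "max_area": 100000,
        "crofton": True,
    },
    "flim": {
        "min_counts": 100.0,
        "fit_start": "peak",
        "rois_per_cell": 3,
        "cells": 6,
    },
    "ocr": {
        "strict_n": 6,
    },
}


def _check_unknown(user: dict, defaults: dict, prefix: str = "") -> None:
    for key, value in user.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {prefix + str(key)!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {prefix + str(key)!r} must be a mapping")
            _check_unknown(value, defaults[key], prefix=f"{prefix}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys rejected."""
    config = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _check_unknown(user, DEFAULTS)
        config = _merge(config, user)
    return config


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def effective_sigma_large(config: dict) -> float:
    pre = config["preprocess"]
    if pre["sigma_large"] is not None:
        return float(pre["sigma_large"])
    return 4.0 * float(pre["expected_cell_diameter"])
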