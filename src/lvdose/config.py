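"""Run configuration: YAML-backed nested defaults with strict key checking.

An empty (or absent) configuration is fully runnable; explicit overrides
are deep-merged over the defaults and unknown keys are rejected with the
list of valid keys.  One global seed deterministically derives independent
per-stage seeds by hashing the stage name, so stages are reproducible in
isolation.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "lvdose_out",
    "log_level": "INFO",
    "phantom": {
        "n_cases": 10,
        "grid_shape": [96, 96, 96],
        "grid_spacing_mm": 1.5,
        "wall_model": "volume-preserving",
        "random_orientation": True,
        "param_ranges": {
            "endo_short_axis_mm": [22.0, 30.0],
            "endo_long_axis_mm": [40.0, 50.0],
            "wall_radial_mm": [6.0, 10.0],
            "wall_long_mm": [5.0, 8.0],
            "es_long_scale": [0.84, 0.95],
            "target_ef_pct": [20.0, 70.0],
            "base_truncation_frac": [0.5, 0.5],
        },
    },
    "ct_sim": {
        "n_detectors": 192,
        "detector_pitch_mm": 1.0,
        "n_angles": 180,
        "mu_water_per_mm": 0.020,
        "tube_current_mA": 500.0,
        "I0_ref": 1.0e5,
        "electronic_noise_sd": 10.0,
        "doses_mA": [500.0, 100.0, 50.0, 25.0, 10.0],
    },
    "segmenter": {
        "base_channels": 8,
        "n_levels": 4,
        "residual_blocks_per_level": 2,
        "deep_supervision": True,
        "patch_size": [64, 64, 32],
        "learning_rate": 5.0e-4,
        "batch_size": 32,
        "epochs": 200,
        "draws_per_epoch": None,
        "rule_based_thresholds": [70.0, 225.0],
        "rule_based_smooth_sigma_vox": 1.0,
    },
    "views": {
        "sax_fractions": {"basal": 0.8, "middle": 0.5, "apical": 0.2},
        "long_axis_azimuth_deg": {"2CH": 0.0, "PLAX": 90.0},
        "pixel_spacing_mm": 1.0,
        "slab_thickness_mm": 3.0,
    },
    "metrics": {
        "n_wt_spokes": 16,
    },
    "study": {
        "threshold_metrics": ["ef", "gls", "cs_basal", "cs_middle", "cs_apical"],
        "threshold_tolerance_pp": 2.5,
        "grid_shape": [64, 64, 64],
        "grid_spacing_mm": 2.25,
        "scaled_geometry": {"n_detectors": 96, "detector_pitch_mm": 1.6, "n_angles": 96},
        "make_figures": False,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            valid = ", ".join(sorted(defaults))
            raise ConfigError(f"unknown configuration key {where!r}; valid keys here: {valid}")
        base = defaults[key]
        if isinstance(base, dict) and not _is_open_dict(path, key):
            if not isinstance(value, dict):
                raise ConfigError(f"{where!r} must be a mapping, got {type(value).__name__}")
            out[key] = _merge(base, value, where)
        else:
            if base is not None and value is not None and not _compatible(base, value):
                raise ConfigError(
                    f"type mismatch for {where!r}: expected {type(base).__name__}, "
                    f"got {type(value).__name__}"
                )
            out[key] = copy.deepcopy(value)
    return out


def _is_open_dict(path: str, key: str) -> bool:
    # leaf mappings whose keys are data (not schema): ranges and view maps
    return key in ("param_ranges", "sax_fractions", "long_axis_azimuth_deg", "scaled_geometry")


def _compatible(base, value) -> bool:
    if isinstance(base, bool) or isinstance(value, bool):
        return isinstance(base, bool) and isinstance(value, bool)
    if isinstance(base, (int, float)) and isinstance(value, (int, float)):
        return True
    if isinstance(base, (list, tuple)) and isinstance(value, (list, tuple)):
        return True
    return type(base) is type(value)


def load_config(path: str | None = None) -> dict:
    """Load the fully resolved run configuration (defaults + overrides)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return copy.deepcopy(DEFAULTS)
    if not isinstance(doc, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(doc).__name__}")
    return _merge(DEFAULTS, doc)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def dump_config(config: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2)
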