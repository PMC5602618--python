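"""Canonical default configuration for the whole pipeline.

Every unstated constant of the method lives here, in one place; a YAML file
with the same layout can override any subset (CLI flags override both). The
repository's ``config/defaults.yaml`` is generated from this dict
(``fundus-cdr defaults > config/defaults.yaml``).
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "profile": "high_quality",
    "seed": 0,
    "fou_width": 10.0,  # footprint-of-uncertainty width, gray levels
    "vessel": {
        "radius": 7,  # disk structuring element, px, at 512-px frame width
        "scale_with_width": True,
        "threshold_rule": "fixed",
        "fixed_threshold": 15.0,  # gray levels on the smoothed top-hat response
        "prefilter_sigma": 1.0,
        "inpaint_iterations": 100,
    },
    "de": {
        "population": 30,
        "generations": 100,
        "F": 0.5,
        "CR": 0.9,
    },
    "localize": {
        "k": 2,
        "roi_fraction": 0.25,  # ROI side as a fraction of image width
        "min_component_frac": 0.0005,  # localization floor, fraction of image area
    },
    "level_set": {
        "time_step": 1.0,
        "iterations": 300,
        "smoothing": 2,
        "sigma": 2.0,
        "balloon": 1.0,
        "tolerance": 1e-3,
        "alpha": 100.0,
        "threshold": "auto",  # balloon stalls below this edge-indicator level
    },
    "cup": {
        "min_spot": 50,  # bright spots below this pixel count are discarded
        "area_floor": 3000.0,  # px, quoted for the reference frame width
        "scale_area_floor": True,
        "reference_width": 2376,
        "closing_radius": 3,
        "bridge_radius": 6,  # vessel gap-bridging closing radius
        "enhance_percentiles": [1.0, 99.0],
        "hough_radius_rel": [0.15, 0.6],  # of the disc-equivalent radius
        "de_population": 30,
        "de_generations": 100,
        "area_test_after_hough": False,  # error conditions checked on the pre-fit candidate
    },
    "evaluate": {
        "cdr_threshold": 0.075,
        "analyses": ["hcdr", "vcdr", "final"],
        # optional per-parameter overrides of the data-driven mean-SD
        # thresholds, e.g. {disc_area: 8000.0, disc_centroid: 10.0}
        "thresholds": {},
    },
    "simulate": {
        "profile": "small",
        "n_images": 20,
        "noise_sigma": 8.0,
        "n_vessels": 4,
        "grader": {
            "n_graders": 6,
            "area_jitter_cv": 0.05,
            "centroid_jitter_sd": 2.0,
            "cdr_jitter_sd": 0.03,
            "outlier_rate": 0.0,
            "outlier_scale": 10.0,
        },
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursive dict merge; override wins leaf-by-leaf."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path:
        with open(path) as fh:
            cfg = merge_config(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = merge_config(cfg, overrides)
    return cfg


def dump_defaults() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=False)
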