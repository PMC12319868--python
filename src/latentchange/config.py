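"""Structured text configuration for the analysis pipeline."""

from __future__ import annotations

import copy
import hashlib

import yaml

from .builders import MeasurementSchema
from .preprocess import DEFAULT_RANGES

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results",
    "input_csv": None,          # if None, a synthetic cohort is generated
    "native_scale": False,      # input is on native scales -> run exclusions + scaling
    "n": 5000,                  # synthetic sample size
    "schema": MeasurementSchema().to_dict(),
    "ranges": {k: list(v) for k, v in DEFAULT_RANGES.items()},
    "grouping": "early_vs_nonearly",
    "invariance_levels": ["configural", "weak", "strong", "partial"],
    "stages": [
        "invariance",
        "lcsm",
        "multigroup_puberty",
        "multigroup_ses",
        "indicator_lcsms",
    ],
    "missingness": None,        # e.g. {"ct_t2_rate": .2, "indicator_t2_rate": .1}
    "structural_overrides": {},  # generator: label -> value
    "group_overrides": {},       # generator: group label -> {label: value}
    "bonferroni_family": None,   # default: number of tested structural paths
    "include_demographics": True,
}


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict) and key == "schema":
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path: str | None) -> dict:
    if path is None:
        return merge_config(None)
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
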