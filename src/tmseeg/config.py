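"""Pipeline configuration: a structured parameter tree with defaults.

Defaults follow the study protocol wherever it states a value (1–80 Hz
band-pass, 50 Hz notch, −1..+10 ms interpolation, 3000 permutations,
cluster threshold p < 0.025, 10-point run criterion, 23 wavelet
frequencies in 4–50 Hz at 3.5 cycles, integer band edges). The config
round-trips losslessly through YAML.
"""
from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "tmseeg_results",
    "simulation": {
        "n_real": 10,
        "n_sham": 10,
        "trials_per_block": 80,
        "sampling_rate": 1000.0,
        "epoch_window": [-1.0, 1.0],
        "between_subject_sd": 0.2,
        "modulation": {
            "cTBS": {"gain": 1.3, "window": [0.10, 0.20], "band_gain": {"alpha": 0.7}},
            "iTBS": {"gain": 0.7, "window": [0.10, 0.20], "band_gain": {"beta": 1.3}},
        },
        "affected_channels": ["FCz", "FC1", "Cz", "C3", "CP1", "CP5"],
    },
    "preprocess": {
        "stage_order": ["interpolate", "rereference", "bandpass", "notch",
                        "ica", "epoch", "reject"],
        "allow_reorder": False,
        "interpolation_window": [-0.001, 0.010],
        "band": [1.0, 80.0],
        "notch": 50.0,
        "run_ica": False,
        "rejection_threshold": 200.0,
    },
    "tep": {
        "threshold_p": 0.025,
        "n_perm": 3000,
        "tois": [
            ["P30", [0.010, 0.035]],
            ["N45", [0.035, 0.055]],
            ["P60", [0.055, 0.070]],
            ["N100", [0.070, 0.130]],
            ["P180", [0.130, 0.250]],
            ["N280", [0.250, 0.360]],
        ],
    },
    "lmfp": {
        "window": [-0.1, 0.5],
        "n_perm": 3000,
        "alpha": 0.025,
        "fdr_q": 0.05,
        "min_run": 10,
        "p_source": "permutation",
        "rois": {"M1": ["C3", "CP1", "CP5"], "PPC": ["P3", "P7"]},
    },
    "trsp": {
        "f_min": 4.0,
        "f_max": 50.0,
        "n_steps": 23,
        "cycles": 3.5,
        "spacing": "linear",
        "baseline": [-0.55, -0.15],
        "window": [0.010, 0.300],
        "bands": {"theta": [4.0, 6.0], "alpha": [7.0, 13.0],
                  "beta": [14.0, 30.0], "gamma": [31.0, 50.0]},
    },
}

_CANONICAL_STAGES = ["interpolate", "rereference", "bandpass", "notch", "ica",
                     "epoch", "reject"]


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


class PipelineConfig:
    """Validated parameter tree for :func:`tmseeg.pipeline.run_pipeline`."""

    def __init__(self, tree: Mapping[str, Any], merge_defaults: bool = True):
        self.tree = _deep_merge(DEFAULTS, tree) if merge_defaults else copy.deepcopy(dict(tree))
        self.validate()

    # -- access -----------------------------------------------------------
    def __getitem__(self, dotted: str) -> Any:
        node: Any = self.tree
        for part in dotted.split("."):
            node = node[part]
        return node

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PipelineConfig) and self.tree == other.tree

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        tree = self.tree
        for section in ("simulation", "preprocess", "tep", "lmfp", "trsp"):
            if section not in tree:
                raise ValueError(f"config missing section {section!r}")
        rois = tree["lmfp"].get("rois")
        if not rois:
            raise ValueError("config missing required lmfp.rois")
        for name, channels in rois.items():
            if len(channels) < 2:
                raise ValueError(f"ROI {name!r} needs >= 2 channels")
        order = tree["preprocess"].get("stage_order", _CANONICAL_STAGES)
        if list(order) != _CANONICAL_STAGES and not tree["preprocess"].get("allow_reorder"):
            raise ValueError(
                f"preprocess.stage_order {order} deviates from the canonical "
                f"{_CANONICAL_STAGES}; set preprocess.allow_reorder to override")
        band = tree["preprocess"]["band"]
        if not band[0] < band[1]:
            raise ValueError("preprocess.band must be (low, high) with low < high")
        if not 0 < tree["tep"]["threshold_p"] < 0.5:
            raise ValueError("tep.threshold_p must lie in (0, 0.5)")
        for key in ("n_real", "n_sham", "trials_per_block"):
            if tree["simulation"][key] < 0:
                raise ValueError(f"simulation.{key} must be non-negative")
        lo, hi = tree["trsp"]["baseline"]
        if hi > 0:
            raise ValueError("trsp.baseline must end before t = 0")

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.tree, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str, merge_defaults: bool = True) -> "PipelineConfig":
        return cls(yaml.safe_load(text) or {}, merge_defaults=merge_defaults)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, merge_defaults: bool = True) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"),
                             merge_defaults=merge_defaults)
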