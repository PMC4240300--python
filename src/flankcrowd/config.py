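"""YAML/JSON configuration loading and validation."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .geometry import ViewingGeometry
from .synthcohort import CohortConfig, MechanismParams, default_group_params

#: Recognised top-level sections and their keys.
_SCHEMA = {
    "geometry": {"distance_mm", "pixel_pitch_mm"},
    "stimuli": {
        "height_deg",
        "items_per_task",
        "fixation_box_flanked_deg",
        "fixation_box_unflanked_deg",
    },
    "cohort": {
        "seed",
        "n_pca",
        "n_tad",
        "n_control",
        "items_per_task",
        "participant_sd",
        "latency_noise_scale_ms",
        "latency_sigma",
        "outlier_prob",
        "outlier_scale",
        "distract_prob",
        "group_params",
    },
    "similarity": {"metric", "align"},
}

_MECH_KEYS = {
    "w_avg",
    "w_subst",
    "w_mask",
    "beta_avg",
    "critical_spacing_deg",
    "crowding_exponent",
    "rho",
    "critical_spacing_fraction",
    "lapse_rate",
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Raise :class:`ConfigError` naming the offending field path."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for section, body in cfg.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(body, dict):
            raise ConfigError(f"{section}: must be a mapping")
        for key, value in body.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"{section}.{key}: unknown field")
            if key == "group_params":
                for grp, mech in value.items():
                    if grp not in ("PCA", "tAD", "control"):
                        raise ConfigError(f"cohort.group_params.{grp}: unknown group")
                    for mk in mech:
                        if mk not in _MECH_KEYS:
                            raise ConfigError(f"cohort.group_params.{grp}.{mk}: unknown field")


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def geometry_from_config(cfg: dict) -> ViewingGeometry:
    g = cfg.get("geometry", {})
    return ViewingGeometry(
        distance_mm=g.get("distance_mm", 500.0),
        pixel_pitch_mm=g.get("pixel_pitch_mm", 0.25),
    )


def stimuli_from_config(cfg: dict) -> dict:
    """Stimulus parameters with defaults: glyph height and fixation boxes."""
    s = cfg.get("stimuli", {})
    return {
        "height_deg": s.get("height_deg", 1.20),
        "fixation_box_flanked_deg": tuple(s.get("fixation_box_flanked_deg", (6.4, 2.9))),
        "fixation_box_unflanked_deg": tuple(s.get("fixation_box_unflanked_deg", (3.2, 2.9))),
    }


def cohort_from_config(cfg: dict, seed: int | None = None) -> CohortConfig:
    c = dict(cfg.get("cohort", {}))
    gp = c.pop("group_params", None)
    group_params = default_group_params()
    if gp:
        for grp, mech in gp.items():
            group_params[grp] = MechanismParams(**mech)
    if seed is not None:
        c["seed"] = seed
    if "seed" not in c:
        raise ConfigError("cohort.seed: required (pass --seed or set it in the config)")
    return CohortConfig(group_params=group_params, **c)
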