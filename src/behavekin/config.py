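"""Validated run configuration for the command-line workflows.

One YAML (or JSON) document configures every threshold in the toolbox;
unknown keys are rejected so typos fail loudly before any work is done.
All randomness in a run flows from the single ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "load_config", "ConfigError", "ValidationError"]


class ConfigError(ValueError):
    """Configuration file malformed or failing schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BoardConfig(_Strict):
    n_cols: int = 10
    n_rows: int = 7
    square_size: float = 115.0  # mm


class CalibrationConfig(_Strict):
    board: BoardConfig = Field(default_factory=BoardConfig)
    estimate_distortion: bool = False
    estimate_skew: bool = False


class ReachConfig(_Strict):
    conf_min: float = 0.5
    residual_max: float = 1e9  # px; effectively no filter unless set
    smooth_window: int = 5
    max_gap_frames: int = 5
    v_on: float = 20.0  # mm/s
    v_off: float = 10.0  # mm/s (hysteresis: v_on = 2 v_off)
    min_duration_s: float = 0.1
    merge_gap_s: float = 0.05


class ArenaConfig(_Strict):
    arena_width: float = 45.0  # cm
    arena_height: float = 45.0
    px_per_cm: float = 20.0
    cup_centers: dict[str, tuple[float, float]] = Field(default_factory=dict)
    cup_radius: float = 5.0
    interact_margin: float = 2.0
    chamber_boundaries: list[float] = Field(default_factory=list)


class SocialConfig(_Strict):
    arena: ArenaConfig = Field(default_factory=ArenaConfig)
    contact_threshold_cm: float = 10.0
    nose_contact_cm: float = 3.0
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.3
    class_map: dict[str, tuple[str, str]] = Field(default_factory=dict)


class ClusterConfig(_Strict):
    method: str = "dtw"  # dtw | dtak
    linkage: str = "average"
    sigma: float | None = None  # dtak Gaussian width; None = median heuristic
    k: int | None = None
    center: str | None = None  # start | none


class SimulateConfig(_Strict):
    noise_px: float = 0.0
    dropout_p: float = 0.0
    n_reaches: int = 10
    n_views: int = 24
    rig_preset: str = "mouse"


class RunConfig(_Strict):
    seed: int = 0
    fps: float = 124.0
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    reach: ReachConfig = Field(default_factory=ReachConfig)
    social: SocialConfig = Field(default_factory=SocialConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON config; None gives all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if doc is None:
        return RunConfig()
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def resolved_dict(cfg: RunConfig) -> dict:
    return json.loads(cfg.model_dump_json())
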