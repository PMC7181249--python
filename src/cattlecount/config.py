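"""Run configuration: every tunable constant of the counting pipeline.

All thresholds and rules of the segmentation/counting stages are exposed
here with their field defaults, so a single YAML file fully determines a
run. Unknown keys are rejected to catch typos in parameter files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class RunConfig(BaseModel):
    """All tunable parameters of the counting pipeline.

    Defaults are the values used for light-coated (Canchim/Nelore) cattle
    imaged at ~1 cm/pixel ground sample distance; size rules scale with
    GSD and should be rescaled for other flight altitudes.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # --- ROI grid -----------------------------------------------------
    tile_size: int = 224
    classifier: str = "brightness"  # built-in keyword or dotted path
    coat_rgb: tuple[int, int, int] = (232, 226, 212)
    coat_tolerance: float = 40.0     # per-channel distance for the heuristic
    coat_min_fraction: float = 0.02  # fraction of coat-like pixels => cattle

    # --- color masks --------------------------------------------------
    target_mean: float = 85.0        # cf = target_mean / mean(pixel values)
    min_active_pixels: int = 50_000  # Y>0 pixels needed to keep a quadrant
    c_threshold_scale: float = 40.0  # C threshold = min(cap, scale*cf)
    c_threshold_cap: float = 100.0
    m_threshold: float = 30.0
    custom_threshold_scale: float = 120.0
    custom_threshold_cap: float = 150.0
    dark_threshold: int = 10         # Y threshold for very dark quadrants
    dark_low_bins: int = 10          # "first 10 points" of the histogram
    dark_high_bins: int = 156        # "last 156 points"
    smooth_window: int = 25          # moving-average window on the histogram
    peak_min_separation: int = 30    # peaks closer than this are merged
    valley_fraction: float = 0.10    # amplitude cut for valley candidates

    # --- object counting ----------------------------------------------
    min_object_area: int = 2000
    small_object_area: int = 5000
    min_solidity: float = 0.7
    ev_area_breaks: tuple[float, float] = (8000.0, 15000.0)
    ev_values: tuple[float, float, float] = (1.0, 1.25, 1.5)
    cluster_area_high: float = 15000.0
    cluster_solidity_low: float = 0.65
    cluster_area_low: float = 12000.0
    cluster_solidity_high: float = 0.7
    thinning_scale: float = 20.0     # thinning iterations = round(scale*ev)
    fragment_min_area: int = 100
    fragment_max_solidity: float = 0.5
    final_margin: int = 3            # max-vs-second-highest arbitration
    n_formula: Literal["max", "additive"] = "max"
    empty_object_policy: Literal["count_one", "zero"] = "count_one"

    # --- survey de-duplication ----------------------------------------
    border_band: int = 10            # px from any edge
    carryover_tolerance: float = 150.0  # px; stored-border matching radius
    min_matches: int = 6             # below this, fall back detector
    registration_backend: Literal["orb", "phase", "truth"] = "orb"
    min_registration_score: float = 0.2

    # --- plumbing ------------------------------------------------------
    seed: int = 0
    debug_dump: bool = False

    @field_validator("tile_size", "min_object_area", "smooth_window",
                     "border_band", "min_matches")
    @classmethod
    def _positive(cls, v: int, info) -> int:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    # -- (de)serialization ---------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = self.model_dump()
        # YAML round-trip friendliness: tuples -> lists is handled by
        # pydantic coercion on reload.
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


DEFAULT_CONFIG = RunConfig()
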