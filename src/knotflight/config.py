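"""Pipeline configuration: every numeric constant of the analysis in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the simulate → clean → classify → annotate → fit pipeline.

    Defaults are the analysis constants: 100 m/s speed filter, 150 m sd
    filter, 5-fix median smoother, 2 h detection gap, 20-min straightness
    window with 90° max turn, 95th-percentile cut-off, 30 available times
    per departure over 96 h with 1/1000 weights, 100 bootstrap replicates.
    """

    # cleaning
    speed_threshold: float = 100.0  # m/s
    sd_threshold: float = 150.0  # m
    smooth_window: int = 5  # fixes

    # departure classification
    detection_gap_hours: float = 2.0
    straightness_window_min: float = 20.0
    max_turn_deg: float = 90.0
    transit_speed: float = 5.0  # m/s
    westward_range: tuple[float, float] = (225.0, 315.0)
    cutoff_quantile: float = 0.95

    # environment
    site_lat: float = 53.25
    site_lon: float = 5.25
    tide_lag_min: float = 30.0
    goal_bearing: float = 262.0  # site -> destination flight direction

    # selection model
    n_avail: int = 30
    avail_window_hours: float = 96.0
    used_weight: float = 1.0
    avail_weight: float = 1000.0
    spline_k: int = 10
    bootstrap_B: int = 100

    # simulation scenario
    n_resident: int = 58
    n_departing: int = 34
    n_passthrough: int = 2
    sim_start: str = "2019-09-01"
    sim_end: str = "2019-11-30"
    fix_interval_s: float = 60.0
    loc_error_sd: float = 25.0
    flight_speed: float = 18.0
    use_selection: bool = True  # draw departure times from the true selection function

    # run control
    seed: int = 1
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_quantile <= 1:
            raise ValueError("cutoff_quantile must be in (0, 1]")
        for name in ("speed_threshold", "sd_threshold", "detection_gap_hours",
                     "straightness_window_min", "max_turn_deg", "n_avail",
                     "avail_window_hours", "avail_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["westward_range"] = list(self.westward_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "westward_range" in d:
            d["westward_range"] = tuple(d["westward_range"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
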