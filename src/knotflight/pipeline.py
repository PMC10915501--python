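"""End-to-end driver: simulate → clean → classify → annotate → fit → report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .config import PipelineConfig
from .departures import (
    DepartureEvent,
    Rejection,
    classify_departure,
    cutoff_date,
    departure_proportions,
)
from .rsf import GAMSpec, bootstrap_peaks, build_design, fit_gam, peak_estimate
from .simulate import SimScenario, TrueSelection, default_regions, gen_departure_times, gen_env, gen_tracks
from .tracks import StageReport, preprocess

logger = logging.getLogger("knotflight")

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Stage-by-stage accounting plus the fitted selection model."""

    seed: int
    n_tags: int
    n_fixes_input: int
    n_speed_removed: int
    n_sd_removed: int
    n_fixes_output: int
    n_departures: int
    n_rejections: int
    rejection_reasons: dict
    departures_per_year: dict
    cutoff: str
    n_departed_at_cutoff: int
    n_remaining_at_cutoff: int
    pct_departed: float
    design_rows: int
    coefficients: dict
    peaks: dict
    peak_cis: dict = field(default_factory=dict)
    label_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.n_fixes_input != (
            self.n_fixes_output + self.n_speed_removed + self.n_sd_removed
        ):
            raise ValueError("stage counts do not reconcile: input != output + removed")
        if self.n_departures + self.n_rejections != self.n_tags:
            raise ValueError("classification counts do not reconcile with tag count")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_tags": self.n_tags,
            "fixes": {
                "input": self.n_fixes_input,
                "speed_removed": self.n_speed_removed,
                "sd_removed": self.n_sd_removed,
                "output": self.n_fixes_output,
            },
            "departures": {
                "n": self.n_departures,
                "rejected": self.n_rejections,
                "reasons": self.rejection_reasons,
                "per_year": self.departures_per_year,
            },
            "cutoff": {
                "date": self.cutoff,
                "departed": self.n_departed_at_cutoff,
                "remaining": self.n_remaining_at_cutoff,
                "pct_departed": self.pct_departed,
            },
            "model": {
                "design_rows": self.design_rows,
                "coefficients": self.coefficients,
                "peaks": self.peaks,
                "peak_cis": self.peak_cis,
            },
            "label_accuracy": self.label_accuracy,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        lines = [
            f"tags tracked: {self.n_tags}",
            f"fixes: {self.n_fixes_input} in, {self.n_speed_removed} speed-filtered, "
            f"{self.n_sd_removed} sd-filtered, {self.n_fixes_output} out",
            f"departures classified: {self.n_departures} "
            f"({self.n_rejections} rejections: {self.rejection_reasons})",
            f"cut-off {self.cutoff}: {self.n_departed_at_cutoff} departed vs "
            f"{self.n_remaining_at_cutoff} remaining -> {self.pct_departed}% departed",
            f"design: {self.design_rows} rows",
            "coefficients: "
            + ", ".join(f"{k}={v['beta']:+.3f}" for k, v in self.coefficients.items()),
            "smooth peaks (min): "
            + ", ".join(f"{k}={v:+.0f}" for k, v in self.peaks.items()),
        ]
        return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig,
    bootstrap: bool = False,
    write_artifacts: bool = True,
) -> RunReport:
    """Run every stage on a synthetic scenario defined by ``config``.

    Fully deterministic for a fixed ``config.seed``.  With ``bootstrap=True``
    the smooth-peak confidence intervals are case-bootstrapped
    (``config.bootstrap_B`` refits).
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    start = pd.Timestamp(config.sim_start, tz="UTC")
    end = pd.Timestamp(config.sim_end, tz="UTC")
    regions = default_regions()
    scenario = SimScenario(
        n_resident=config.n_resident,
        n_departing=config.n_departing,
        n_passthrough=config.n_passthrough,
        start=start,
        end=end,
        fix_interval=config.fix_interval_s,
        loc_error_sd=config.loc_error_sd,
        flight_speed=config.flight_speed,
        flight_bearing=config.goal_bearing,
        site=(config.site_lat, config.site_lon),
        seed=seeds[0],
    )

    logger.info("simulating environment %s .. %s", start.date(), end.date())
    env = gen_env(start, end, seed=seeds[1], site=(config.site_lat, config.site_lon))

    departure_times = None
    if config.use_selection and scenario.n_departing > 0:
        grid = env.grid_10min()
        # keep 96 h of availability history and room for the season margins
        grid = grid[(grid >= start + pd.Timedelta(hours=100)) & (grid <= end - pd.Timedelta(days=3))]
        departure_times = gen_departure_times(
            env, TrueSelection(), scenario.n_departing, candidate_grid=grid,
            seed=seeds[2], track_bearing=config.goal_bearing,
        )

    tracks, logs, labels = gen_tracks(scenario, regions, departure_times=departure_times)
    logs_by_tag = {log.tag_id: log for log in logs}

    clean_tracks = []
    stage = StageReport("all")
    for tr in tracks:
        rep = StageReport(tr.tag_id)
        clean_tracks.append(
            preprocess(tr, config.speed_threshold, config.sd_threshold,
                       config.smooth_window, report=rep)
        )
        stage.n_input += rep.n_input
        stage.n_speed_removed += rep.n_speed_removed
        stage.n_sd_removed += rep.n_sd_removed
        stage.n_output += rep.n_output

    events: list[DepartureEvent] = []
    rejections: list[Rejection] = []
    for tr in clean_tracks:
        result = classify_departure(
            tr, logs_by_tag[tr.tag_id], regions,
            gap_hours=config.detection_gap_hours,
            straightness_window=config.straightness_window_min,
            max_turn=config.max_turn_deg,
            transit_speed=config.transit_speed,
        )
        (events if isinstance(result, DepartureEvent) else rejections).append(result)

    predicted = {ev.tag_id: "departing" for ev in events}
    correct = sum(
        1
        for tag, label in labels.items()
        if (label == "departing") == (predicted.get(tag) == "departing")
    )
    label_accuracy = correct / len(labels) if labels else None

    reasons: dict[str, int] = {}
    for r in rejections:
        reasons[r.reason] = reasons.get(r.reason, 0) + 1
    per_year: dict[str, int] = {}
    for ev in events:
        yr = str(pd.Timestamp(ev.departure_time).year)
        per_year[yr] = per_year.get(yr, 0) + 1

    cut = cutoff_date([ev.departure_time for ev in events], q=config.cutoff_quantile)
    last_active = {tr.tag_id: tr.df["t"].iloc[-1] for tr in tracks}
    n_dep, n_rem, pct = departure_proportions(events, last_active, cut)

    rng = np.random.default_rng(seeds[3])
    spec = GAMSpec(k=config.spline_k)
    design = build_design(
        events, env, n_avail=config.n_avail, window_hours=config.avail_window_hours,
        rng=rng, track_bearing=config.goal_bearing,
        used_weight=config.used_weight, avail_weight=config.avail_weight,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        fit = fit_gam(design, spec)
        coefficients = {
            name: {
                "beta": fit.linear_coef(name),
                "se": float(fit.bse[name]),
                "p": float(fit.pvalues[name]),
            }
            for name in fit.linear_terms
        }
        peaks = {s: peak_estimate(fit, s) for s in fit.smooth_terms}

    peak_cis: dict = {}
    if bootstrap and len(events) >= 10:
        boot = bootstrap_peaks(
            events, env, spec, B=config.bootstrap_B, n_avail=config.n_avail,
            rng=rng, track_bearing=config.goal_bearing,
        )
        peak_cis = {
            s: {"mean": boot[s]["mean"], "ci": list(boot[s]["ci"])}
            for s in fit.smooth_terms
        }

    report = RunReport(
        seed=config.seed,
        n_tags=len(tracks),
        n_fixes_input=stage.n_input,
        n_speed_removed=stage.n_speed_removed,
        n_sd_removed=stage.n_sd_removed,
        n_fixes_output=stage.n_output,
        n_departures=len(events),
        n_rejections=len(rejections),
        rejection_reasons=reasons,
        departures_per_year=per_year,
        cutoff=str(cut),
        n_departed_at_cutoff=n_dep,
        n_remaining_at_cutoff=n_rem,
        pct_departed=pct,
        design_rows=len(design),
        coefficients=coefficients,
        peaks=peaks,
        peak_cis=peak_cis,
        label_accuracy=label_accuracy,
    )

    if write_artifacts:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        kio.write_localizations(tracks, out / "localizations.csv")
        kio.write_detections(logs, out / "detections.csv")
        kio.write_regions(regions, out / "regions.geojson")
        kio.write_departures(events, rejections, out / "departures.csv",
                             out / "rejections.csv")
        design.to_csv(out / "design.csv", index=False)
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.summary() + "\n")
        config.to_yaml(out / "config.yaml")

    return report
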