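#!/usr/bin/env python
"""Generate the synthetic tracking season used by the downstream analyses.

Emulates one Wadden Sea season: 58 resident knots, 34 departers whose
departure times are drawn from the known selection function (tailwind
preference, cloud avoidance, peaks after sunset and before high tide), and
2 pass-through tracks, plus tide/cloud/weather series.  Writes everything
under results/analysis/data/.
"""

import json
from pathlib import Path

import pandas as pd

from knotflight import io as kio
from knotflight.config import PipelineConfig
from knotflight.simulate import (
    SimScenario,
    TrueSelection,
    default_regions,
    gen_departure_times,
    gen_env,
    gen_tracks,
)

OUT = Path("results/analysis/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig()
    start = pd.Timestamp(cfg.sim_start, tz="UTC")
    end = pd.Timestamp(cfg.sim_end, tz="UTC")

    env = gen_env(start, end, seed=cfg.seed + 1, site=(cfg.site_lat, cfg.site_lon))
    grid = env.grid_10min()
    grid = grid[(grid >= start + pd.Timedelta(hours=100)) & (grid <= end - pd.Timedelta(days=3))]
    dep_times = gen_departure_times(
        env, TrueSelection(), cfg.n_departing, candidate_grid=grid,
        seed=cfg.seed + 2, track_bearing=cfg.goal_bearing,
    )

    scenario = SimScenario(
        n_resident=cfg.n_resident, n_departing=cfg.n_departing,
        n_passthrough=cfg.n_passthrough, start=start, end=end,
        fix_interval=cfg.fix_interval_s, loc_error_sd=cfg.loc_error_sd,
        flight_speed=cfg.flight_speed, flight_bearing=cfg.goal_bearing,
        site=(cfg.site_lat, cfg.site_lon), seed=cfg.seed,
    )
    tracks, logs, labels = gen_tracks(scenario, default_regions(), departure_times=dep_times)

    kio.write_localizations(tracks, OUT / "localizations.csv")
    kio.write_detections(logs, OUT / "detections.csv")
    kio.write_regions(default_regions(), OUT / "regions.geojson")
    kio.write_series(env.tide, "level", OUT / "tide.csv")
    kio.write_series(env.cloud, "okta", OUT / "cloud.csv")
    kio.write_weather(env.weather, OUT / "weather.csv")
    with open(OUT / "labels.json", "w") as fh:
        json.dump(labels, fh, indent=1, sort_keys=True)
    cfg.to_yaml(OUT / "config.yaml")

    n_fix = sum(len(t) for t in tracks)
    print(f"simulated {len(tracks)} tags ({n_fix} localizations), "
          f"{len(dep_times)} true departures between "
          f"{dep_times[0].date()} and {dep_times[-1].date()}")
    print(f"data written to {OUT}")


if __name__ == "__main__":
    main()
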