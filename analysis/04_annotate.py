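#!/usr/bin/env python
"""Attach environmental covariates to each classified departure time.

Minutes to sunset and to the closest high tide, cloud cover, rain, 1-h
pressure change and full-drift wind assistance along the goal bearing.
"""

from pathlib import Path

from knotflight import io as kio
from knotflight.config import PipelineConfig
from knotflight.environment import EnvBundle, annotate, lag_series

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def load_env(cfg: PipelineConfig) -> EnvBundle:
    return EnvBundle(
        tide=lag_series(kio.read_series(DATA / "tide.csv", "level"), 0.0),
        cloud=kio.read_series(DATA / "cloud.csv", "okta"),
        weather=kio.read_weather(DATA / "weather.csv"),
        site=(cfg.site_lat, cfg.site_lon),
    )


def main() -> None:
    cfg = PipelineConfig.from_yaml(DATA / "config.yaml")
    events = kio.read_departures(OUT / "departures.csv")
    env = load_env(cfg)
    rows = annotate([e.departure_time for e in events], env, track_bearing=cfg.goal_bearing)
    rows.insert(0, "tag_id", [e.tag_id for e in events])
    rows.to_csv(OUT / "departure_covariates.csv", index=False)

    after_sunset = (rows["min_to_sunset"] > 0).mean()
    print(f"annotated {len(rows)} departures")
    print(f"  {100 * after_sunset:.0f}% after sunset; "
          f"median {rows['min_to_sunset'].median():+.0f} min to sunset, "
          f"median {rows['min_to_hightide'].median():+.0f} min to high tide")
    print(f"  mean wind assistance {rows['wind_assist'].mean():+.1f} m/s, "
          f"median cloud {rows['cloud'].median():.0f} okta")


if __name__ == "__main__":
    main()
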