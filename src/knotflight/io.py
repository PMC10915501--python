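"""CSV / GeoJSON / YAML readers and writers.

CSV dialects (headers are fixed, timestamps ISO-8601 UTC; epoch seconds are
also accepted on read):

* localizations: ``tag_id,time,x,y,sd[,n_receivers]``
* detections: ``tag_id,time``
* tide: ``time,level``          * cloud: ``time,okta``
* weather: ``time,pressure_mb,rain,wind_speed_ms,wind_dir_deg``
* departures: ``tag_id,departure_time,x,y,bearing`` (+ rejection file with
  ``tag_id,reason``)

Polygons travel as GeoJSON (planar metres; the CRS is recorded in a
``properties`` sidecar field), configuration as flat YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .departures import DepartureEvent, DetectionLog, RegionSet, Rejection
from .tracks import Track

logger = logging.getLogger("knotflight")

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_detections",
    "write_detections",
    "read_series",
    "write_series",
    "read_weather",
    "write_weather",
    "read_regions",
    "write_regions",
    "write_departures",
    "read_departures",
]


def _parse_times(col: pd.Series) -> pd.Series:
    """ISO-8601 or epoch-seconds timestamps, to UTC."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return pd.to_datetime(numeric, unit="s", utc=True)
    return pd.to_datetime(col, utc=True, format="ISO8601")


def read_localizations(path) -> list[Track]:
    """One cleaned-up :class:`Track` per tag.

    Rows that fail to parse are logged and skipped; duplicate timestamps
    within a tag keep the lower-sd record.
    """
    raw = pd.read_csv(path, dtype={"tag_id": str})
    required = ["tag_id", "time", "x", "y", "sd"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"localization file {path} missing column(s) {missing}")

    n0 = len(raw)
    raw = raw.assign(
        x=pd.to_numeric(raw["x"], errors="coerce"),
        y=pd.to_numeric(raw["y"], errors="coerce"),
        sd=pd.to_numeric(raw["sd"], errors="coerce"),
    )
    times = pd.Series(pd.NaT, index=raw.index, dtype="datetime64[ns, UTC]")
    numeric_t = pd.to_numeric(raw["time"], errors="coerce")
    times[numeric_t.notna()] = pd.to_datetime(numeric_t[numeric_t.notna()], unit="s", utc=True)
    iso_mask = numeric_t.isna()
    if iso_mask.any():
        times[iso_mask] = pd.to_datetime(raw.loc[iso_mask, "time"], utc=True, errors="coerce")
    raw = raw.assign(t=times)
    ok = raw[["t", "x", "y", "sd"]].notna().all(axis=1) & raw["tag_id"].notna()
    if (~ok).any():
        logger.warning("skipped %d malformed localization rows", int((~ok).sum()))
    raw = raw.loc[ok]

    tracks = []
    for tag, g in raw.groupby("tag_id", sort=True):
        g = g.sort_values(["t", "sd"], kind="stable").drop_duplicates("t", keep="first")
        tracks.append(Track(str(tag), g[["t", "x", "y", "sd"]]))
    logger.info("read %d localizations (%d tags) from %s", n0, len(tracks), path)
    return tracks


def write_localizations(tracks, path) -> None:
    frames = []
    for tr in tracks:
        df = tr.df.copy()
        df.insert(0, "tag_id", tr.tag_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["tag_id", "t", "x", "y", "sd"]
    )
    out = out.rename(columns={"t": "time"})
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_detections(path) -> list[DetectionLog]:
    raw = pd.read_csv(path, dtype={"tag_id": str})
    for c in ("tag_id", "time"):
        if c not in raw.columns:
            raise ValueError(f"detection file {path} missing column {c!r}")
    raw["t"] = _parse_times(raw["time"])
    return [DetectionLog(str(tag), g["t"]) for tag, g in raw.groupby("tag_id", sort=True)]


def write_detections(logs, path) -> None:
    frames = [
        pd.DataFrame({"tag_id": log.tag_id, "time": log.times.dt.strftime("%Y-%m-%dT%H:%M:%S%z")})
        for log in logs
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["tag_id", "time"]
    )
    out.to_csv(path, index=False)


def read_series(path, value_col: str) -> pd.DataFrame:
    """A single-valued regular series (tide ``level`` or cloud ``okta``)."""
    raw = pd.read_csv(path)
    aliases = {"level": ("level", "level_cm"), "okta": ("okta", "cloud")}
    col = next((c for c in aliases.get(value_col, (value_col,)) if c in raw.columns), None)
    if "time" not in raw.columns or col is None:
        raise ValueError(f"series file {path} needs columns 'time' and {value_col!r}")
    return pd.DataFrame({"t": _parse_times(raw["time"]), value_col: pd.to_numeric(raw[col])})


def write_series(df: pd.DataFrame, value_col: str, path) -> None:
    out = pd.DataFrame(
        {"time": df["t"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"), value_col: df[value_col]}
    )
    out.to_csv(path, index=False)


_WEATHER_COLS = {
    "pressure_mb": "pressure",
    "rain": "rain",
    "wind_speed_ms": "wind_speed",
    "wind_dir_deg": "wind_dir",
}


def read_weather(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    missing = [c for c in ["time", *_WEATHER_COLS] if c not in raw.columns]
    if missing:
        raise ValueError(f"weather file {path} missing column(s) {missing}")
    out = pd.DataFrame({"t": _parse_times(raw["time"])})
    for src, dst in _WEATHER_COLS.items():
        out[dst] = pd.to_numeric(raw[src])
    return out


def write_weather(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"time": df["t"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")})
    for src, dst in _WEATHER_COLS.items():
        out[src] = df[dst]
    out.to_csv(path, index=False)


def read_regions(path) -> RegionSet:
    """RegionSet from a GeoJSON FeatureCollection.

    Features are identified by a ``role`` property: ``core_area`` and
    ``sea_region``; an optional top-level ``westward_bearing_range`` property
    overrides the default sector.
    """
    with open(path) as fh:
        gj = json.load(fh)
    polys = {}
    for feat in gj.get("features", []):
        role = feat.get("properties", {}).get("role")
        if role in ("core_area", "sea_region"):
            polys[role] = shape(feat["geometry"])
    missing = {"core_area", "sea_region"} - set(polys)
    if missing:
        raise ValueError(f"regions file {path} missing feature role(s) {sorted(missing)}")
    kwargs = {}
    rng = gj.get("westward_bearing_range")
    if rng is not None:
        kwargs["westward_bearing_range"] = tuple(rng)
    return RegionSet(polys["core_area"], polys["sea_region"], **kwargs)


def write_regions(regions: RegionSet, path, crs_note: str = "planar metres (local)") -> None:
    gj = {
        "type": "FeatureCollection",
        "crs_note": crs_note,
        "westward_bearing_range": list(regions.westward_bearing_range),
        "features": [
            {
                "type": "Feature",
                "properties": {"role": role},
                "geometry": mapping(poly),
            }
            for role, poly in (
                ("core_area", regions.core_area),
                ("sea_region", regions.sea_region),
            )
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)


def write_departures(events, rejections, events_path, rejections_path=None) -> None:
    ev = pd.DataFrame(
        [
            {
                "tag_id": e.tag_id,
                "departure_time": pd.Timestamp(e.departure_time).strftime("%Y-%m-%dT%H:%M:%S%z"),
                "x": e.takeoff_position[0],
                "y": e.takeoff_position[1],
                "bearing": e.final_bearing,
            }
            for e in events
        ],
        columns=["tag_id", "departure_time", "x", "y", "bearing"],
    )
    ev.to_csv(events_path, index=False)
    if rejections_path is not None:
        rj = pd.DataFrame(
            [{"tag_id": r.tag_id, "reason": r.reason} for r in rejections],
            columns=["tag_id", "reason"],
        )
        rj.to_csv(rejections_path, index=False)


def read_departures(path) -> list[DepartureEvent]:
    raw = pd.read_csv(path, dtype={"tag_id": str})
    return [
        DepartureEvent(
            tag_id=row["tag_id"],
            departure_time=pd.Timestamp(row["departure_time"]),
            takeoff_position=(float(row["x"]), float(row["y"])),
            final_bearing=float(row["bearing"]),
        )
        for _, row in raw.iterrows()
    ]
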