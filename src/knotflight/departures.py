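"""Rule-based classification of westward relocation-flight departures.

A tagged bird is classified as having departed on a westward relocation
flight (Wadden Sea toward the UK, across the North Sea) when, after track
cleaning, all four criteria of the decision tree hold:

1. no detection more than ``gap`` hours (default 2 h) after the last
   localization — the bird really left the receiver array;
2. the last localization lies outside the core tracking area;
3. the final ``window`` minutes (default 20) of track are straight: every
   turn between consecutive segments is below ``max_turn`` (default 90°);
4. the last localization is over the sea region and the final segment
   bearing is westward (default [225°, 315°], inclusive).

Tracks that enter the study area already in directed flight ("pass-through"
birds whose take-off was never observed) are excluded.  Departure time is
defined as the start of the terminal directed segment — the take-off fix —
found by walking backwards from the last fix while the flight remains fast
and straight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .tracks import Track

__all__ = [
    "DetectionLog",
    "RegionSet",
    "DepartureEvent",
    "Rejection",
    "bearing",
    "angular_difference",
    "criterion_detection_gap",
    "criterion_outside_core",
    "criterion_straightness",
    "criterion_westward_over_sea",
    "exclude_passthrough",
    "classify_departure",
    "cutoff_date",
    "departure_proportions",
]


@dataclass
class DetectionLog:
    """Times a tag was detected by the array (with or without a position)."""

    tag_id: str
    times: pd.Series

    def __post_init__(self) -> None:
        self.times = pd.Series(pd.to_datetime(self.times, utc=True)).sort_values(
            ignore_index=True
        )

    def last_detection(self) -> pd.Timestamp | None:
        return self.times.iloc[-1] if len(self.times) else None


@dataclass
class RegionSet:
    """Study-area geometry: core tracking area, sea region, westward sector."""

    core_area: Polygon
    sea_region: Polygon
    westward_bearing_range: tuple[float, float] = (225.0, 315.0)

    def __post_init__(self) -> None:
        for name, poly in (("core_area", self.core_area), ("sea_region", self.sea_region)):
            if poly.is_empty or not poly.is_valid or poly.area <= 0:
                raise ValueError(f"{name} polygon is degenerate or invalid")
        lo, hi = self.westward_bearing_range
        if not (0 <= lo < 360 and 0 <= hi < 360):
            raise ValueError("westward bearing range must lie within [0, 360)")

    def bearing_is_westward(self, b: float, tol: float = 1e-9) -> bool:
        lo, hi = self.westward_bearing_range
        b = b % 360.0
        if lo <= hi:
            return lo - tol <= b <= hi + tol
        return b >= lo - tol or b <= hi + tol  # interval wrapping north


@dataclass
class DepartureEvent:
    tag_id: str
    departure_time: pd.Timestamp
    takeoff_position: tuple[float, float]
    final_bearing: float
    criteria_flags: dict = field(default_factory=dict)


@dataclass
class Rejection:
    """Why a track was not classified as a departure."""

    tag_id: str
    reason: str
    criteria_flags: dict = field(default_factory=dict)


def bearing(a, b) -> float:
    """Compass bearing from point ``a`` to ``b`` in planar coordinates.

    0° = north (+y), 90° = east (+x), increasing clockwise; result in [0, 360).
    """
    dx = b[0] - a[0]
    dy = b[1] - a[1]
    if dx == 0 and dy == 0:
        raise ValueError("bearing undefined for coincident points")
    return math.degrees(math.atan2(dx, dy)) % 360.0


def angular_difference(b1: float, b2: float) -> float:
    """Smallest absolute angle between two bearings, in [0, 180]."""
    d = abs(b1 - b2) % 360.0
    return min(d, 360.0 - d)


def _segment_bearings(xy: np.ndarray) -> np.ndarray:
    """Bearings of consecutive segments; zero-length segments are skipped
    (a stationary pair of fixes has no direction to turn from)."""
    out = []
    for i in range(len(xy) - 1):
        if xy[i + 1, 0] != xy[i, 0] or xy[i + 1, 1] != xy[i, 1]:
            out.append(bearing(xy[i], xy[i + 1]))
    return np.array(out)


def criterion_detection_gap(track: Track, log: DetectionLog, gap_hours: float = 2.0) -> bool:
    """True iff no detection occurs more than ``gap_hours`` after the last fix."""
    if len(track) == 0:
        raise ValueError("empty track")
    if log.tag_id != track.tag_id:
        raise ValueError(
            f"detection log tag {log.tag_id!r} does not match track {track.tag_id!r}"
        )
    last_fix = track.df["t"].iloc[-1]
    last_det = log.last_detection()
    if last_det is None:
        return True
    return last_det <= last_fix + pd.Timedelta(hours=gap_hours)


def criterion_outside_core(track: Track, regions: RegionSet) -> bool:
    """True iff the last fix lies strictly outside the core area (boundary = inside)."""
    if len(track) == 0:
        raise ValueError("empty track")
    last = track.df.iloc[-1]
    p = Point(last["x"], last["y"])
    return not (regions.core_area.contains(p) or regions.core_area.touches(p))


def criterion_straightness(
    track: Track, window_minutes: float = 20.0, max_turn: float = 90.0
) -> bool | None:
    """Straightness of the final ``window_minutes`` of track.

    Returns True/False when assessable; ``None`` when fewer than 3 fixes fall
    in the window (insufficient data — callers treat this as not-a-departure
    with its own reason code rather than a plain failure).
    """
    df = track.df
    if len(df) == 0:
        raise ValueError("empty track")
    t_end = df["t"].iloc[-1]
    tail = df.loc[df["t"] >= t_end - pd.Timedelta(minutes=window_minutes)]
    if len(tail) < 3:
        return None
    bearings = _segment_bearings(tail[["x", "y"]].to_numpy(dtype=float))
    turns = np.array(
        [angular_difference(bearings[i], bearings[i + 1]) for i in range(len(bearings) - 1)]
    )
    return bool((turns < max_turn).all())


def criterion_westward_over_sea(track: Track, regions: RegionSet) -> bool:
    """True iff last fix is in the sea region and the final segment heads westward."""
    df = track.df
    if len(df) < 2:
        raise ValueError("need at least 2 fixes for a final bearing")
    last = df.iloc[-1]
    prev = df.iloc[-2]
    p = Point(last["x"], last["y"])
    over_sea = regions.sea_region.contains(p) or regions.sea_region.touches(p)
    b = bearing((prev["x"], prev["y"]), (last["x"], last["y"]))
    return bool(over_sea and regions.bearing_is_westward(b))


def exclude_passthrough(track: Track, regions: RegionSet, transit_speed: float = 5.0) -> bool:
    """True (exclude) iff the track starts outside the core already in fast flight."""
    df = track.df
    if len(df) == 0:
        raise ValueError("empty track")
    first = df.iloc[0]
    p = Point(first["x"], first["y"])
    inside = regions.core_area.contains(p) or regions.core_area.touches(p)
    if inside or len(df) < 2:
        return False
    dt = (df["t"].iloc[1] - df["t"].iloc[0]).total_seconds()
    speed = math.hypot(df["x"].iloc[1] - first["x"], df["y"].iloc[1] - first["y"]) / dt
    return speed > transit_speed


def _takeoff_index(df: pd.DataFrame, transit_speed: float, max_turn: float) -> int:
    """Walk backwards from the last fix while segments stay fast and straight.

    Returns the index (into ``df``) of the first fix of the terminal directed
    segment — the take-off fix.
    """
    xy = df[["x", "y"]].to_numpy(dtype=float)
    t = df["t"].to_numpy()
    n = len(df)
    i = n - 1
    prev_bearing = None
    while i > 0:
        dt = pd.Timedelta(t[i] - t[i - 1]).total_seconds()
        dist = math.hypot(xy[i, 0] - xy[i - 1, 0], xy[i, 1] - xy[i - 1, 1])
        if dist == 0 or dist / dt <= transit_speed:
            break
        b = bearing(xy[i - 1], xy[i])
        if prev_bearing is not None and angular_difference(b, prev_bearing) >= max_turn:
            break
        prev_bearing = b
        i -= 1
    return i


def classify_departure(
    track: Track,
    log: DetectionLog,
    regions: RegionSet,
    gap_hours: float = 2.0,
    straightness_window: float = 20.0,
    max_turn: float = 90.0,
    transit_speed: float = 5.0,
) -> DepartureEvent | Rejection:
    """Run the full decision tree on one cleaned track.

    Returns a :class:`DepartureEvent` when all four criteria hold and the
    track is not a pass-through; otherwise a :class:`Rejection` carrying a
    reason code and the per-criterion flags evaluated so far.
    """
    flags: dict = {}
    if len(track) < 2:
        return Rejection(track.tag_id, "too-few-fixes", flags)

    if exclude_passthrough(track, regions, transit_speed):
        flags["passthrough"] = True
        return Rejection(track.tag_id, "pass-through", flags)
    flags["passthrough"] = False

    flags["detection_gap"] = criterion_detection_gap(track, log, gap_hours)
    if not flags["detection_gap"]:
        return Rejection(track.tag_id, "detected-after-gap", flags)

    flags["outside_core"] = criterion_outside_core(track, regions)
    if not flags["outside_core"]:
        return Rejection(track.tag_id, "last-fix-in-core", flags)

    straight = criterion_straightness(track, straightness_window, max_turn)
    if straight is None:
        flags["straightness"] = False
        return Rejection(track.tag_id, "insufficient-fixes-in-window", flags)
    flags["straightness"] = straight
    if not straight:
        return Rejection(track.tag_id, "track-not-straight", flags)

    flags["westward_over_sea"] = criterion_westward_over_sea(track, regions)
    if not flags["westward_over_sea"]:
        return Rejection(track.tag_id, "not-westward-over-sea", flags)

    df = track.df
    i0 = _takeoff_index(df, transit_speed, max_turn)
    takeoff = df.iloc[i0]
    last, prev = df.iloc[-1], df.iloc[-2]
    final_bearing = bearing((prev["x"], prev["y"]), (last["x"], last["y"]))
    return DepartureEvent(
        tag_id=track.tag_id,
        departure_time=takeoff["t"],
        takeoff_position=(float(takeoff["x"]), float(takeoff["y"])),
        final_bearing=final_bearing,
        criteria_flags=flags,
    )


def cutoff_date(departure_dates, q: float = 0.95) -> date:
    """Smallest date by which a fraction ``q`` of departures had occurred.

    Empirical inverse-CDF convention: with n sorted dates, the ceil(q*n)-th.
    """
    dates = sorted(pd.Timestamp(d).date() for d in departure_dates)
    if not dates:
        raise ValueError("cutoff_date needs at least one departure")
    if not 0 < q <= 1:
        raise ValueError("quantile must be in (0, 1]")
    k = math.ceil(q * len(dates))
    return dates[k - 1]


def departure_proportions(events, tag_last_active: dict, cutoff) -> tuple[int, int, float]:
    """Departure accounting against a cut-off date.

    ``events`` are classified departures; ``tag_last_active`` maps every tag
    to the date it was last localized in the study area.  Only tags still
    active at the cut-off enter the denominator: departures on or before the
    cut-off count as departed, non-departing tags last active on or after the
    cut-off count as remaining.

    Returns ``(n_departed, n_remaining, pct_departed)`` with the percentage
    rounded to one decimal.
    """
    cutoff = pd.Timestamp(cutoff).date()
    departed_tags = set()
    n_departed = 0
    for ev in events:
        d = pd.Timestamp(ev.departure_time).date()
        departed_tags.add(ev.tag_id)
        if d <= cutoff:
            n_departed += 1
    n_remaining = sum(
        1
        for tag, last in tag_last_active.items()
        if tag not in departed_tags and pd.Timestamp(last).date() >= cutoff
    )
    denom = n_departed + n_remaining
    if denom == 0:
        raise ValueError("no tags active at cut-off: proportion undefined")
    return n_departed, n_remaining, round(100.0 * n_departed / denom, 1)
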