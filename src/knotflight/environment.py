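"""Environmental covariates for departure times.

Six covariates drive the departure-timing analysis: minutes to sunset,
minutes to the closest high tide, cloud cover (okta), rain rate, 1-h change
in atmospheric pressure, and wind assistance along the intended track.  All
are computable for any timestamp from an :class:`EnvBundle` holding the
aligned raw series:

* tidal water level at 10-min cadence (station-lagged to the study site),
* cloud cover at 10-min cadence, integer okta 0-8,
* hourly weather: pressure (mb), rain (0.1 mm/h), wind speed (m/s) and
  meteorological wind direction (degrees FROM which the wind blows).

Conventions: all timestamps UTC; signed minutes are negative before and
positive after the reference event (sunset or high tide); cloud and tide are
matched to the nearest recorded stamp and pressure/rain to the hour
containing the timestamp — no interpolation, since that would invent
unrecorded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "EnvBundle",
    "lag_series",
    "find_high_tides",
    "time_to_high_tide",
    "sunset_time",
    "wind_assistance",
    "delta_pressure",
    "annotate",
]

TIDAL_PERIOD_MIN = 745.0  # semidiurnal lunar period, minutes


def lag_series(series: pd.DataFrame, lag_minutes: float = 30.0) -> pd.DataFrame:
    """Shift every timestamp forward by ``lag_minutes``; values unchanged.

    Used to carry a tide-gauge record from the measuring station to the study
    site (here +30 min from West-Terschelling to Griend).
    """
    out = series.copy()
    out["t"] = out["t"] + pd.Timedelta(minutes=lag_minutes)
    return out


def find_high_tides(tide: pd.DataFrame, min_separation_hours: float = 8.0) -> pd.DatetimeIndex:
    """High-tide times: local maxima of the water-level series.

    Peaks closer than ``min_separation_hours`` are merged (highest wins),
    which suppresses noise wiggles well below the ~12.4 h semidiurnal period.
    """
    level = tide["level"].to_numpy(dtype=float)
    if len(level) < 3 or np.ptp(level) == 0:
        raise ValueError("tide series is flat or too short: no high tides found")
    cadence_s = (tide["t"].iloc[1] - tide["t"].iloc[0]).total_seconds()
    # the crest of a semidiurnal curve is flat relative to gauge noise, so a
    # short centred rolling mean (~1 h) stabilises the argmax before peaking
    smooth_n = max(1, int(round(3600 / cadence_s)) | 1)
    smoothed = (
        pd.Series(level).rolling(smooth_n, center=True, min_periods=1).mean().to_numpy()
    )
    distance = max(1, int(round(min_separation_hours * 3600 / cadence_s)))
    idx, _ = find_peaks(smoothed, distance=distance)
    if len(idx) == 0:
        raise ValueError("no high-tide peaks detected")
    return pd.DatetimeIndex(tide["t"].iloc[idx]).sort_values()


def time_to_high_tide(t, high_tides) -> float:
    """Signed minutes from ``t`` to the closest high tide (− before, + after).

    An exact midpoint between two tides resolves to the upcoming tide, i.e.
    the negative sign, keeping results within [−P/2, +P/2].
    """
    t = pd.Timestamp(t)
    tides = pd.DatetimeIndex(high_tides)
    if len(tides) == 0:
        raise ValueError("empty high-tide list")
    lo = tides[0] - pd.Timedelta(minutes=TIDAL_PERIOD_MIN / 2)
    hi = tides[-1] + pd.Timedelta(minutes=TIDAL_PERIOD_MIN / 2)
    if not (lo <= t <= hi):
        raise ValueError(f"time {t} outside high-tide coverage [{lo}, {hi}]")
    deltas = (t - tides).total_seconds() / 60.0
    i = int(np.argmin(np.abs(deltas)))
    best = deltas[i]
    # tie at the exact midpoint: prefer the upcoming tide (negative minutes)
    for d in deltas:
        if abs(d) == abs(best) and d < best:
            best = d
    return float(best)


def _noaa_sunset_minutes(d: date, lat: float, lon: float, jc_offset_min: float) -> float:
    """Minutes past UTC midnight of sunset on date ``d`` (NOAA solar geometry).

    ``jc_offset_min`` is the time-of-day (minutes) at which the slowly varying
    solar elements are evaluated; one refinement pass is enough for <1 min
    accuracy at temperate latitudes.
    """
    # Julian day at UTC midnight of d
    a = (14 - d.month) // 12
    y = d.year + 4800 - a
    m = d.month + 12 * a - 3
    jdn = d.day + (153 * m + 2) // 5 + 365 * y + y // 4 - y // 100 + y // 400 - 32045
    jd = jdn - 0.5 + jc_offset_min / 1440.0
    jc = (jd - 2451545.0) / 36525.0

    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m_anom)
    eq_ctr = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + eq_ctr
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    obr = math.radians(obliq)
    decl = math.asin(math.sin(obr) * math.sin(math.radians(app_long)))

    var_y = math.tan(obr / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mr)
        + 4.0 * ecc * var_y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * var_y ** 2 * math.sin(4 * l0r)
        - 1.25 * ecc ** 2 * math.sin(2 * mr)
    )

    latr = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(90.833)) / (math.cos(latr) * math.cos(decl))
        - math.tan(latr) * math.tan(decl)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise ValueError(
            f"no sunset at lat={lat} on {d} (polar day or night)"
        )
    ha = math.degrees(math.acos(cos_ha))
    solar_noon = 720.0 - 4.0 * lon - eqtime
    return solar_noon + 4.0 * ha


def sunset_time(d, lat: float, lon: float) -> pd.Timestamp:
    """UTC sunset (sun centre at −0.833° altitude) for a calendar date.

    Standard NOAA solar-position geometry with one refinement pass; accurate
    to well under 2 minutes at mid-latitudes.  Raises for polar day/night.
    """
    d = pd.Timestamp(d).date()
    approx = _noaa_sunset_minutes(d, lat, lon, 720.0)
    refined = _noaa_sunset_minutes(d, lat, lon, approx)
    return pd.Timestamp(d, tz="UTC") + pd.Timedelta(minutes=refined)


def wind_assistance(wind_speed: float, wind_dir_from: float, track_bearing: float) -> float:
    """Along-track wind component under full drift, in m/s.

    ``wind_dir_from`` is meteorological (direction the wind blows FROM);
    internally converted to the blow-to direction.  Positive = tailwind.
    No airspeed correction: full drift is the simple projection
    ``speed * cos(theta_to - track_bearing)``.
    """
    if wind_speed < 0:
        raise ValueError("wind speed must be non-negative")
    theta_to = (wind_dir_from + 180.0) % 360.0
    return wind_speed * math.cos(math.radians(theta_to - track_bearing))


def _floor_hour(t: pd.Timestamp) -> pd.Timestamp:
    return t.floor("h")


@dataclass
class EnvBundle:
    """Aligned environmental series with lookup by time.

    ``tide`` must already be station-lagged; high-tide times are derived on
    construction.
    """

    tide: pd.DataFrame  # columns t, level
    cloud: pd.DataFrame  # columns t, okta
    weather: pd.DataFrame  # columns t, pressure, rain, wind_speed, wind_dir
    site: tuple[float, float] = (53.25, 5.25)  # (lat, lon), Griend area
    high_tides: pd.DatetimeIndex = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name, df, cols in (
            ("tide", self.tide, ["t", "level"]),
            ("cloud", self.cloud, ["t", "okta"]),
            ("weather", self.weather, ["t", "pressure", "rain", "wind_speed", "wind_dir"]),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} series missing columns {missing}")
            if not df["t"].is_monotonic_increasing:
                raise ValueError(f"{name} series not time-sorted")
        okta = self.cloud["okta"]
        if ((okta < 0) | (okta > 8)).any():
            raise ValueError("cloud okta values must lie in [0, 8]")
        if self.high_tides is None:
            self.high_tides = find_high_tides(self.tide)
        self._weather_by_hour = self.weather.set_index("t")

    def cloud_at(self, t) -> float:
        """Okta at the nearest 10-min stamp."""
        t = pd.Timestamp(t)
        ts = self.cloud["t"]
        i = int(np.argmin(np.abs((ts - t).dt.total_seconds())))
        return float(self.cloud["okta"].iloc[i])

    def weather_at(self, t) -> pd.Series:
        """Weather row of the hour containing ``t``."""
        hour = _floor_hour(pd.Timestamp(t))
        try:
            return self._weather_by_hour.loc[hour]
        except KeyError:
            raise ValueError(f"weather coverage: no record for hour {hour}") from None

    def grid_10min(self) -> pd.DatetimeIndex:
        """10-min timestamps on which every covariate is defined.

        The start allows one hour of pressure history (for the 1-h pressure
        change) and the end stays within half a tidal period of the last
        detected high tide (for tide matching).
        """
        start = max(self.tide["t"].iloc[0], self.cloud["t"].iloc[0],
                    self.weather["t"].iloc[0] + pd.Timedelta(hours=1),
                    self.high_tides[0] - pd.Timedelta(minutes=TIDAL_PERIOD_MIN / 2))
        end = min(self.tide["t"].iloc[-1], self.cloud["t"].iloc[-1],
                  self.weather["t"].iloc[-1] + pd.Timedelta(minutes=59),
                  self.high_tides[-1] + pd.Timedelta(minutes=TIDAL_PERIOD_MIN / 2))
        return pd.date_range(start.ceil("10min"), end.floor("10min"), freq="10min")


def delta_pressure(weather: pd.DataFrame, t, window_hours: float = 1.0) -> float:
    """Pressure change over the preceding ``window_hours`` (mb).

    Hourly records matched by flooring to the hour:
    ``P(hour of t) − P(hour of t − window)``.
    """
    t = pd.Timestamp(t)
    by_hour = weather.set_index("t")["pressure"]
    h1 = _floor_hour(t)
    h0 = _floor_hour(t - pd.Timedelta(hours=window_hours))
    for h in (h0, h1):
        if h not in by_hour.index:
            raise ValueError(f"pressure coverage: no record for hour {h}")
    return float(by_hour.loc[h1] - by_hour.loc[h0])


def _nearest_sunset_minutes(t: pd.Timestamp, lat: float, lon: float) -> float:
    """Signed minutes from ``t`` to the nearest sunset (− before, + after)."""
    d = t.date()
    best = None
    for dd in (-1, 0, 1):
        s = sunset_time(d + timedelta(days=dd), lat, lon)
        delta = (t - s).total_seconds() / 60.0
        if best is None or abs(delta) < abs(best):
            best = delta
    return float(best)


def annotate(times, env: EnvBundle, track_bearing: float = 262.0) -> pd.DataFrame:
    """Covariate rows for a set of timestamps.

    One row per time with columns ``t, min_to_sunset, min_to_hightide, cloud,
    rain, d_pressure, wind_assist, year``.  ``track_bearing`` is the intended
    flight direction used for wind assistance (default 262°, the approximate
    Griend→Wash great-circle bearing).
    """
    times = pd.DatetimeIndex(pd.to_datetime(times, utc=True))
    lat, lon = env.site

    # sunset: one solar computation per distinct date, then nearest of the
    # adjacent evenings per timestamp
    sunset_cache: dict[date, pd.Timestamp] = {}

    def _sunset(d: date) -> pd.Timestamp:
        if d not in sunset_cache:
            sunset_cache[d] = sunset_time(d, lat, lon)
        return sunset_cache[d]

    min_to_sunset = np.empty(len(times))
    for i, t in enumerate(times):
        d = t.date()
        deltas = [
            (t - _sunset(d + timedelta(days=dd))).total_seconds() / 60.0
            for dd in (-1, 0, 1)
        ]
        min_to_sunset[i] = min(deltas, key=abs)

    # tide: signed minutes to the nearest detected high tide, midpoint ties
    # resolving to the upcoming tide
    tides_ns = env.high_tides.asi8
    t_ns = times.asi8
    lo = tides_ns[0] - TIDAL_PERIOD_MIN / 2 * 60e9
    hi = tides_ns[-1] + TIDAL_PERIOD_MIN / 2 * 60e9
    if t_ns.size and (t_ns.min() < lo or t_ns.max() > hi):
        bad = times[(t_ns < lo) | (t_ns > hi)][0]
        raise ValueError(f"time {bad} outside high-tide coverage")
    j = np.searchsorted(tides_ns, t_ns)
    prev_idx = np.clip(j - 1, 0, len(tides_ns) - 1)
    next_idx = np.clip(j, 0, len(tides_ns) - 1)
    d_prev = (t_ns - tides_ns[prev_idx]) / 60e9
    d_next = (t_ns - tides_ns[next_idx]) / 60e9
    min_to_hightide = np.where(np.abs(d_next) <= np.abs(d_prev), d_next, d_prev)

    # cloud: nearest 10-min stamp
    cloud_t = pd.DatetimeIndex(env.cloud["t"]).asi8
    k = np.searchsorted(cloud_t, t_ns)
    k0 = np.clip(k - 1, 0, len(cloud_t) - 1)
    k1 = np.clip(k, 0, len(cloud_t) - 1)
    nearer = np.abs(t_ns - cloud_t[k1]) < np.abs(t_ns - cloud_t[k0])
    cloud = env.cloud["okta"].to_numpy(dtype=float)[np.where(nearer, k1, k0)]

    # weather: hour containing t; pressure change vs the preceding hour
    hours = times.floor("h")
    prev_hours = hours - pd.Timedelta(hours=1)
    wx = env._weather_by_hour
    for h in pd.DatetimeIndex(np.unique(hours.union(prev_hours))):
        if h not in wx.index:
            raise ValueError(f"weather coverage: no record for hour {h}")
    cur = wx.loc[hours]
    prev = wx.loc[prev_hours]
    d_pressure_v = cur["pressure"].to_numpy() - prev["pressure"].to_numpy()
    theta_to = np.radians((cur["wind_dir"].to_numpy() + 180.0) % 360.0 - track_bearing)
    wind_assist = cur["wind_speed"].to_numpy() * np.cos(theta_to)

    return pd.DataFrame(
        {
            "t": times,
            "min_to_sunset": min_to_sunset,
            "min_to_hightide": min_to_hightide,
            "cloud": cloud,
            "rain": cur["rain"].to_numpy(dtype=float),
            "d_pressure": d_pressure_v,
            "wind_assist": wind_assist,
            "year": times.year,
        }
    )
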