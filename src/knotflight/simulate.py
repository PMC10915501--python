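"""Synthetic tracking and environmental data with known ground truth.

Emulates the study system — overwintering red knots on a Wadden Sea mudflat
tracked by a regional array — well enough that every downstream stage
(cleaning, departure classification, covariate annotation, selection-model
fitting) can be exercised and verified at desk scale:

* **residents** random-walk inside the core tracking area for the whole
  season and are detected throughout;
* **departers** behave like residents, then take off on a straight westward
  flight over the sea region, after which both localizations and detections
  cease;
* **pass-through** birds enter the area already in directed flight and cross
  it, so their take-off is unobserved;
* the tide is a noisy sinusoid at the semidiurnal lunar period (only the
  high-tide *times* matter downstream), weather is an autocorrelated hourly
  process, cloud cover a bounded random walk on 0-8 okta;
* departure times are drawn from an explicit selection function over a
  10-min candidate grid, so the fitted model can be checked against known
  coefficients and smooth peaks.

Every generator takes a seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from . import environment as envmod
from .environment import EnvBundle, annotate
from .tracks import Track
from .departures import RegionSet

__all__ = [
    "SimScenario",
    "TrueSelection",
    "WeatherParams",
    "default_regions",
    "gen_tide",
    "gen_cloud",
    "gen_weather",
    "gen_env",
    "gen_tracks",
    "gen_departure_times",
    "extend_detections",
]


@dataclass
class SimScenario:
    """Study-design parameters for one simulated tracking season."""

    n_resident: int = 58
    n_departing: int = 34
    n_passthrough: int = 0
    start: pd.Timestamp = pd.Timestamp("2019-09-01", tz="UTC")
    end: pd.Timestamp = pd.Timestamp("2019-11-30", tz="UTC")
    fix_interval: float = 60.0  # seconds
    loc_error_sd: float = 25.0  # metres, Gaussian per coordinate
    flight_speed: float = 18.0  # m/s, transit speed of a departing knot
    flight_bearing: float = 262.0  # degrees, Griend -> Wash
    site: tuple[float, float] = (53.25, 5.25)  # lat, lon for solar geometry
    resident_step_sd: float = 150.0  # metres per fix while foraging
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_resident, self.n_departing, self.n_passthrough) < 0:
            raise ValueError("counts must be non-negative")
        if self.start >= self.end:
            raise ValueError("scenario start must precede end")
        if self.fix_interval <= 0 or self.flight_speed <= 0:
            raise ValueError("fix_interval and flight_speed must be positive")
        if self.loc_error_sd < 0:
            raise ValueError("loc_error_sd must be non-negative")
        if not 0 <= self.flight_bearing < 360:
            raise ValueError("flight_bearing must lie in [0, 360)")


@dataclass
class TrueSelection:
    """Ground-truth departure-time selection function.

    The linear effects and the two Gaussian bumps (minutes relative to sunset
    and to high tide) define the log relative selection strength
    ``eta(t)``; departure times are sampled with probability proportional to
    ``exp(eta(t))`` over a 10-min candidate grid.  Defaults mirror the kind
    of selection the analysis is meant to detect: tailwind preference, cloud
    avoidance, a peak ~108 min after sunset and ~238 min before high tide.
    """

    beta_wind: float = 0.3  # per m/s of wind assistance
    beta_cloud: float = -0.2  # per okta
    beta_dpressure: float = 0.0  # per mb/h
    beta_rain: float = 0.0  # per 0.1 mm/h
    sunset_peak: float = 108.0  # minutes after sunset
    tide_peak: float = -238.0  # minutes relative to high tide
    smooth_scales: tuple[float, float] = (90.0, 120.0)  # bump widths, minutes
    bump_heights: tuple[float, float] = (2.0, 2.0)  # log-odds at peak

    def __post_init__(self) -> None:
        if min(self.smooth_scales) <= 0:
            raise ValueError("smooth_scales must be positive")

    def eta(self, cov: pd.DataFrame) -> np.ndarray:
        """Log selection strength for annotated covariate rows."""
        s_sun, s_tide = self.smooth_scales
        h_sun, h_tide = self.bump_heights
        return (
            self.beta_wind * cov["wind_assist"].to_numpy()
            + self.beta_cloud * cov["cloud"].to_numpy()
            + self.beta_dpressure * cov["d_pressure"].to_numpy()
            + self.beta_rain * cov["rain"].to_numpy()
            + h_sun * np.exp(-0.5 * ((cov["min_to_sunset"].to_numpy() - self.sunset_peak) / s_sun) ** 2)
            + h_tide * np.exp(-0.5 * ((cov["min_to_hightide"].to_numpy() - self.tide_peak) / s_tide) ** 2)
        )


def default_regions() -> RegionSet:
    """Study-area geometry used by the simulator.

    A 12x12 km core tracking area around the origin (the mudflat) and a sea
    region beginning 9 km to its west.
    """
    return RegionSet(
        core_area=box(-6000, -6000, 6000, 6000),
        sea_region=box(-80000, -40000, -9000, 40000),
    )


def _check_interval(start, end) -> tuple[pd.Timestamp, pd.Timestamp]:
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    if end.tzinfo is None:
        end = end.tz_localize("UTC")
    if end <= start:
        raise ValueError("invalid interval: end must be after start")
    return start, end


def gen_tide(
    start,
    end,
    period_min: float = envmod.TIDAL_PERIOD_MIN,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Water level at 10-min cadence: a cosine at the semidiurnal period plus noise.

    High tides sit at integer multiples of ``period_min`` after ``start``.
    """
    if period_min <= 0 or amplitude <= 0:
        raise ValueError("period and amplitude must be positive")
    start, end = _check_interval(start, end)
    t = pd.date_range(start, end, freq="10min")
    minutes = (t - start).total_seconds() / 60.0
    rng = np.random.default_rng(seed)
    level = amplitude * np.cos(2 * np.pi * minutes / period_min)
    if noise_sd > 0:
        level = level + rng.normal(0.0, noise_sd, len(t))
    return pd.DataFrame({"t": t, "level": level})


def gen_cloud(start, end, seed: int = 0, step_prob: float = 0.4) -> pd.DataFrame:
    """Cloud cover as integer okta 0-8 at 10-min cadence, bounded random walk."""
    start, end = _check_interval(start, end)
    t = pd.date_range(start, end, freq="10min")
    rng = np.random.default_rng(seed)
    okta = np.empty(len(t), dtype=int)
    okta[0] = rng.integers(0, 9)
    steps = rng.choice([-1, 0, 1], size=len(t) - 1, p=[step_prob / 2, 1 - step_prob, step_prob / 2])
    for i, s in enumerate(steps, start=1):
        okta[i] = min(8, max(0, okta[i - 1] + s))
    return pd.DataFrame({"t": t, "okta": okta})


@dataclass
class WeatherParams:
    """Marginal and autocorrelation settings of the hourly weather process."""

    pressure_mean: float = 1013.0  # mb
    pressure_phi: float = 0.9  # AR(1) coefficient
    pressure_sd: float = 0.4  # innovation sd, mb
    wind_mean: float = 7.0  # m/s
    wind_phi: float = 0.9
    wind_sd: float = 1.5  # innovation sd, m/s (truncated at 0)
    dir_step_sd: float = 20.0  # degrees per hour, circular random walk
    p_wet_given_dry: float = 0.05
    p_wet_given_wet: float = 0.75
    rain_scale: float = 6.0  # 0.1 mm/h units, exponential magnitude when wet


def gen_weather(start, end, seed: int = 0, params: WeatherParams | None = None) -> pd.DataFrame:
    """Hourly weather: AR(1) pressure, truncated AR(1) wind speed, circular
    random-walk wind direction (degrees FROM), and a two-state wet/dry rain
    chain with exponential wet-hour intensities (0.1 mm/h units)."""
    start, end = _check_interval(start, end)
    if params is None:
        params = WeatherParams()
    t = pd.date_range(start.floor("h"), end, freq="h")
    n = len(t)
    rng = np.random.default_rng(seed)

    pressure = np.empty(n)
    pressure[0] = params.pressure_mean
    innov = rng.normal(0.0, 1.0, n) * params.pressure_sd
    for i in range(1, n):
        pressure[i] = params.pressure_mean + params.pressure_phi * (
            pressure[i - 1] - params.pressure_mean
        ) + innov[i]

    wind = np.empty(n)
    wind[0] = params.wind_mean
    winnov = rng.normal(0.0, 1.0, n) * params.wind_sd
    for i in range(1, n):
        wind[i] = max(
            0.0,
            params.wind_mean + params.wind_phi * (wind[i - 1] - params.wind_mean) + winnov[i],
        )

    direction = (rng.uniform(0, 360) + np.cumsum(rng.normal(0, params.dir_step_sd, n))) % 360.0

    wet = np.zeros(n, dtype=bool)
    u = rng.uniform(size=n)
    for i in range(1, n):
        p = params.p_wet_given_wet if wet[i - 1] else params.p_wet_given_dry
        wet[i] = u[i] < p
    rain = np.where(wet, np.round(rng.exponential(params.rain_scale, n) + 1.0), 0.0)

    return pd.DataFrame(
        {"t": t, "pressure": pressure, "rain": rain, "wind_speed": wind, "wind_dir": direction}
    )


def gen_env(
    start,
    end,
    seed: int = 0,
    site: tuple[float, float] = (53.25, 5.25),
    tide_amplitude: float = 1.0,
    tide_noise_sd: float = 0.02,
    weather_params: WeatherParams | None = None,
) -> EnvBundle:
    """Convenience bundle: tide, cloud and weather over one interval."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    return EnvBundle(
        tide=gen_tide(start, end, amplitude=tide_amplitude, noise_sd=tide_noise_sd, seed=seeds[0]),
        cloud=gen_cloud(start, end, seed=seeds[1]),
        weather=gen_weather(start, end, seed=seeds[2], params=weather_params),
        site=site,
    )


def gen_departure_times(
    env: EnvBundle,
    truth: TrueSelection,
    n: int,
    candidate_grid: pd.DatetimeIndex | None = None,
    seed: int = 0,
    track_bearing: float = 262.0,
) -> pd.DatetimeIndex:
    """Draw ``n`` departure times from the selection function over a 10-min grid.

    Probability of each candidate time is proportional to ``exp(eta(t))``;
    draws are independent across birds (ties allowed).
    """
    if candidate_grid is None:
        candidate_grid = env.grid_10min()
    candidate_grid = pd.DatetimeIndex(candidate_grid)
    cov = annotate(candidate_grid, env, track_bearing=track_bearing)  # raises on coverage gaps
    eta = truth.eta(cov)
    eta = eta - eta.max()
    p = np.exp(eta)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidate_grid), size=n, replace=True, p=p)
    return pd.DatetimeIndex(candidate_grid[np.sort(idx)])


def _confined_walk(rng, polygon: Polygon, start_xy, n_steps: int, step_sd: float) -> np.ndarray:
    """Random walk of ``n_steps`` positions confined to ``polygon``."""
    pts = np.empty((n_steps, 2))
    pos = np.asarray(start_xy, dtype=float)
    centre = np.array([polygon.centroid.x, polygon.centroid.y])
    for i in range(n_steps):
        for attempt in range(60):
            # weak pull to the centre keeps walks off the boundary
            prop = pos + 0.02 * (centre - pos) + rng.normal(0.0, step_sd, 2)
            if polygon.contains(Point(prop)):
                pos = prop
                break
        else:
            raise ValueError(
                "polygon too small for the requested walk step "
                f"(step_sd={step_sd} m, polygon area={polygon.area:.0f} m^2)"
            )
        pts[i] = pos
    return pts


def _flight_leg(start_xy, t0, bearing_deg: float, speed: float, fix_interval: float,
                sea: Polygon, n_extra: int = 3,
                min_duration_s: float = 1500.0) -> tuple[np.ndarray, pd.DatetimeIndex]:
    """Straight outbound flight from ``start_xy`` until ``n_extra`` fixes inside
    the sea region and at least ``min_duration_s`` of flight (so the terminal
    straightness window contains flight only)."""
    b = np.radians(bearing_deg)
    step = speed * fix_interval * np.array([np.sin(b), np.cos(b)])
    min_fixes = int(np.ceil(min_duration_s / fix_interval))
    pts = [np.asarray(start_xy, dtype=float)]
    inside = 0
    while inside < n_extra or len(pts) <= min_fixes:
        nxt = pts[-1] + step
        pts.append(nxt)
        if sea.contains(Point(nxt)):
            inside += 1
        if len(pts) > 100000:
            raise ValueError("flight never reached the sea region; check geometry")
    pts = np.array(pts)
    times = pd.DatetimeIndex([t0 + pd.Timedelta(seconds=fix_interval * i) for i in range(len(pts))])
    return pts, times


def gen_tracks(
    scenario: SimScenario,
    regions: RegionSet | None = None,
    departure_times: pd.DatetimeIndex | None = None,
    seed: int | None = None,
):
    """Generate tracks, detection logs and true class labels for a scenario.

    Returns ``(tracks, logs, labels)``: lists of :class:`Track` and
    :class:`DetectionLog` plus a dict tag_id -> {"resident", "departing",
    "passthrough"}.  Residents are detected at every fix through the whole
    season; departers' detections stop with their last localization (over the
    sea); pass-through tracks start outside the core already at flight speed.
    """
    from .departures import DetectionLog

    if regions is None:
        regions = default_regions()
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    core = regions.core_area
    fix = scenario.fix_interval
    season_s = (scenario.end - scenario.start).total_seconds()

    # residents are sampled at a sparse cadence (hourly) over the whole season
    # to keep desk-scale scenarios small; departers use the full fix cadence
    # around their departure so the terminal window is well resolved.
    resident_cadence = max(fix, 3600.0)
    n_res_fix = int(season_s // resident_cadence) + 1

    if departure_times is None and scenario.n_departing > 0:
        lo = scenario.start + pd.Timedelta(seconds=0.2 * season_s)
        hi = scenario.end - pd.Timedelta(seconds=0.2 * season_s)
        offs = rng.uniform(0.0, (hi - lo).total_seconds(), scenario.n_departing)
        departure_times = pd.DatetimeIndex(
            [lo + pd.Timedelta(seconds=round(o)) for o in sorted(offs)]
        )
    elif departure_times is not None:
        departure_times = pd.DatetimeIndex(departure_times)
        if len(departure_times) != scenario.n_departing:
            raise ValueError("need one departure time per departing bird")

    tracks: list[Track] = []
    logs: list[DetectionLog] = []
    labels: dict[str, str] = {}
    tag_no = 0

    def _emit(tag, xy, times, label, det_times=None):
        nonlocal tag_no
        noisy = xy + (
            rng.normal(0.0, scenario.loc_error_sd, xy.shape)
            if scenario.loc_error_sd > 0
            else 0.0
        )
        sd = np.full(len(xy), max(scenario.loc_error_sd, 1.0))
        tracks.append(Track.from_arrays(tag, times, noisy[:, 0], noisy[:, 1], sd))
        logs.append(DetectionLog(tag, pd.Series(det_times if det_times is not None else times)))
        labels[tag] = label

    for _ in range(scenario.n_resident):
        tag = f"res{tag_no:03d}"
        tag_no += 1
        start_xy = _random_point_in(rng, core)
        times = pd.DatetimeIndex(
            [scenario.start + pd.Timedelta(seconds=resident_cadence * i) for i in range(n_res_fix)]
        )
        xy = _confined_walk(rng, core, start_xy, n_res_fix, scenario.resident_step_sd)
        _emit(tag, xy, times, "resident")

    for k in range(scenario.n_departing):
        tag = f"dep{tag_no:03d}"
        tag_no += 1
        t_dep = departure_times[k]
        # a foraging period before take-off at the full fix cadence: one hour
        n_pre = max(3, int(3600 // fix))
        start_xy = _random_point_in(rng, core)
        pre_xy = _confined_walk(rng, core, start_xy, n_pre, scenario.resident_step_sd * fix / 600.0)
        pre_times = pd.DatetimeIndex(
            [t_dep - pd.Timedelta(seconds=fix * (n_pre - i)) for i in range(n_pre)]
        )
        fly_xy, fly_times = _flight_leg(
            pre_xy[-1], t_dep, scenario.flight_bearing, scenario.flight_speed, fix,
            regions.sea_region,
        )
        xy = np.vstack([pre_xy, fly_xy[1:]])
        times = pre_times.append(fly_times[1:])
        _emit(tag, xy, times, "departing")

    for _ in range(scenario.n_passthrough):
        tag = f"pas{tag_no:03d}"
        tag_no += 1
        minx, miny, maxx, maxy = core.bounds
        # enters from just east of the core, already in directed flight
        entry = np.array([maxx + 500.0, rng.uniform(miny * 0.5, maxy * 0.5)])
        t0 = scenario.start + pd.Timedelta(
            seconds=round(rng.uniform(0.25, 0.75) * season_s)
        )
        fly_xy, fly_times = _flight_leg(
            entry, t0, scenario.flight_bearing, scenario.flight_speed, fix, regions.sea_region
        )
        _emit(tag, fly_xy, fly_times, "passthrough")

    return tracks, logs, labels


def _random_point_in(rng, polygon: Polygon, shrink: float = 0.5) -> np.ndarray:
    """Uniform point in a centrally shrunken copy of the polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    cx, cy = polygon.centroid.x, polygon.centroid.y
    for _ in range(1000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        x = cx + shrink * (x - cx)
        y = cy + shrink * (y - cy)
        if polygon.contains(Point(x, y)):
            return np.array([x, y])
    raise ValueError("could not place a start point inside the polygon")


def extend_detections(log, extra_hours: float = 3.0, cadence_minutes: float = 10.0):
    """A 'false departure' detection log: detections continue after the last fix.

    Used to exercise the detection-gap criterion — a bird that is still heard
    by the array hours after its last localization did not leave.
    """
    from .departures import DetectionLog

    last = log.times.iloc[-1]
    extra = pd.date_range(
        last + pd.Timedelta(minutes=cadence_minutes),
        last + pd.Timedelta(hours=extra_hours),
        freq=f"{int(cadence_minutes)}min",
    )
    return DetectionLog(log.tag_id, pd.concat([log.times, pd.Series(extra)], ignore_index=True))
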