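"""Covariate computation: tides, sunset, wind assistance, pressure change."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from knotflight.environment import (
    EnvBundle,
    TIDAL_PERIOD_MIN,
    annotate,
    delta_pressure,
    find_high_tides,
    lag_series,
    sunset_time,
    time_to_high_tide,
    wind_assistance,
)
from knotflight.simulate import gen_env, gen_tide


def _usno_solar_elevation(t: pd.Timestamp, lat: float, lon: float) -> float:
    """Sun elevation (degrees) from the USNO low-precision solar ephemeris.

    An independent route from the implementation: ecliptic coordinates →
    right ascension/declination → Greenwich sidereal time → hour angle.
    Positional accuracy ~0.01°, i.e. seconds-level for sunset times.
    """
    d = t.to_julian_date() - 2451545.0
    g = math.radians((357.529 + 0.98560028 * d) % 360.0)
    q = (280.459 + 0.98564736 * d) % 360.0
    lam = math.radians(q + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    e = math.radians(23.439 - 0.00000036 * d)
    ra = math.degrees(math.atan2(math.cos(e) * math.sin(lam), math.cos(lam))) % 360.0
    decl = math.asin(math.sin(e) * math.sin(lam))
    gmst = (18.697374558 + 24.06570982441908 * d) % 24.0
    ha = math.radians((gmst * 15.0 + lon - ra + 540.0) % 360.0 - 180.0)
    latr = math.radians(lat)
    sin_el = math.sin(latr) * math.sin(decl) + math.cos(latr) * math.cos(decl) * math.cos(ha)
    return math.degrees(math.asin(sin_el))


def usno_sunset(d, lat, lon):
    """Almanac-grade sunset oracle: bisection on solar elevation = −0.833°."""
    day = pd.Timestamp(d, tz="UTC")
    # evening window: solar elevation decreasing through the horizon
    lo = day + pd.Timedelta(hours=12) - pd.Timedelta(hours=lon / 15.0)
    hi = lo + pd.Timedelta(hours=11)
    for _ in range(40):
        mid = lo + (hi - lo) / 2
        if _usno_solar_elevation(mid, lat, lon) > -0.833:
            lo = mid
        else:
            hi = mid
    return lo + (hi - lo) / 2


class TestLagSeries:
    def _tide(self):
        return gen_tide("2019-10-01", "2019-10-03", noise_sd=0.0, seed=0)

    def test_zero_lag_is_identity(self):
        tide = self._tide()
        assert lag_series(tide, 0.0).equals(tide)

    def test_shifts_high_tide_forward(self):
        tide = self._tide()
        lagged = lag_series(tide, 30.0)
        assert (lagged["t"] - tide["t"] == pd.Timedelta(minutes=30)).all()
        assert (lagged["level"] == tide["level"]).all()

    def test_lag_additivity(self):
        tide = self._tide()
        assert lag_series(lag_series(tide, 30), 30).equals(lag_series(tide, 60))


class TestHighTides:
    def test_noise_free_cosine_peaks_at_period_multiples(self):
        tide = gen_tide("2019-10-01", "2019-10-06", noise_sd=0.0, seed=0)
        tides = find_high_tides(tide)
        start = tide["t"].iloc[0]
        for i, ht in enumerate(tides):
            expected = start + pd.Timedelta(minutes=TIDAL_PERIOD_MIN * (i + 1))
            assert abs((ht - expected).total_seconds()) <= 600  # 10-min grid
        assert len(tides) >= 8

    def test_noisy_cosine_within_20_minutes(self):
        tide = gen_tide("2019-10-01", "2019-10-06", amplitude=1.0, noise_sd=0.01, seed=3)
        tides = find_high_tides(tide)
        start = tide["t"].iloc[0]
        for i, ht in enumerate(tides):
            expected = start + pd.Timedelta(minutes=TIDAL_PERIOD_MIN * (i + 1))
            assert abs((ht - expected).total_seconds()) <= 1200

    def test_flat_series_errors(self):
        t = pd.date_range("2019-10-01", periods=200, freq="10min", tz="UTC")
        with pytest.raises(ValueError):
            find_high_tides(pd.DataFrame({"t": t, "level": np.zeros(200)}))


class TestTimeToHighTide:
    TIDES = pd.DatetimeIndex(
        [pd.Timestamp("2019-10-01 00:00", tz="UTC"), pd.Timestamp("2019-10-01 12:25", tz="UTC")]
    )

    def test_at_high_tide_zero(self):
        assert time_to_high_tide(self.TIDES[0], self.TIDES) == 0.0

    def test_after_first_tide(self):
        t = pd.Timestamp("2019-10-01 04:00", tz="UTC")
        assert time_to_high_tide(t, self.TIDES) == pytest.approx(240.0)

    def test_before_second_tide(self):
        t = pd.Timestamp("2019-10-01 10:00", tz="UTC")
        assert time_to_high_tide(t, self.TIDES) == pytest.approx(-145.0)

    def test_midpoint_tie_resolves_negative(self):
        t = pd.Timestamp("2019-10-01 06:12:30", tz="UTC")
        got = time_to_high_tide(t, self.TIDES)
        assert got == pytest.approx(-372.5)

    def test_outside_coverage_errors(self):
        with pytest.raises(ValueError, match="coverage"):
            time_to_high_tide(pd.Timestamp("2019-10-05", tz="UTC"), self.TIDES)

    def test_piecewise_linear_slope_one(self):
        ts = [pd.Timestamp("2019-10-01 02:00", tz="UTC") + pd.Timedelta(minutes=m) for m in range(0, 60, 10)]
        vals = [time_to_high_tide(t, self.TIDES) for t in ts]
        assert np.allclose(np.diff(vals), 10.0)


class TestSunset:
    def test_equinox_near_1800_utc(self):
        # at the equinox the sun sets ~18:12 UTC at lon 0 (refraction + the
        # equation of time push it past naive 18:00)
        s = sunset_time("2019-03-20", 53.0, 0.0)
        naive = pd.Timestamp("2019-03-20 18:00", tz="UTC")
        assert abs((s - naive).total_seconds()) < 15 * 60

    def test_longitude_shift_one_hour(self):
        s0 = sunset_time("2019-03-20", 53.0, 0.0)
        s15 = sunset_time("2019-03-20", 53.0, 15.0)
        assert abs((s0 - s15).total_seconds() - 3600) < 120

    def test_against_independent_almanac_all_year(self):
        """Within 2 minutes of the Julian-cycle oracle on 12 dates at the study site."""
        for month in range(1, 13):
            d = f"2019-{month:02d}-15"
            ours = sunset_time(d, 53.25, 5.25)
            oracle = usno_sunset(d, 53.25, 5.25)
            assert abs((ours - oracle).total_seconds()) < 120, d

    def test_polar_night_errors(self):
        with pytest.raises(ValueError, match="polar"):
            sunset_time("2019-12-21", 80.0, 0.0)


class TestWindAssistance:
    @pytest.mark.parametrize(
        "speed, wind_from, track, expected",
        [
            (10.0, 90.0, 270.0, 10.0),   # easterly wind, westward track: tailwind
            (10.0, 270.0, 270.0, -10.0),  # westerly wind, westward track: headwind
            (8.0, 0.0, 270.0, 0.0),       # northerly crosswind: no assistance
        ],
    )
    def test_closed_forms(self, speed, wind_from, track, expected):
        assert wind_assistance(speed, wind_from, track) == pytest.approx(expected, abs=1e-9)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            wind_assistance(-1.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(0, 40), st.floats(0, 360, exclude_max=True), st.floats(0, 360, exclude_max=True),
        st.floats(-720, 720),
    )
    def test_bounded_and_rotation_invariant(self, speed, wind_from, track, phi):
        a = wind_assistance(speed, wind_from, track)
        assert abs(a) <= speed + 1e-9
        rotated = wind_assistance(speed, (wind_from + phi) % 360.0, track + phi)
        assert rotated == pytest.approx(a, abs=1e-6 * max(1.0, speed))

    def test_equality_iff_parallel(self):
        assert wind_assistance(12.0, 90.0, 270.0) == pytest.approx(12.0)
        assert abs(wind_assistance(12.0, 91.0, 270.0)) < 12.0


class TestDeltaPressure:
    def _weather(self, pressures, start="2019-10-01 00:00"):
        t = pd.date_range(start, periods=len(pressures), freq="h", tz="UTC")
        return pd.DataFrame(
            {"t": t, "pressure": pressures, "rain": 0.0, "wind_speed": 0.0, "wind_dir": 0.0}
        )

    def test_constant_pressure_zero(self):
        w = self._weather([1013.0] * 5)
        assert delta_pressure(w, pd.Timestamp("2019-10-01 03:30", tz="UTC")) == 0.0

    def test_floor_to_hour_convention(self):
        w = self._weather([1010.0, 1013.0], start="2019-10-01 17:00")
        t = pd.Timestamp("2019-10-01 18:20", tz="UTC")
        assert delta_pressure(w, t) == pytest.approx(3.0)

    def test_linear_ramp(self):
        w = self._weather([1000.0 + 2 * i for i in range(6)])
        for minute in (5, 25, 55):
            t = pd.Timestamp(f"2019-10-01 03:{minute:02d}", tz="UTC")
            assert delta_pressure(w, t) == pytest.approx(2.0)

    def test_missing_hour_errors(self):
        w = self._weather([1010.0, 1013.0])
        with pytest.raises(ValueError, match="coverage"):
            delta_pressure(w, pd.Timestamp("2019-10-01 00:30", tz="UTC"))


class TestAnnotate:
    def test_cloud_at_exact_stamp(self, env_short):
        t = env_short.cloud["t"].iloc[500]
        row = annotate([t], env_short).iloc[0]
        assert row["cloud"] == env_short.cloud["okta"].iloc[500]

    def test_zero_weather_gives_zero_covariates(self):
        t = pd.date_range("2019-10-01", "2019-10-08", freq="h", tz="UTC")
        weather = pd.DataFrame(
            {"t": t, "pressure": 1013.0, "rain": 0.0, "wind_speed": 0.0, "wind_dir": 0.0}
        )
        tide = gen_tide("2019-10-01", "2019-10-08", noise_sd=0.0, seed=0)
        cloud = pd.DataFrame(
            {"t": pd.date_range("2019-10-01", "2019-10-08", freq="10min", tz="UTC")}
        ).assign(okta=0)
        env = EnvBundle(tide=tide, cloud=cloud, weather=weather)
        rows = annotate([pd.Timestamp("2019-10-03 12:00", tz="UTC")], env)
        assert rows.iloc[0][["cloud", "rain", "d_pressure", "wind_assist"]].eq(0).all()

    def test_matches_scalar_operations(self, env_short):
        """The vectorized annotation agrees with the scalar covariate functions."""
        times = env_short.grid_10min()[200:220]
        rows = annotate(times, env_short, track_bearing=262.0)
        for i, t in enumerate(times):
            assert rows["min_to_hightide"].iloc[i] == pytest.approx(
                time_to_high_tide(t, env_short.high_tides), abs=1e-6
            )
            assert rows["cloud"].iloc[i] == env_short.cloud_at(t)
            assert rows["d_pressure"].iloc[i] == pytest.approx(
                delta_pressure(env_short.weather, t), abs=1e-9
            )
            w = env_short.weather_at(t)
            assert rows["wind_assist"].iloc[i] == pytest.approx(
                wind_assistance(w["wind_speed"], w["wind_dir"], 262.0), abs=1e-9
            )

    def test_sunset_sign_convention(self, env_short):
        lat, lon = env_short.site
        s = sunset_time("2019-10-05", lat, lon)
        rows = annotate([s - pd.Timedelta(minutes=30), s + pd.Timedelta(minutes=30)], env_short)
        assert rows["min_to_sunset"].iloc[0] == pytest.approx(-30.0, abs=0.1)
        assert rows["min_to_sunset"].iloc[1] == pytest.approx(30.0, abs=0.1)

    def test_coverage_error_names_offender(self, env_short):
        before = env_short.weather["t"].iloc[0] - pd.Timedelta(hours=2)
        with pytest.raises(ValueError, match="coverage"):
            annotate([before], env_short)
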