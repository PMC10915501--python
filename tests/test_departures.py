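"""Departure decision tree, cut-off accounting and classifier fidelity."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from knotflight.departures import (
    DepartureEvent,
    DetectionLog,
    RegionSet,
    Rejection,
    angular_difference,
    bearing,
    classify_departure,
    criterion_detection_gap,
    criterion_outside_core,
    criterion_straightness,
    criterion_westward_over_sea,
    cutoff_date,
    departure_proportions,
    exclude_passthrough,
)
from knotflight.simulate import SimScenario, extend_detections, gen_tracks
from knotflight.tracks import Track, preprocess

T0 = pd.Timestamp("2019-10-01 12:00", tz="UTC")


def track_from(points, dt=60.0, tag="t1", t0=T0):
    times = [t0 + pd.Timedelta(seconds=dt * i) for i in range(len(points))]
    xs, ys = zip(*points)
    return Track.from_arrays(tag, times, xs, ys, [10.0] * len(points))


class TestBearings:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0), (0, 1), 0.0),
            ((0, 0), (-1, 0), 270.0),
            ((0, 0), (1, 1), 45.0),
            ((0, 0), (1, 0), 90.0),
            ((0, 0), (0, -1), 180.0),
        ],
    )
    def test_compass_convention(self, a, b, expected):
        assert bearing(a, b) == pytest.approx(expected)

    def test_coincident_points_undefined(self):
        with pytest.raises(ValueError):
            bearing((3, 3), (3, 3))

    @pytest.mark.parametrize(
        "b1, b2, expected", [(350, 10, 20), (90, 270, 180), (100, 30, 70), (0, 0, 0)]
    )
    def test_angular_difference(self, b1, b2, expected):
        assert angular_difference(b1, b2) == pytest.approx(expected)

    def test_angular_difference_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for b1, b2 in rng.uniform(0, 360, (200, 2)):
            d = angular_difference(b1, b2)
            assert 0 <= d <= 180
            assert d == pytest.approx(angular_difference(b2, b1))


class TestDetectionGap:
    def _track(self):
        return track_from([(0, 0), (100, 0)], dt=60)

    def test_detection_within_gap(self):
        tr = self._track()
        log = DetectionLog("t1", pd.Series([tr.df["t"].iloc[-1] + pd.Timedelta(minutes=90)]))
        assert criterion_detection_gap(tr, log) is True

    def test_detection_just_past_gap_fails(self):
        tr = self._track()
        log = DetectionLog("t1", pd.Series([tr.df["t"].iloc[-1] + pd.Timedelta(hours=2, minutes=1)]))
        assert criterion_detection_gap(tr, log) is False

    def test_empty_log_vacuously_true(self):
        assert criterion_detection_gap(self._track(), DetectionLog("t1", pd.Series([], dtype="datetime64[ns, UTC]"))) is True

    def test_mismatched_tag_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            criterion_detection_gap(self._track(), DetectionLog("other", pd.Series([T0])))


class TestGeometryCriteria:
    def setup_method(self):
        self.regions = RegionSet(box(-5000, -5000, 5000, 5000), box(-50000, -20000, -8000, 20000))

    def test_last_fix_in_core_fails(self):
        tr = track_from([(0, 0), (100, 0)])
        assert criterion_outside_core(tr, self.regions) is False

    def test_last_fix_far_west_passes(self):
        tr = track_from([(0, 0), (-10000, 0)])
        assert criterion_outside_core(tr, self.regions) is True

    def test_boundary_counts_as_inside(self):
        tr = track_from([(0, 0), (5000, 0)])
        assert criterion_outside_core(tr, self.regions) is False

    def test_westward_over_sea(self):
        tr = track_from([(-8000, 0), (-9000, 0)])  # due west into sea box
        assert criterion_westward_over_sea(tr, self.regions) is True

    def test_eastward_fails(self):
        tr = track_from([(-10000, 0), (-9000, 0)])
        assert criterion_westward_over_sea(tr, self.regions) is False

    def test_bearing_225_inclusive(self):
        d = 1000.0 / math.sqrt(2)
        tr = track_from([(-9000 + d, d), (-9000, 0)])  # bearing exactly 225
        assert criterion_westward_over_sea(tr, self.regions) is True

    def test_passthrough_detection(self):
        inside = track_from([(0, 0), (100, 0)])
        assert exclude_passthrough(inside, self.regions) is False
        fast_entry = track_from([(6000, 0), (4920, 0)])  # 18 m/s entering from the east
        assert exclude_passthrough(fast_entry, self.regions) is True
        slow_outside = track_from([(6000, 0), (6030, 0)])  # 0.5 m/s
        assert exclude_passthrough(slow_outside, self.regions) is False


class TestStraightness:
    def test_straight_line_true(self):
        tr = track_from([(i * 1000, 0) for i in range(10)], dt=120)
        assert criterion_straightness(tr) is True

    def test_right_angle_dogleg_false(self):
        # one turn of exactly 90 degrees inside the final window: not below 90
        pts = [(0, 0), (1000, 0), (2000, 0), (2000, 1000), (2000, 2000)]
        tr = track_from(pts, dt=120)
        assert criterion_straightness(tr) is False

    def test_zigzag_under_90_true(self):
        # successive bearing changes of 30, 89, 45 degrees, all below 90
        bearings = [0.0, 30.0, -59.0, -14.0]
        pts = [(0.0, 0.0)]
        for b in bearings:
            br = math.radians(b)
            pts.append((pts[-1][0] + 1000 * math.sin(br), pts[-1][1] + 1000 * math.cos(br)))
        tr = track_from(pts, dt=120)
        assert criterion_straightness(tr) is True

    def test_insufficient_fixes_is_indeterminate(self):
        tr = track_from([(0, 0), (1000, 0)], dt=60)
        assert criterion_straightness(tr) is None

    def test_matches_bruteforce_oracle_on_random_windows(self):
        """1,000 random windows against an independent vector-geometry oracle."""
        rng = np.random.default_rng(42)
        agree = 0
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            pts = rng.uniform(-5000, 5000, (n, 2))
            tr = track_from([tuple(p) for p in pts], dt=60)
            got = criterion_straightness(tr, window_minutes=60)
            # oracle: signed angle between consecutive step vectors via atan2
            steps = np.diff(pts, axis=0)
            keep = ~np.all(steps == 0, axis=1)
            steps = steps[keep]
            expected = True
            for v1, v2 in zip(steps[:-1], steps[1:]):
                cross = v1[0] * v2[1] - v1[1] * v2[0]
                dot = float(np.dot(v1, v2))
                ang = abs(math.degrees(math.atan2(cross, dot)))
                if ang >= 90.0:
                    expected = False
                    break
            assert got == expected
            agree += 1
        assert agree == 1000


class TestCutoff:
    def test_identical_dates(self):
        d = pd.Timestamp("2019-11-06")
        assert cutoff_date([d] * 20) == d.date()

    def test_inverse_cdf_on_1_to_100(self):
        dates = pd.date_range("2019-01-01", periods=100, freq="D")
        assert cutoff_date(dates, q=0.95) == pd.Timestamp("2019-04-05").date()  # day 95

    def test_single_departure(self):
        assert cutoff_date([pd.Timestamp("2020-11-29")]) == pd.Timestamp("2020-11-29").date()

    def test_monotone_in_q(self):
        rng = np.random.default_rng(1)
        dates = pd.to_datetime(
            rng.integers(0, 90, 40), unit="D", origin="2019-09-01"
        )
        cuts = [cutoff_date(dates, q) for q in (0.25, 0.5, 0.75, 0.95, 1.0)]
        assert cuts == sorted(cuts)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cutoff_date([])


class TestProportions:
    def _events(self, n, day="2019-10-01"):
        return [
            DepartureEvent(f"d{i}", pd.Timestamp(day, tz="UTC"), (0, 0), 262.0)
            for i in range(n)
        ]

    @pytest.mark.parametrize(
        "n_dep, n_rem, pct", [(34, 58, 37.0), (27, 47, 36.5), (0, 10, 0.0)]
    )
    def test_printed_proportions(self, n_dep, n_rem, pct):
        cutoff = pd.Timestamp("2019-11-06").date()
        events = self._events(n_dep)
        status = {f"d{i}": pd.Timestamp("2019-10-01") for i in range(n_dep)}
        status.update({f"r{i}": pd.Timestamp("2019-12-01") for i in range(n_rem)})
        got = departure_proportions(events, status, cutoff)
        assert got == (n_dep, n_rem, pct)

    def test_counts_reconcile(self):
        events = self._events(5)
        status = {f"d{i}": pd.Timestamp("2019-10-01") for i in range(5)}
        status.update({f"r{i}": pd.Timestamp("2019-12-01") for i in range(7)})
        n_dep, n_rem, _ = departure_proportions(events, status, pd.Timestamp("2019-11-06"))
        assert n_dep + n_rem == 12

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            departure_proportions([], {}, pd.Timestamp("2019-11-06"))


class TestClassifierFidelity:
    def _run(self, noise, seed, n_dep=12, n_res=8, n_pass=3):
        sc = SimScenario(
            n_resident=n_res, n_departing=n_dep, n_passthrough=n_pass,
            loc_error_sd=noise, seed=seed,
        )
        tracks, logs, labels = gen_tracks(sc)
        from knotflight.simulate import default_regions

        regions = default_regions()
        logd = {l.tag_id: l for l in logs}
        predicted = {}
        for tr in tracks:
            res = classify_departure(preprocess(tr), logd[tr.tag_id], regions)
            predicted[tr.tag_id] = (
                "departing" if isinstance(res, DepartureEvent) else res.reason
            )
        return labels, predicted

    def test_noise_free_confusion_matrix_diagonal(self):
        labels, predicted = self._run(noise=0.0, seed=101)
        for tag, label in labels.items():
            if label == "departing":
                assert predicted[tag] == "departing"
            elif label == "resident":
                assert predicted[tag] == "last-fix-in-core"
            else:
                assert predicted[tag] == "pass-through"

    def test_recall_with_50m_noise(self):
        """At 50 m localization error the classifier keeps >= 95% recall."""
        hits = total = 0
        for seed in (7, 8):
            labels, predicted = self._run(noise=50.0, seed=seed, n_dep=20, n_res=3, n_pass=0)
            for tag, label in labels.items():
                if label == "departing":
                    total += 1
                    hits += predicted[tag] == "departing"
        assert total == 40
        assert hits / total >= 0.95

    def test_false_departure_rejected_by_detection_gap(self):
        """A track that looks like a departure but keeps being detected is rejected."""
        sc = SimScenario(n_resident=0, n_departing=1, n_passthrough=0, loc_error_sd=0.0, seed=5)
        tracks, logs, _ = gen_tracks(sc)
        from knotflight.simulate import default_regions

        regions = default_regions()
        good = classify_departure(preprocess(tracks[0]), logs[0], regions)
        assert isinstance(good, DepartureEvent)
        bad = classify_departure(
            preprocess(tracks[0]), extend_detections(logs[0], extra_hours=3.0), regions
        )
        assert isinstance(bad, Rejection)
        assert bad.reason == "detected-after-gap"

    def test_departure_time_is_takeoff(self):
        """The reported departure time is the start of the terminal flight."""
        sc = SimScenario(n_resident=0, n_departing=1, n_passthrough=0, loc_error_sd=0.0, seed=5)
        t_dep = pd.DatetimeIndex([pd.Timestamp("2019-10-10 18:00", tz="UTC")])
        tracks, logs, _ = gen_tracks(sc, departure_times=t_dep)
        from knotflight.simulate import default_regions

        ev = classify_departure(preprocess(tracks[0]), logs[0], default_regions())
        assert isinstance(ev, DepartureEvent)
        # take-off fix is the last pre-flight fix, one fix interval before t_dep
        assert abs((ev.departure_time - t_dep[0]).total_seconds()) <= sc.fix_interval
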