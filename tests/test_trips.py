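import numpy as np
import pandas as pd
import pytest

from pairforage.hmm import StatePath
from pairforage.trips import (
    Dive,
    audit_trips,
    deployment_summary,
    detect_dives,
    differential_depth,
    hourly_mean_depth,
    segment_trips,
    trip_summary_indices,
)
from conftest import make_series


def depth_frame(depths, rate_hz=1.0, start="2022-07-25T12:00:00"):
    t0 = np.datetime64(start, "ms")
    times = t0 + (np.arange(len(depths)) * 1000.0 / rate_hz).astype("timedelta64[ms]")
    return pd.DataFrame({"time": times, "depth_m": np.asarray(depths, dtype=float)})


def fake_path(states):
    states = np.asarray(states, dtype=object).astype(str)
    n = len(states)
    return StatePath(states=states, state_idx=np.zeros(n, dtype=int),
                     posteriors=np.full((n, 4), 0.25), loglik=0.0, path_logprob=0.0)


class TestDetectDives:
    def test_flat_surface_gives_no_dives(self):
        assert detect_dives(depth_frame(np.zeros(600))) == []

    def test_single_60s_excursion_to_20m(self):
        d = np.zeros(600)
        d[100:160] = 20.0
        dives = detect_dives(depth_frame(d))
        assert len(dives) == 1
        assert dives[0].max_depth_m == 20.0
        assert dives[0].duration_min == pytest.approx(1.0)

    def test_two_second_spike_filtered(self):
        d = np.zeros(600)
        d[100:102] = 5.0
        assert detect_dives(depth_frame(d)) == []

    def test_hour_of_day_uses_colony_local_time(self):
        d = np.zeros(60)
        d[10:40] = 10.0
        (dive,) = detect_dives(depth_frame(d, start="2022-07-25T12:00:00"), tz_offset_h=-5.0)
        assert dive.hour_of_day == 7

    def test_empty_series(self):
        assert detect_dives(depth_frame([])) == []


def series_with_excursions(excursions, colony_pos=0.0, far_lat=0.3):
    """Step series alternating colony residency and excursions.

    ``excursions``: list of step counts; each excursion goes to ``far_lat``
    degrees north (~33 km) and back, padded with 3 colony steps between.
    """
    lats = [0.0] * 3
    for n in excursions:
        lats += list(np.linspace(0.02, far_lat, n // 2 + 1))[1:]
        lats += list(np.linspace(far_lat, 0.02, n - n // 2 + 1))[1:-1]
        lats += [0.0] * 3
    return make_series(np.zeros(len(lats)), lats)


def dive_at(offset_s, duration_s=60, depth=15.0, start="2022-07-25T00:00:00"):
    t0 = np.datetime64(start, "ms") + np.timedelta64(int(offset_s * 1000), "ms")
    return Dive(start=t0, end=t0 + np.timedelta64(duration_s * 1000, "ms"),
                duration_min=duration_s / 60, max_depth_m=depth, mean_depth_m=depth / 2,
                hour_of_day=int((offset_s / 3600 - 5) % 24))


class TestSegmentTrips:
    def test_track_never_beyond_1km_gives_no_trips(self):
        s = make_series(np.zeros(20), np.full(20, 0.005))
        assert segment_trips(s, [dive_at(600)]) == []

    def test_three_engineered_excursions_found(self):
        s = series_with_excursions([24, 24, 24])  # 2-h excursions
        away = s.colony_dist_km > 1.0
        # one dive inside each away-run
        runs = np.flatnonzero(np.diff(away.astype(int)) == 1) + 1
        dives = [dive_at(int(i) * 300 + 100) for i in runs]
        trips = segment_trips(s, dives)
        assert len(trips) == 3
        assert audit_trips(trips)

    def test_short_excursion_filtered_by_duration(self):
        s = series_with_excursions([24])
        away = np.flatnonzero(s.colony_dist_km > 1.0)
        # keep only 3 away steps (20 min (3+1)*5 > 20 but ≤ for 3... use 2 steps)
        keep = away[:2]
        lats = np.full(len(s), 0.0)
        lats[keep] = 0.3
        s2 = make_series(np.zeros(len(s)), lats)
        trips = segment_trips(s2, [dive_at(int(keep[0]) * 300 + 10)], min_duration_min=20.0)
        # 2 consecutive away steps span 15 min < 20 → rejected
        assert trips == []

    def test_excursion_without_dive_rejected(self):
        s = series_with_excursions([24])
        assert segment_trips(s, []) == []


class TestTripSummary:
    def test_azimuth_due_east(self):
        lons = [0.0, 0.1, 0.2, 0.1, 0.0]
        s = make_series(lons, np.zeros(5))
        out = trip_summary_indices(s, 1, 4)
        assert out["azimuth_deg"] == pytest.approx(90.0, abs=0.1)

    def test_out_and_back_distances(self):
        lats = np.concatenate([np.linspace(0, 0.18, 10), np.linspace(0.18, 0, 10)[1:]])
        s = make_series(np.zeros(len(lats)), lats)
        out = trip_summary_indices(s, 0, len(lats))
        assert out["max_colony_distance_km"] == pytest.approx(0.18 * 111.195, rel=1e-3)
        # 20 km out plus 20 km back along the meridian
        assert out["total_path_km"] == pytest.approx(2 * 0.18 * 111.195, rel=1e-3)

    def test_single_step_trip_path_is_step_length(self):
        s = make_series([0.0, 0.1], [0.0, 0.0])
        out = trip_summary_indices(s, 1, 2)
        assert out["total_path_km"] == pytest.approx(s.step_km[1])

    def test_time_reversal_preserves_scalars(self):
        lats = np.concatenate([np.linspace(0, 0.2, 8), np.linspace(0.2, 0.02, 5)])
        fwd = make_series(np.zeros(len(lats)), lats)
        rev = make_series(np.zeros(len(lats)), lats[::-1])
        a = trip_summary_indices(fwd, 1, len(lats))
        b = trip_summary_indices(rev, 0, len(lats) - 1)
        assert a["max_colony_distance_km"] == pytest.approx(b["max_colony_distance_km"])


class TestHourlyDepth:
    def test_constant_depth_everywhere(self):
        dives = [dive_at(i * 3600, depth=20.0) for i in range(5)]
        hm = hourly_mean_depth(dives)
        defined = hm[np.isfinite(hm)]
        assert np.allclose(defined, 10.0)  # mean depth of a 20-m V dive object here is 10

    def test_two_dives_same_hour_average(self):
        d1, d2 = dive_at(0, depth=20.0), dive_at(60, depth=40.0)
        hm = hourly_mean_depth([d1, d2])
        assert hm[d1.hour_of_day] == pytest.approx(15.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hourly_mean_depth([])


class TestDifferentialDepth:
    def test_dive_at_hourly_mean_is_zero(self):
        d = dive_at(0, depth=20.0)
        hm = hourly_mean_depth([d])
        assert differential_depth(d, hm) == 0.0

    def test_missing_hour_rejected_by_name(self):
        d = dive_at(0)
        hm = np.full(24, np.nan)
        with pytest.raises(ValueError, match=str(d.hour_of_day)):
            differential_depth(d, hm)

    def test_six_dive_manual_oracle(self):
        """Hand-computed spreadsheet-style differentials."""
        specs = [(0, 10.0), (30, 30.0), (3700, 16.0), (3760, 24.0), (7300, 8.0), (7400, 12.0)]
        dives = [dive_at(off, depth=2 * d) for off, d in specs]  # mean depth = d
        hm = hourly_mean_depth(dives)
        # hours: two dives each in 3 consecutive hours; hourly means 20, 20, 10
        expected = [-10.0, 10.0, -4.0, 4.0, -2.0, 2.0]
        got = [differential_depth(d, hm) for d in dives]
        np.testing.assert_allclose(got, expected)


class TestDeploymentSummary:
    def _setup(self, excursions):
        s = series_with_excursions(excursions)
        away = s.colony_dist_km > 1.0
        runs = np.flatnonzero(np.diff(away.astype(int)) == 1) + 1
        dives = [dive_at(int(i) * 300 + 100) for i in runs]
        trips = segment_trips(s, dives)
        hm = hourly_mean_depth(dives)
        path = fake_path(np.where(away, "flying", "colony"))
        return s, dives, trips, hm, path

    def test_two_trip_means(self):
        s, dives, trips, hm, path = self._setup([24, 48])  # 2 h and 4 h away
        bm = deployment_summary(trips, dives, path, s, hm)
        assert bm.values["n_trips"] == 2
        assert bm.values["trip_duration_h_mean"] == pytest.approx(
            np.mean([t.duration_h for t in trips])
        )
        assert abs(trips[1].duration_h - trips[0].duration_h - 2.0) < 0.2

    def test_single_trip_sd_zero_with_flag(self):
        s, dives, trips, hm, path = self._setup([24])
        bm = deployment_summary(trips, dives, path, s, hm)
        assert bm.single_trip
        assert bm.values["trip_duration_h_sd"] == 0.0

    def test_daily_distance_is_total_over_span(self):
        s, dives, trips, hm, path = self._setup([24, 24])
        bm = deployment_summary(trips, dives, path, s, hm)
        span_days = (s.times[-1] - s.times[0]).astype("timedelta64[ms]").astype(float) / 86400000.0
        assert bm.values["daily_distance_km"] == pytest.approx(bm.values["total_distance_km"] / span_days)

    def test_activity_proportions_sum_to_one(self):
        s, dives, trips, hm, path = self._setup([24, 24])
        bm = deployment_summary(trips, dives, path, s, hm)
        tot = sum(bm.values[f"prop_{a}"] for a in ("colony", "diving", "flying", "swimming"))
        assert tot == pytest.approx(1.0, abs=1e-6)

    def test_no_trips_rejected(self):
        s = make_series(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            deployment_summary([], [], fake_path(["colony"] * 5), s, np.full(24, np.nan))
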