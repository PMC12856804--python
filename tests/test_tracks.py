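import numpy as np
import pandas as pd
import pytest

from pelagos import pipeline, synthetic, tracks
from pelagos.geo import destination, great_circle_km
from pelagos.tracks import Colony, Trip

from conftest import BIRD, make_fixes


def offset_point(colony, bearing, km):
    return destination(colony.lat, colony.lon, bearing, km)


class TestSpeedFilter:
    def test_stationary_track_untouched(self):
        f = make_fixes("b1", "2022-02-01", range(10), [-54.0] * 10, [-38.05] * 10)
        kept, removed = tracks.speed_filter(f)
        assert len(kept) == 10 and len(removed) == 0

    def test_single_outlier_removed(self):
        lat0, lon0 = -54.0, -38.05
        lat_far, lon_far = destination(lat0, lon0, 90.0, 150.0)
        f = make_fixes(
            "b1", "2022-02-01", [0, 1, 2], [lat0, lat_far, lat0], [lon0, lon_far, lon0]
        )
        kept, removed = tracks.speed_filter(f, vmax_kmh=80.0)
        assert len(removed) == 1
        assert removed.iloc[0]["lat"] == pytest.approx(lat_far)
        assert len(kept) == 2

    def test_duplicate_timestamps_rejected(self):
        f = make_fixes("b1", "2022-02-01", [0, 0, 1], [-54, -54, -54], [-38, -38, -38])
        with pytest.raises(ValueError, match="b1"):
            tracks.speed_filter(f)

    def test_synthetic_outliers_recovered_exactly(self):
        cfg = synthetic.compact_config(trips_per_colony=15, outlier_rate=0.01)
        ts = synthetic.simulate_tracks(cfg, seed=5)
        assert len(ts.outliers) > 0
        kept, removed = tracks.speed_filter(ts.fixes)
        got = set(zip(removed["bird_id"], removed["timestamp"]))
        truth = set(zip(ts.outliers["bird_id"], ts.outliers["timestamp"]))
        assert got == truth

    def test_no_fast_pairs_after_filter(self):
        cfg = synthetic.compact_config(trips_per_colony=10, outlier_rate=0.02)
        ts = synthetic.simulate_tracks(cfg, seed=9)
        kept, _ = tracks.speed_filter(ts.fixes)
        for _, g in kept.groupby("bird_id"):
            lat, lon = g["lat"].to_numpy(), g["lon"].to_numpy()
            d = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
            dt = np.diff(g["timestamp"].astype("int64").to_numpy()) / 3.6e12
            assert np.all(d / dt <= 80.0 + 1e-9)


class TestRegularize:
    def test_hourly_track_is_fixed_point(self):
        lats = np.linspace(-54.0, -53.0, 8)
        f = make_fixes("b1", "2022-02-01", range(8), lats, [-38.0] * 8)
        out = tracks.regularize(f)
        assert np.allclose(out["lat"].to_numpy(), lats)
        assert np.allclose(out["lon"].to_numpy(), -38.0)

    def test_midpoint_inserted(self):
        f = make_fixes("b1", "2022-02-01", [0, 2], [-54.0, -53.0], [-38.0, -37.0])
        out = tracks.regularize(f)
        assert len(out) == 3
        assert out.iloc[1]["lat"] == pytest.approx(-53.5)
        assert out.iloc[1]["lon"] == pytest.approx(-37.5)

    def test_long_gaps_not_bridged(self):
        f = make_fixes("b1", "2022-02-01", [0, 1, 30, 31], [-54.0] * 4, [-38.0] * 4)
        out = tracks.regularize(f, max_gap_h=12.0)
        hours = (out["timestamp"] - out["timestamp"].iloc[0]).dt.total_seconds() / 3600
        assert set(hours) == {0.0, 1.0, 30.0, 31.0}

    def test_dense_track_within_one_km_of_raw(self):
        # 5-min GPS fixes moving at 20 km/h: hourly marks must stay close
        rng = np.random.default_rng(2)
        n = 12 * 6
        heading = np.cumsum(rng.normal(0, 10, n))
        steps_km = 20.0 / 12
        lat, lon = [-54.0], [-38.0]
        for h in heading[:-1]:
            la, lo = destination(lat[-1], lon[-1], h % 360, steps_km)
            lat.append(la)
            lon.append(lo)
        f = make_fixes("b1", "2022-02-01", np.arange(n) / 12.0, lat, lon)
        out = tracks.regularize(f)
        for _, row in out.iterrows():
            d = great_circle_km(row["lat"], row["lon"], np.array(lat), np.array(lon))
            assert float(np.min(d)) < 1.0


class TestSplitTrips:
    def test_never_leaves_buffer(self):
        f = make_fixes("b1", "2022-02-01", range(20), [BIRD.lat] * 20, [BIRD.lon] * 20)
        assert tracks.split_trips(f, BIRD) == []

    def test_out_and_back_then_unfinished(self):
        far_lat, far_lon = offset_point(BIRD, 270.0, 100.0)
        lats = [BIRD.lat] * 2 + [far_lat] * 9 + [BIRD.lat] * 3 + [far_lat] * 5
        lons = [BIRD.lon] * 2 + [far_lon] * 9 + [BIRD.lon] * 3 + [far_lon] * 5
        f = make_fixes("b1", "2022-02-01", range(len(lats)), lats, lons)
        trips = tracks.split_trips(f, BIRD, min_trip_h=4.0)
        assert len(trips) == 2
        assert trips[0].complete and not trips[1].complete

    def test_short_excursions_discarded(self):
        far_lat, far_lon = offset_point(BIRD, 270.0, 30.0)
        lats = [BIRD.lat] * 2 + [far_lat] * 2 + [BIRD.lat] * 2
        lons = [BIRD.lon] * 2 + [far_lon] * 2 + [BIRD.lon] * 2
        f = make_fixes("b1", "2022-02-01", range(6), lats, lons)
        assert tracks.split_trips(f, BIRD, min_trip_h=6.0) == []

    def test_warning_when_never_at_colony(self):
        far_lat, far_lon = offset_point(BIRD, 90.0, 500.0)
        f = make_fixes("b1", "2022-02-01", range(5), [far_lat] * 5, [far_lon] * 5)
        with pytest.warns(UserWarning, match="buffer"):
            assert tracks.split_trips(f, BIRD) == []

    def test_synthetic_trip_count_recovered(self, compact_trackset, colonies):
        cfg, ts = compact_trackset
        fixes = pipeline.clean_tracks(ts.fixes)
        for colony in colonies:
            trips = pipeline.colony_trips(
                fixes, colony, stage_windows=cfg.stage_windows()
            )
            assert len(trips) == ts.trip_counts[colony.name]

    def test_non_buffer_fixes_partitioned(self, compact_trackset, colonies):
        cfg, ts = compact_trackset
        colony = colonies[0]
        sel = ts.fixes[ts.fixes["colony"] == colony.name]
        trips = tracks.split_trips(sel, colony)
        dist = great_circle_km(
            colony.lat, colony.lon, sel["lat"].to_numpy(), sel["lon"].to_numpy()
        )
        outside = sel[np.atleast_1d(dist) > colony.buffer_km]
        covered = pd.concat([t.fixes for t in trips])
        keys_out = set(zip(outside["bird_id"], outside["timestamp"]))
        keys_cov = set(zip(covered["bird_id"], covered["timestamp"]))
        assert keys_out <= keys_cov
        # and no outside fix is in two trips
        n_outside_in_trips = sum(
            (great_circle_km(colony.lat, colony.lon, t.fixes["lat"].to_numpy(),
                             t.fixes["lon"].to_numpy()) > colony.buffer_km).sum()
            for t in trips
        )
        assert n_outside_in_trips == len(outside)


def _trip(start, dur_h, attendance=np.nan, complete=True):
    far_lat, far_lon = offset_point(BIRD, 270.0, 80.0)
    f = make_fixes(
        "b1",
        start,
        [0, dur_h / 2, dur_h],
        [BIRD.lat, far_lat, BIRD.lat],
        [BIRD.lon, far_lon, BIRD.lon],
    )
    return Trip("t", "b1", BIRD.name, f, complete, attendance_after_h=attendance)


class TestInferStage:
    def test_february_is_incubation(self):
        (t,) = tracks.infer_stage([_trip("2022-02-10", 48.0)])
        assert t.stage == "incubation"

    def test_june_is_postguard(self):
        (t,) = tracks.infer_stage([_trip("2022-06-10", 48.0)])
        assert t.stage == "postguard"

    def test_april_overlap_with_long_attendance_is_brood(self):
        # ends 10 April, followed by 20 h at the nest -> brood guard
        (t,) = tracks.infer_stage([_trip("2022-04-08", 48.0, attendance=20.0)])
        assert t.stage == "brood_guard"

    def test_april_overlap_with_short_attendance_is_postguard(self):
        (t,) = tracks.infer_stage([_trip("2022-04-08", 48.0, attendance=5.0)])
        assert t.stage == "postguard"

    def test_march_overlap_with_long_attendance_is_incubation(self):
        (t,) = tracks.infer_stage([_trip("2022-03-10", 48.0, attendance=30.0)])
        assert t.stage == "incubation"


class TestTripMetrics:
    def test_out_and_back_hand_case(self):
        far_lat, far_lon = offset_point(BIRD, 270.0, 30.0)
        f = make_fixes(
            "b1",
            "2022-02-01",
            [0, 1, 2],
            [BIRD.lat, far_lat, BIRD.lat],
            [BIRD.lon, far_lon, BIRD.lon],
        )
        m = tracks.trip_metrics(Trip("t", "b1", BIRD.name, f, True), BIRD)
        assert m.duration_h == pytest.approx(2.0)
        assert m.total_distance_km == pytest.approx(60.0, rel=1e-6)
        assert m.foraging_range_km == pytest.approx(30.0, rel=1e-6)
        assert m.bearing_far_deg == pytest.approx(270.0, abs=0.5)

    def test_total_distance_invariant_to_collinear_midpoints(self):
        far_lat, far_lon = offset_point(BIRD, 270.0, 100.0)
        base = make_fixes(
            "b1", "2022-02-01", [0, 4], [BIRD.lat, far_lat], [BIRD.lon, far_lon]
        )
        dense = tracks.regularize(base)
        m1 = tracks.trip_metrics(Trip("t", "b1", BIRD.name, base, False), BIRD)
        m2 = tracks.trip_metrics(Trip("t", "b1", BIRD.name, dense, False), BIRD)
        assert m2.total_distance_km == pytest.approx(m1.total_distance_km, rel=1e-3)

    def test_incomplete_trips_excluded_from_summary(self):
        trips = [_trip("2022-02-01", 24.0), _trip("2022-02-05", 24.0, complete=False)]
        tracks.infer_stage(trips)
        table = tracks.summarize_trips(trips, BIRD)
        assert len(table) == 1
        assert table["complete"].all()

    def test_synthetic_range_scale_matches_generator(self, compact_trackset, colonies):
        # outbound ~35% of a 24 h trip at ~20 km/h -> ranges of order 170 km
        cfg, ts = compact_trackset
        fixes = pipeline.clean_tracks(ts.fixes)
        trips = pipeline.colony_trips(
            fixes, colonies[0], stage_windows=cfg.stage_windows()
        )
        table = tracks.summarize_trips(trips, colonies[0])
        med = table["duration_h"].median()
        assert med == pytest.approx(cfg.stages["brood_guard"].duration_median_h, rel=0.3)
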