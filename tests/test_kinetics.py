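"""Classification, segmentation, kinetic estimation and speed tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon

import patchforage as pf
from patchforage.core import DwellInterval, StateSegmentation, TrackRecording
from patchforage.kinetics import (
    PatchKineticsModel,
    classify_frame,
    compute_speeds,
    estimate_kinetics,
    interpolate_gaps,
    segment_states,
)


class TestClassifyFrame:
    def test_both_points_on_food(self, square_patch):
        assert classify_frame((0.2, 0.2), (-0.2, 0.1), square_patch) == "F"

    def test_exactly_one_point_on_food(self, square_patch):
        assert classify_frame((0.5, 0.0), (3.0, 0.0), square_patch) == "B"

    def test_neither_point_on_food(self, square_patch):
        assert classify_frame((2.0, 2.0), (3.0, 3.0), square_patch) == "O"

    def test_boundary_point_counts_as_contact(self, square_patch):
        assert classify_frame((1.0, 0.0), (0.0, 0.0), square_patch) == "F"

    def test_delta_extends_contact_zone(self, square_patch):
        head, tail = (1.3, 0.0), (4.0, 0.0)
        assert classify_frame(head, tail, square_patch, delta=0.0) == "O"
        assert classify_frame(head, tail, square_patch, delta=0.5) == "B"

    def test_degenerate_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            classify_frame((0, 0), (1, 1), bowtie)

    def test_nonfinite_point_rejected(self, square_patch):
        with pytest.raises(ValueError):
            classify_frame((np.nan, 0.0), (0.0, 0.0), square_patch)


class TestSegmentStates:
    def test_constant_labels_single_censored_interval(self):
        t = np.arange(10) * 0.5
        seg = segment_states(["F"] * 10, t)
        assert len(seg.intervals) == 1
        iv = seg.intervals[0]
        assert iv.state == "F" and iv.censored_start and iv.censored_end
        assert (iv.t_start, iv.t_end) == (0.0, 4.5)

    def test_repair_inserts_one_frame_border_interval(self):
        seg = segment_states(["F", "F", "O", "O"], [0.0, 0.5, 1.0, 1.5])
        states = [iv.state for iv in seg.intervals]
        assert states == ["F", "B", "O"]
        b = seg.intervals[1]
        assert b.duration == pytest.approx(0.5)
        assert (b.t_start, b.t_end) == (0.5, 1.0)

    def test_debounce_merges_single_frame_blip(self):
        t = np.arange(5) * 0.5
        seg = segment_states(["F", "F", "B", "F", "F"], t, debounce=2)
        assert [iv.state for iv in seg.intervals] == ["F"]

    def test_debounce_off_by_default(self):
        t = np.arange(5) * 0.5
        seg = segment_states(["F", "F", "B", "F", "F"], t)
        assert [iv.state for iv in seg.intervals] == ["F", "B", "F"]

    def test_boundaries_at_frame_midpoints(self):
        seg = segment_states(["F", "B"], [0.0, 1.0])
        assert seg.intervals[0].t_end == pytest.approx(0.5)

    def test_empty_and_nonmonotonic_rejected(self):
        with pytest.raises(ValueError):
            segment_states([], [])
        with pytest.raises(ValueError):
            segment_states(["F", "F"], [1.0, 0.5])

    def test_intervals_tile_recording(self):
        rng = np.random.default_rng(0)
        labels = np.array(list("FBO"))[rng.integers(0, 3, 200)]
        t = np.arange(200) * 0.2
        seg = segment_states(labels, t)
        assert seg.total_time == pytest.approx(t[-1] - t[0])
        for a, b in zip(seg.intervals[:-1], seg.intervals[1:]):
            assert a.t_end == pytest.approx(b.t_start)

    @given(st.lists(st.sampled_from("FBO"), min_size=2, max_size=80))
    def test_no_direct_food_offfood_adjacency_survives_repair(self, labels):
        t = np.arange(len(labels), dtype=float)
        seg = segment_states(labels, t)
        for a, b in zip(seg.intervals[:-1], seg.intervals[1:]):
            assert {a.state, b.state} != {"F", "O"}
            assert a.state != b.state


def _make_seg(spec):
    """Build a segmentation from (state, duration) pairs."""
    intervals, t = [], 0.0
    for i, (s, d) in enumerate(spec):
        intervals.append(
            DwellInterval(s, t, t + d, censored_start=i == 0,
                          censored_end=i == len(spec) - 1)
        )
        t += d
    return StateSegmentation(intervals, None, None)


class TestEstimateKinetics:
    def test_state_probabilities_are_time_fractions(self):
        seg = _make_seg([("F", 300), ("B", 50), ("O", 100), ("B", 50)])
        est = estimate_kinetics(seg)
        assert (est.P_F, est.P_B, est.P_O) == (0.6, 0.2, 0.2)

    def test_rate_constant_per_minute(self):
        # three F->B transitions over 300 s in F -> 0.6 per min
        seg = _make_seg(
            [("F", 100), ("B", 10), ("F", 100), ("B", 10),
             ("F", 100), ("B", 10), ("O", 30)]
        )
        est = estimate_kinetics(seg)
        assert est.N_FB == 3 and est.T_F == 300
        assert est.k_FB == pytest.approx(0.6)

    def test_censored_terminal_edge_contributes_no_transition(self):
        seg = _make_seg([("F", 100), ("B", 50)])
        est = estimate_kinetics(seg)
        assert est.N_FB == 1  # interior junction only
        assert est.N_BF == est.N_BO == 0

    def test_unvisited_state_rate_is_nan_not_zero(self):
        seg = _make_seg([("F", 100), ("B", 50)])
        est = estimate_kinetics(seg)
        assert np.isnan(est.k_OB)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        labels = np.array(list("FBO"))[rng.integers(0, 3, 500)]
        seg = segment_states(labels, np.arange(500) * 0.5)
        est = estimate_kinetics(seg)
        assert est.P_F + est.P_B + est.P_O == pytest.approx(1.0, abs=1e-12)

    def test_illegal_adjacency_without_repair_rejected(self):
        seg = segment_states(["F", "O"], [0.0, 0.5], repair=False)
        with pytest.raises(ValueError):
            estimate_kinetics(seg)


class TestSpeeds:
    def _track(self, xy, arena, dt=0.5):
        n = len(xy)
        xy = np.asarray(xy, float)
        df = pd.DataFrame({
            "frame": np.arange(n), "time_s": np.arange(n) * dt,
            "head_x_mm": xy[:, 0], "head_y_mm": xy[:, 1],
            "tail_x_mm": xy[:, 0], "tail_y_mm": xy[:, 1],
            "centroid_x_mm": xy[:, 0], "centroid_y_mm": xy[:, 1],
        })
        return TrackRecording(df, arena)

    def test_stationary_centroid_zero_speed(self, arena):
        track = self._track([(3.0, 0.0)] * 10, arena)
        s = compute_speeds(track, ["F"] * 5 + ["O"] * 5)
        assert s.speed_on == 0.0 and s.speed_off == 0.0

    def test_straight_line_speed(self, arena):
        # 0.05 mm per 0.5 s frame = 0.1 mm/s, all off food
        xy = [(3.0 + 0.05 * i, 0.0) for i in range(20)]
        track = self._track(xy, arena)
        s = compute_speeds(track, ["O"] * 20)
        assert s.speed_off == pytest.approx(0.1)
        assert np.isnan(s.speed_on)

    def test_single_frame_rejected(self, arena):
        with pytest.raises(ValueError):
            compute_speeds(self._track([(0.0, 0.0)], arena), ["F"])

    def test_recovery_from_simulated_tracks(self, arena, short_params):
        tracks = pf.simulate_tracks(6, arena, short_params, seed=21)
        res = PatchKineticsModel(tracks).fit()
        assert res.per_worm.speed_on.mean() == pytest.approx(0.05, rel=0.10)
        assert res.per_worm.speed_off.mean() == pytest.approx(0.15, rel=0.10)


class TestEquivariance:
    def test_rigid_motion_of_track_and_patch_preserves_everything(self, short_track):
        import shapely.affinity as aff

        res0 = PatchKineticsModel([short_track]).fit()
        theta, dx, dy = 37.0, 2.5, -1.1
        df = short_track.frames.copy()
        c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        for prefix in ("head", "tail", "centroid"):
            x = df[f"{prefix}_x_mm"].to_numpy()
            y = df[f"{prefix}_y_mm"].to_numpy()
            df[f"{prefix}_x_mm"] = c * x - s * y + dx
            df[f"{prefix}_y_mm"] = s * x + c * y + dy
        patch = aff.translate(
            aff.rotate(short_track.arena.patch, theta, origin=(0, 0)), dx, dy
        )
        moved = TrackRecording(df, short_track.arena, "moved")
        labels0 = pf.classify_frames(short_track)
        labels1 = pf.classify_frames(moved, patch=patch)
        assert (labels0 == labels1).all()
        seg = segment_states(labels1, moved.times)
        est = estimate_kinetics(seg)
        np.testing.assert_allclose(
            est.as_series().to_numpy(float),
            res0.pooled.as_series().to_numpy(float), rtol=1e-9, equal_nan=True,
        )
        s1 = compute_speeds(moved, labels1)
        s0 = compute_speeds(short_track, labels0)
        assert s1.speed_on == pytest.approx(s0.speed_on, rel=1e-9)
        assert s1.speed_off == pytest.approx(s0.speed_off, rel=1e-9)


class TestGaps:
    def _frames(self, n=20, dt=0.5):
        t = np.arange(n) * dt
        return pd.DataFrame({
            "frame": np.arange(n), "time_s": t,
            "head_x_mm": t, "head_y_mm": 0.0,
            "tail_x_mm": t, "tail_y_mm": 0.0,
            "centroid_x_mm": t, "centroid_y_mm": 0.0,
        })

    def test_short_gap_interpolated(self):
        df = self._frames()
        df.loc[5:6, ["head_x_mm", "tail_x_mm", "centroid_x_mm"]] = np.nan
        parts = interpolate_gaps(df, max_gap_s=2.0)
        assert len(parts) == 1
        # linear in time, so interpolation restores the line exactly
        np.testing.assert_allclose(
            parts[0]["centroid_x_mm"], parts[0]["time_s"], atol=1e-12
        )

    def test_long_gap_splits_recording(self):
        df = self._frames(30)
        df.loc[10:16, ["head_x_mm", "tail_x_mm", "centroid_x_mm"]] = np.nan  # 3.5 s
        parts = interpolate_gaps(df, max_gap_s=2.0)
        assert len(parts) == 2
        assert len(parts[0]) == 10 and len(parts[1]) == 13


class TestModelResults:
    def test_per_worm_table_and_pooled(self, arena, short_params):
        tracks = pf.simulate_tracks(3, arena, short_params, seed=2)
        res = PatchKineticsModel(tracks).fit()
        assert len(res.per_worm) == 3
        sums = res.per_worm[["P_F", "P_B", "P_O"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert res.pooled.P_F + res.pooled.P_B + res.pooled.P_O == pytest.approx(1.0)
        text = res.summary()
        assert "Pooled" in text and "k_FB" in text

    def test_ilr_coordinates_finite(self, arena, short_params):
        tracks = pf.simulate_tracks(2, arena, short_params, seed=3)
        z = PatchKineticsModel(tracks).fit().ilr()
        assert np.isfinite(z[["z1", "z2"]].to_numpy()).all()
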