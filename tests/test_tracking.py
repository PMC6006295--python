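"""Background modelling, segmentation, trajectory and stop-bout extraction."""

import numpy as np
import pytest

from lumitrack import tracking as tk
from lumitrack.synthdata import marker_roi, simulate_session
from lumitrack.videoio import VideoSequence

from conftest import fast_config, oracle_largest_component


def _video(frames, frame_ms=50.0):
    return VideoSequence(frames=np.asarray(frames, dtype=np.uint8),
                         frame_ms=frame_ms)


class TestBackground:
    def test_static_scene_background_equals_any_frame(self):
        frame = np.random.default_rng(0).integers(0, 50, (20, 20))
        video = _video(np.repeat(frame[None], 10, axis=0))
        np.testing.assert_array_equal(tk.build_background(video, 5), frame)

    def test_all_zero_frames_give_zero_background(self):
        video = _video(np.zeros((5, 8, 8)))
        np.testing.assert_array_equal(tk.build_background(video, 3), 0.0)

    def test_transiently_occupied_pixel_takes_dark_median(self):
        # larva covers pixel (3, 3) in 2 of 7 frames: the median over the
        # stack must come from the dark values, not the larva value
        frames = np.full((7, 8, 8), 10, dtype=np.uint8)
        frames[2, 3, 3] = 200
        frames[4, 3, 3] = 200
        video = _video(frames)
        bg = tk.build_background(video, 7)
        assert bg[3, 3] == np.median(frames[:, 3, 3])
        assert bg[3, 3] == 10

    def test_too_few_frames_error_and_short_video_warning(self):
        with pytest.raises(ValueError):
            tk.build_background(_video(np.zeros((2, 4, 4))), 3)
        with pytest.warns(UserWarning):
            tk.build_background(_video(np.zeros((4, 4, 4))), 10)


class TestSegmentation:
    def test_uniform_square_centroid_and_area(self):
        frame = np.zeros((32, 40), dtype=np.uint8)
        frame[10:15, 20:25] = 100
        bg = np.zeros((32, 40))
        got = tk.segment_larva(frame, bg,
                               tk.TrackingParams(thresh=10, min_area=5))
        assert got == (pytest.approx(22.0), pytest.approx(12.0), 25)

    def test_small_component_filtered_by_min_area(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[5:15, 5:15] = 100       # 100 px
        frame[30:33, 30:33] = 100     # 9 px
        got = tk.segment_larva(frame, np.zeros((40, 40)),
                               tk.TrackingParams(thresh=10, min_area=20))
        assert got is not None
        x, y, area = got
        assert area == 100
        assert (x, y) == (pytest.approx(9.5), pytest.approx(9.5))

    def test_empty_difference_image_yields_none(self):
        frame = np.full((16, 16), 7, dtype=np.uint8)
        assert tk.segment_larva(frame, np.full((16, 16), 7.0),
                                tk.TrackingParams(thresh=5)) is None

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            tk.segment_larva(np.zeros((8, 8), dtype=np.uint8),
                             np.zeros((9, 9)))

    def test_marker_roi_is_excluded_from_segmentation(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[0:8, 0:8] = 255          # shutter marker
        frame[20:26, 20:26] = 100      # larva, smaller but the only candidate
        got = tk.segment_larva(
            frame, np.zeros((40, 40)),
            tk.TrackingParams(thresh=10, min_area=5,
                              marker_roi=(slice(0, 8), slice(0, 8))))
        assert got is not None
        assert got[0] == pytest.approx(22.5)

    def test_matches_brute_force_oracle_on_random_scenes(self):
        rng = np.random.default_rng(42)
        params = tk.TrackingParams(thresh=0.5, min_area=3, max_area=400)
        for _ in range(40):
            h, w = rng.integers(8, 33, size=2)
            img = (rng.random((h, w)) < 0.35).astype(np.uint8) * 100
            got = tk.segment_larva(img, np.zeros((h, w)), params)
            want = oracle_largest_component(img.astype(float), 0.5, 3, 400)
            if want is None:
                assert got is None
            else:
                assert got[2] == want[2]
                assert got[0] == pytest.approx(want[0])
                assert got[1] == pytest.approx(want[1])

    def test_translation_equivariance(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[10:16, 8:20] = 120
        params = tk.TrackingParams(thresh=10, min_area=5)
        x0, y0, _ = tk.segment_larva(frame, np.zeros((40, 40)), params)
        shifted = np.roll(np.roll(frame, 7, axis=0), 3, axis=1)
        x1, y1, _ = tk.segment_larva(shifted, np.zeros((40, 40)), params)
        assert (x1 - x0, y1 - y0) == (pytest.approx(3.0), pytest.approx(7.0))

    def test_intensity_scale_invariance(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[10:16, 8:20] = 60
        bg = np.zeros((40, 40))
        p1 = tk.TrackingParams(thresh=10, min_area=5)
        p2 = tk.TrackingParams(thresh=20, min_area=5)
        r1 = tk.segment_larva(frame, bg, p1)
        r2 = tk.segment_larva(frame * 2, bg * 2, p2)
        assert r1[:2] == pytest.approx(r2[:2])
        assert r1[2] == r2[2]


class TestTrack:
    def test_noise_free_session_recovers_truth_positions(self):
        cfg = fast_config(video_noise_sigma=0.0, n_frames=200, rng_seed=7)
        s = simulate_session(cfg)
        traj = tk.track(s.video, tk.TrackingParams(marker_roi=marker_roi(cfg)))
        assert traj.valid_mask.all()
        err = np.hypot(*(traj.positions - s.truth.positions).T)
        assert err.max() <= 0.5

    def test_short_gaps_are_linearly_interpolated(self):
        cfg = fast_config(video_noise_sigma=0.0, n_frames=30, rng_seed=3, shutter_open_time_ms=0.0)
        s = simulate_session(cfg)
        frames = s.video.frames.copy()
        frames[10:12] = s.video.frames[0] * 0  # larva vanishes for 2 frames
        video = VideoSequence(frames=frames, frame_ms=cfg.frame_ms)
        traj = tk.track(video, tk.TrackingParams(
            marker_roi=marker_roi(cfg), max_gap=2))
        d = traj.data
        assert d.loc[10, "interpolated"] and d.loc[11, "interpolated"]
        for i, w in ((10, 1 / 3), (11, 2 / 3)):
            want_x = d.loc[9, "x_px"] + w * (d.loc[12, "x_px"] - d.loc[9, "x_px"])
            want_y = d.loc[9, "y_px"] + w * (d.loc[12, "y_px"] - d.loc[9, "y_px"])
            assert d.loc[i, "x_px"] == pytest.approx(want_x)
            assert d.loc[i, "y_px"] == pytest.approx(want_y)

    def test_long_gaps_stay_invalid(self):
        cfg = fast_config(video_noise_sigma=0.0, n_frames=30, rng_seed=3, shutter_open_time_ms=0.0)
        s = simulate_session(cfg)
        frames = s.video.frames.copy()
        frames[10:16] = 0
        video = VideoSequence(frames=frames, frame_ms=cfg.frame_ms)
        traj = tk.track(video, tk.TrackingParams(
            marker_roi=marker_roi(cfg), max_gap=2))
        assert not traj.data.loc[10:15, "valid"].any()

    def test_all_dark_video_yields_empty_trajectory(self):
        video = _video(np.zeros((20, 30, 30)))
        traj = tk.track(video, tk.TrackingParams())
        assert not traj.valid_mask.any()
        assert np.isnan(traj.positions).all()

    def test_track_file_round_trip(self, tmp_path):
        cfg = fast_config(n_frames=40, rng_seed=1)
        s = simulate_session(cfg)
        traj = tk.track(s.video, tk.TrackingParams(marker_roi=marker_roi(cfg)))
        path = tmp_path / "track.tsv"
        tk.write_track(traj, path)
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == ["frame", "time_ms", "x_px", "y_px",
                                      "area_px", "valid", "interpolated"]
        loaded = tk.read_track(path)
        np.testing.assert_allclose(loaded.positions, traj.positions, atol=1e-3)


class TestSpeed:
    def _traj_from_positions(self, pos, frame_ms=50.0):
        import pandas as pd
        n = len(pos)
        data = pd.DataFrame({
            "frame": np.arange(n),
            "time_ms": np.arange(n) * frame_ms,
            "x_px": [p[0] for p in pos], "y_px": [p[1] for p in pos],
            "area_px": 25.0, "valid": True, "interpolated": False,
        })
        return tk.Trajectory(data=data, frame_ms=frame_ms)

    def test_straight_unit_steps_give_constant_speed(self):
        traj = self._traj_from_positions([(i, 0.0) for i in range(20)])
        speed = tk.compute_speed(traj, smooth_win=5)
        np.testing.assert_allclose(speed[1:], 20.0)  # 1 px / 50 ms

    def test_stationary_larva_has_zero_speed(self):
        traj = self._traj_from_positions([(5.0, 5.0)] * 20)
        speed = tk.compute_speed(traj, smooth_win=5)
        np.testing.assert_allclose(speed[1:], 0.0)

    def test_alternating_axis_steps_same_speed_as_straight(self):
        pos, p = [], [0.0, 0.0]
        for i in range(20):
            pos.append(tuple(p))
            p[i % 2] += 1.0
        speed = tk.compute_speed(self._traj_from_positions(pos), smooth_win=1)
        np.testing.assert_allclose(speed[1:], 20.0)

    def test_too_few_valid_frames_gives_all_missing(self):
        traj = self._traj_from_positions([(0, 0)])
        assert np.isnan(tk.compute_speed(traj)).all()


class TestStops:
    def test_fully_stationary_trace_is_one_bout(self):
        t = np.arange(0, 60_000, 50.0)
        bouts = tk.detect_stops(t, np.zeros(t.size), 1.0, 2_000.0)
        assert len(bouts) == 1
        start, end = bouts[0]
        assert start == 0.0
        assert end == pytest.approx(60_000.0)

    def test_fast_crawling_has_no_stops(self):
        t = np.arange(0, 60_000, 50.0)
        assert tk.detect_stops(t, np.full(t.size, 5.0), 1.0, 2_000.0) == []

    def test_brief_dips_below_threshold_are_ignored(self):
        t = np.arange(0, 10_000, 50.0)
        speed = np.full(t.size, 5.0)
        speed[40:50] = 0.0  # 500 ms < min_stop
        assert tk.detect_stops(t, speed, 1.0, 2_000.0) == []

    def test_nearby_bouts_merge(self):
        t = np.arange(0, 20_000, 50.0)
        speed = np.full(t.size, 5.0)
        speed[40:100] = 0.0    # 2-5 s
        speed[106:166] = 0.0   # 5.3-8.3 s, gap 300 ms < merge_gap
        bouts = tk.detect_stops(t, speed, 1.0, 2_000.0, merge_gap_ms=500.0)
        assert len(bouts) == 1

    def test_recovers_simulated_co2_stop(self, puff_session):
        s = puff_session
        traj = tk.track(s.video, tk.TrackingParams(
            marker_roi=marker_roi(s.config)))
        speed = tk.compute_speed(traj, 5)
        bouts = tk.detect_stops(traj.data["time_ms"].to_numpy(), speed,
                                1.0, 2_000.0)
        (ts, te), = s.truth.stop_intervals
        best = 0.0
        for bs, be in bouts:
            inter = max(0.0, min(te, be) - max(ts, bs))
            union = max(te, be) - min(ts, bs)
            best = max(best, inter / union)
        assert best >= 0.8


class TestNoiseRobustness:
    @pytest.mark.parametrize("sigma", [2.0, 5.0])
    def test_position_and_speed_recovery_under_noise(self, sigma):
        cfg = fast_config(video_noise_sigma=sigma, n_frames=300, rng_seed=9)
        s = simulate_session(cfg)
        traj = tk.track(s.video, tk.TrackingParams(marker_roi=marker_roi(cfg)))
        err = np.hypot(*(traj.positions - s.truth.positions).T)
        assert np.nanmedian(err) <= 1.0
        speed = tk.compute_speed(traj, 5)
        true_speed = cfg.larva_speed_px_s
        rmse = np.sqrt(np.nanmean((speed[5:] - true_speed) ** 2))
        assert rmse <= 0.1 * true_speed
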