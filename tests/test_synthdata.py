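"""The synthetic rig: kinematics, photon statistics, video and gas streams."""

import numpy as np
import pytest

from lumitrack.config import PuffEvent, SessionConfig
from lumitrack.synthdata import (GroundTruth, ca_kernel, marker_roi,
                                 simulate_gas_trace, simulate_larva_path,
                                 simulate_photon_trace, simulate_session,
                                 simulate_video, true_co2_ppm, load_session,
                                 write_session)
from lumitrack.gas_sensor import ppm_to_voltage

from conftest import fast_config


class TestLarvaPath:
    def test_noise_free_path_is_straight_with_constant_step(self):
        cfg = fast_config(turn_sigma_rad=0.0, larva_speed_px_s=8.0,
                          n_frames=60)  # short enough to stay off the wall
        rng = np.random.default_rng(0)
        pos, _, stops = simulate_larva_path(cfg, rng)
        steps = np.hypot(*np.diff(pos, axis=0).T)
        expected = 8.0 * cfg.frame_ms / 1000.0
        assert stops == []
        np.testing.assert_allclose(steps, expected, rtol=1e-9)
        # collinear: cross products of consecutive steps vanish
        d = np.diff(pos, axis=0)
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    def test_certain_co2_stop_starts_at_configured_latency(self):
        cfg = fast_config(
            n_frames=600,
            puff_events=[PuffEvent(time_ms=10_000.0, kind="co2")])
        cfg.stop_response.prob = 1.0
        cfg.stop_response.latency_ms = 1_500.0
        cfg.stop_response.duration_ms = 5_000.0
        _, _, stops = simulate_larva_path(cfg, np.random.default_rng(1))
        assert len(stops) == 1
        start, end = stops[0]
        assert start == pytest.approx(11_500.0)
        assert end - start == pytest.approx(5_000.0)

    def test_air_puff_does_not_stop_crawling(self):
        cfg = fast_config(
            n_frames=600,
            puff_events=[PuffEvent(time_ms=10_000.0, kind="air")])
        cfg.stop_response.prob = 1.0
        pos, _, stops = simulate_larva_path(cfg, np.random.default_rng(1))
        assert stops == []
        steps = np.hypot(*np.diff(pos, axis=0).T)
        assert steps.min() > 0  # never stationary

    def test_seed_determinism(self):
        cfg = fast_config(rng_seed=5)
        a = simulate_session(cfg)
        b = simulate_session(fast_config(rng_seed=5))
        c = simulate_session(fast_config(rng_seed=6))
        np.testing.assert_array_equal(a.truth.positions, b.truth.positions)
        np.testing.assert_array_equal(a.video.frames, b.video.frames)
        np.testing.assert_array_equal(a.pmt.counts_au, b.pmt.counts_au)
        assert not np.array_equal(a.truth.positions, c.truth.positions)

    def test_path_stays_inside_arena(self):
        cfg = fast_config(n_frames=2_000, turn_sigma_rad=0.05,
                          larva_speed_px_s=20.0, rng_seed=2)
        pos, _, _ = simulate_larva_path(cfg, np.random.default_rng(2))
        cx, cy = cfg.arena_center
        r = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
        assert r.max() <= cfg.arena_radius_px

    def test_zero_duration_session_rejected(self):
        with pytest.raises(ValueError):
            fast_config(n_frames=0)


class TestPhotonTrace:
    def _dark_only(self, dark_au_s, n_frames, seed=0):
        cfg = fast_config(
            n_frames=n_frames, dark_rate_au_s=dark_au_s,
            baseline_lum_au_s=0.0, shutter_open_time_ms=0.0)
        cfg.prior_light.amplitude_au_s = 0.0
        cfg.ca_transient.amplitude_au_s = 0.0
        return simulate_photon_trace(cfg, [], np.random.default_rng(seed))

    def test_dark_only_mean_matches_poisson_law(self):
        # 5 au per 100 ms bin over 10,000 bins: SD of the mean is
        # sqrt(lambda/n), so 3 sigma = 3*sqrt(5/10000)
        trace = self._dark_only(dark_au_s=50.0, n_frames=20_000)
        assert trace.n_bins == 10_000
        assert abs(trace.counts_au.mean() - 5.0) < 3 * np.sqrt(5.0 / 10_000)

    def test_dark_only_fano_factor_near_one(self):
        trace = self._dark_only(dark_au_s=50.0, n_frames=20_000)
        fano = trace.counts_au.var() / trace.counts_au.mean()
        assert 0.8 < fano < 1.2

    def test_shutter_gating_blocks_light_terms(self):
        cfg = fast_config(n_frames=2_000, dark_rate_au_s=50.0,
                          baseline_lum_au_s=500.0,
                          shutter_open_time_ms=100_000.0)  # never opens
        cfg.prior_light.amplitude_au_s = 300.0
        closed = simulate_photon_trace(cfg, [], np.random.default_rng(3))
        dark = self._dark_only(dark_au_s=50.0, n_frames=2_000, seed=3)
        np.testing.assert_array_equal(closed.counts_au, dark.counts_au)

    def test_co2_response_peaks_later_than_one_minute(self):
        # slow evoked rise: with 60 s rise / 90 s decay constants the
        # kernel peak falls beyond 60 s after the puff
        t = np.linspace(0, 600, 6_001)
        k = ca_kernel(t, rise_s=60.0, decay_s=90.0)
        assert t[np.argmax(k)] > 60.0
        assert k.max() == pytest.approx(1.0, abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            fast_config(dark_rate_au_s=-1.0)


class TestVideo:
    def test_centroid_of_noise_free_blob_matches_truth(self):
        cfg = fast_config(video_noise_sigma=0.0, bg_level=0.0, n_frames=3,
                          shutter_open_time_ms=0.0)
        pos = np.array([[40.0, 60.0]] * 3)
        head = np.zeros(3)
        vid = simulate_video(cfg, pos, head, shutter_frame=0,
                             rng=np.random.default_rng(0))
        f = vid.frames[0].astype(float)
        f[marker_roi(cfg)] = 0.0
        ys, xs = np.mgrid[0:f.shape[0], 0:f.shape[1]]
        cx = (f * xs).sum() / f.sum()
        cy = (f * ys).sum() / f.sum()
        assert abs(cx - 40.0) < 0.1
        assert abs(cy - 60.0) < 0.1

    def test_marker_roi_switches_dark_to_bright_at_shutter_frame(self):
        cfg = fast_config(n_frames=40, shutter_open_time_ms=1_000.0)
        s = simulate_session(cfg)
        roi = marker_roi(cfg)
        means = s.video.frames[:, roi[0], roi[1]].mean(axis=(1, 2))
        sf = s.truth.shutter_frame
        assert means[:sf].max() < 60
        assert means[sf:].min() > 180

    def test_marker_switch_frame_independent_of_seed(self):
        frames = []
        for seed in (1, 2):
            cfg = fast_config(n_frames=60, shutter_open_time_ms=1_000.0,
                              rng_seed=seed)
            frames.append(simulate_session(cfg).truth.shutter_frame)
        assert frames[0] == frames[1]

    def test_oversized_larva_rejected(self):
        with pytest.raises(ValueError):
            fast_config(arena_radius_px=5.0, larva_axes_px=(12.0, 5.0))


class TestGasTrace:
    def test_quiet_chamber_gives_constant_atmospheric_voltage(self):
        cfg = fast_config(gas_noise_V=0.0, adc_bits=0)
        trace, ppm = simulate_gas_trace(cfg, np.random.default_rng(0))
        expected = ppm_to_voltage(400.0, cfg.sensor_params)
        np.testing.assert_allclose(trace.voltage_V, expected, rtol=1e-12)
        np.testing.assert_allclose(ppm, 400.0)

    def test_co2_puff_lowers_voltage_under_decreasing_law(self):
        cfg = fast_config(
            n_frames=1_200, gas_noise_V=0.0, adc_bits=0,
            puff_events=[PuffEvent(time_ms=20_000.0, kind="co2")])
        trace, _ = simulate_gas_trace(cfg, np.random.default_rng(0))
        pre = trace.voltage_V[trace.time_ms < 20_000].mean()
        post = trace.voltage_V[trace.time_ms > 40_000].mean()
        assert post < pre

    def test_air_puff_leaves_concentration_unchanged(self):
        cfg = fast_config(
            n_frames=1_200,
            puff_events=[PuffEvent(time_ms=20_000.0, kind="air")])
        t = np.arange(0, cfg.duration_ms, 100.0)
        np.testing.assert_allclose(true_co2_ppm(cfg, t), 400.0)

    def test_voltage_confined_to_module_range(self):
        cfg = fast_config(
            n_frames=1_200, gas_noise_V=0.2,
            puff_events=[PuffEvent(time_ms=5_000.0, kind="co2")],
            gas_plateau_ppm=80_000.0)
        trace, _ = simulate_gas_trace(cfg, np.random.default_rng(0))
        assert trace.voltage_V.min() >= 0.0
        assert trace.voltage_V.max() <= 2.0


class TestSessionConsistency:
    def test_every_configured_puff_reaches_ground_truth(self, puff_session):
        cfg = puff_session.config
        assert len(cfg.puff_events) == 1
        # the co2 puff shows up in the latent concentration
        assert puff_session.truth.co2_ppm.max() > 500

    def test_shutter_events_agree_across_streams(self):
        # with the shutter time on both grids the two anchors coincide
        cfg = fast_config(shutter_open_time_ms=2_000.0)
        s = simulate_session(cfg)
        t_frame = s.truth.shutter_frame * cfg.frame_ms
        t_bin = s.truth.shutter_bin * cfg.pmt_bin_ms + cfg.pmt_t0_ms
        assert abs(t_frame - t_bin) <= cfg.frame_ms

    def test_time_mapping_truth_scale(self):
        cfg = fast_config(pmt_bin_ms=2_000.0)
        s = simulate_session(cfg)
        assert s.truth.time_mapping[1] == pytest.approx(40.0)

    def test_session_round_trip_through_files(self, tmp_path):
        cfg = fast_config(n_frames=50, shutter_open_time_ms=1_000.0)
        s = simulate_session(cfg)
        out = write_session(s, tmp_path / "sess")
        loaded = load_session(out)
        np.testing.assert_array_equal(loaded.video.frames, s.video.frames)
        np.testing.assert_allclose(loaded.pmt.counts_au, s.pmt.counts_au)
        assert loaded.pmt.bin_ms == s.pmt.bin_ms
        np.testing.assert_allclose(loaded.gas.voltage_V, s.gas.voltage_V,
                                   atol=1e-6)
        assert loaded.config.rng_seed == cfg.rng_seed
        np.testing.assert_allclose(loaded.truth.positions, s.truth.positions,
                                   atol=1e-3)
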