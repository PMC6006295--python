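"""Synthetic rig: simulate a complete recording session with ground truth.

The real apparatus produces three loosely coupled streams — a dark-field
video of a larva crawling in a circular arena (bright animal on a dark
background, from IR side illumination), a PMT photon-count log, and a CO2
sensor voltage log — tied together by a manual shutter whose opening is
visible simultaneously as a count step in the PMT trace and as a white
marker appearing in a corner of the video.

The simulator reproduces the statistical structure of each stream:

* larva kinematics as a correlated random walk with reflecting arena
  boundary, arrested transiently after CO2 steps;
* photons as a Poisson process whose rate stacks dark counts, resting
  luminescence, a decaying prior-light background, and slow CO2-evoked
  calcium transients (difference-of-exponentials kernel, minutes scale);
* gas-sensor voltage from the same log-linear calibration law the analysis
  inverts, with additive noise and ADC quantization.

Every random choice flows from one seeded generator, with independent
sub-streams per signal so that e.g. changing the video noise does not
perturb the path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PuffEvent, SessionConfig, load_config, save_config
from .gas_sensor import GasTrace, ppm_to_voltage
from .photon_stream import PhotonTrace
from .videoio import VideoSequence, write_video, read_video

__all__ = [
    "GroundTruth",
    "SimulatedSession",
    "simulate_larva_path",
    "simulate_photon_trace",
    "simulate_video",
    "simulate_gas_trace",
    "simulate_session",
    "write_session",
    "load_session",
    "marker_roi",
    "ca_kernel",
    "amplitude_for_response_ratio",
    "render_blob",
]


@dataclass
class GroundTruth:
    """Latent state of a simulated session, for recovery tests."""

    positions: np.ndarray            # (n_frames, 2) float (x, y) px
    headings: np.ndarray             # (n_frames,) rad
    stop_intervals: list             # [[start_ms, end_ms], ...]
    ca_rate_au_s: np.ndarray         # latent calcium-driven rate at frame times
    transient_onsets: list           # ms
    shutter_frame: int
    shutter_bin: int
    co2_ppm: np.ndarray              # true concentration at gas sample times
    time_mapping: tuple              # (offset_ms, scale = pmt_bin_ms/frame_ms)

    def to_json(self, path) -> None:
        d = {
            "positions": np.round(self.positions, 4).tolist(),
            "headings": np.round(self.headings, 5).tolist(),
            "stop_intervals": self.stop_intervals,
            "ca_rate_au_s": np.round(self.ca_rate_au_s, 4).tolist(),
            "transient_onsets": list(self.transient_onsets),
            "shutter_frame": int(self.shutter_frame),
            "shutter_bin": int(self.shutter_bin),
            "co2_ppm": np.round(self.co2_ppm, 3).tolist(),
            "time_mapping": list(self.time_mapping),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            headings=np.asarray(d["headings"], dtype=float),
            stop_intervals=d["stop_intervals"],
            ca_rate_au_s=np.asarray(d["ca_rate_au_s"], dtype=float),
            transient_onsets=d["transient_onsets"],
            shutter_frame=d["shutter_frame"],
            shutter_bin=d["shutter_bin"],
            co2_ppm=np.asarray(d["co2_ppm"], dtype=float),
            time_mapping=tuple(d["time_mapping"]),
        )


@dataclass
class SimulatedSession:
    """One simulated recording: all three streams plus the latent truth."""

    config: SessionConfig
    video: VideoSequence
    pmt: PhotonTrace
    gas: GasTrace
    truth: GroundTruth


def marker_roi(config: SessionConfig) -> tuple[slice, slice]:
    """Shutter-marker region (row slice, column slice), top-left corner."""
    s = config.marker_size_px
    return slice(2, 2 + s), slice(2, 2 + s)


# -- kinematics -------------------------------------------------------------

def simulate_larva_path(config: SessionConfig, rng: np.random.Generator):
    """Correlated random walk in the circular arena.

    Heading diffuses with per-frame Gaussian turning noise; speed is
    constant except inside stop bouts.  A CO2 puff arrests crawling with
    probability ``stop_response.prob`` after ``latency_ms``; air puffs
    leave the kinematics untouched.  The reflecting boundary mirrors the
    radial coordinate so step length is preserved.

    Returns ``(positions, headings, stop_intervals)``.
    """
    config.validate()
    n = config.n_frames
    dt_s = config.frame_ms / 1000.0
    cx, cy = config.arena_center
    R = config.arena_radius_px - max(config.larva_axes_px) / 2.0 - 1.0

    stop_intervals: list[list[float]] = []
    for p in config.puff_events:
        if p.kind == "co2" and rng.random() < config.stop_response.prob:
            s = p.time_ms + config.stop_response.latency_ms
            stop_intervals.append(
                [s, min(s + config.stop_response.duration_ms, config.duration_ms)]
            )
    stop_intervals.sort()

    def stopped(t_ms: float) -> bool:
        return any(s <= t_ms < e for s, e in stop_intervals)

    pos = np.empty((n, 2))
    headings = np.empty(n)
    # start at a mild offset from centre so short straight runs stay inside
    theta = rng.uniform(0, 2 * np.pi)
    x, y = cx, cy
    step = config.larva_speed_px_s * dt_s
    for i in range(n):
        pos[i] = (x, y)
        headings[i] = theta
        t_ms = i * config.frame_ms
        if stopped(t_ms):
            continue
        if config.turn_sigma_rad > 0:
            theta += rng.normal(0.0, config.turn_sigma_rad)
        x += step * np.cos(theta)
        y += step * np.sin(theta)
        r = np.hypot(x - cx, y - cy)
        if r > R:  # mirror the radial overshoot and head back inward
            ang = np.arctan2(y - cy, x - cx)
            r2 = 2 * R - r
            x = cx + r2 * np.cos(ang)
            y = cy + r2 * np.sin(ang)
            theta = ang + np.pi + rng.normal(0.0, config.turn_sigma_rad or 0.1)
    return pos, headings, stop_intervals


# -- latent photon rate -----------------------------------------------------

def ca_kernel(t_s, rise_s: float, decay_s: float):
    """Difference-of-exponentials response kernel, normalised to unit peak.

    Peaks at ``ln(decay/rise) * rise * decay / (decay - rise)`` seconds;
    with the defaults (60 s rise, 90 s decay) this is ~73 s, i.e. the
    evoked luminescence takes more than a minute to peak.
    """
    t_s = np.asarray(t_s, dtype=float)
    if decay_s <= rise_s:
        raise ValueError("decay_s must exceed rise_s")
    tp = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    g = np.where(t_s >= 0,
                 np.exp(-np.clip(t_s, 0, None) / decay_s)
                 - np.exp(-np.clip(t_s, 0, None) / rise_s), 0.0)
    return g / peak


def _ca_rate_fn(config: SessionConfig, transient_onsets_ms):
    """Latent calcium-driven emission rate (au/s) as a vectorised function of ms."""
    ct = config.ca_transient
    co2_times = [p.time_ms for p in config.puff_events if p.kind == "co2"]

    def rate(t_ms):
        t_ms = np.asarray(t_ms, dtype=float)
        r = np.full(t_ms.shape, config.baseline_lum_au_s)
        for t0 in co2_times:
            r += ct.amplitude_au_s * ca_kernel((t_ms - t0) / 1000.0,
                                               ct.rise_s, ct.decay_s)
        for t0 in transient_onsets_ms:
            r += ct.amplitude_au_s * ca_kernel((t_ms - t0) / 1000.0,
                                               ct.rise_s, ct.decay_s)
        return r

    return rate


def simulate_photon_trace(config: SessionConfig, truth_onsets,
                          rng: np.random.Generator) -> PhotonTrace:
    """Poisson photon counts per PMT bin.

    The expected count of a bin integrates, over the bin interval:
    dark counts (always present), plus — only while the shutter is open —
    the decaying prior-light background and the calcium-driven rate.  The
    prior-light term is integrated analytically, the calcium term at the
    midpoint of the shutter-open overlap (its timescale is minutes, far
    slower than any bin).
    """
    config.validate()
    bin_ms = config.pmt_bin_ms
    n_bins = int((config.duration_ms - config.pmt_t0_ms) // bin_ms)
    if n_bins <= 0:
        raise ValueError("session too short for any PMT bin")
    starts = config.pmt_t0_ms + np.arange(n_bins) * bin_ms  # session time
    ends = starts + bin_ms
    T = config.shutter_open_time_ms

    lam = np.full(n_bins, config.dark_rate_au_s * bin_ms / 1000.0)

    # shutter-open overlap of each bin
    o_start = np.maximum(starts, T)
    o_end = np.maximum(ends, T)
    open_s = (o_end - o_start) / 1000.0

    pl = config.prior_light
    if pl.amplitude_au_s > 0:
        a = (o_start - T) / 1000.0
        b = (o_end - T) / 1000.0
        lam += pl.amplitude_au_s * pl.tau_s * (
            np.exp(-a / pl.tau_s) - np.exp(-b / pl.tau_s))

    ca = _ca_rate_fn(config, truth_onsets)
    mid = (o_start + o_end) / 2.0
    lam += np.where(open_s > 0, ca(mid) * open_s, 0.0)

    counts = rng.poisson(lam).astype(float)
    return PhotonTrace(counts_au=counts, bin_ms=bin_ms, t0_ms=0.0,
                       meta={"pmt_t0_session_ms": config.pmt_t0_ms})


def _spontaneous_onsets(config: SessionConfig, rng: np.random.Generator):
    """Homogeneous-Poisson spontaneous transient onsets after shutter opening."""
    if config.spontaneous_per_min <= 0:
        return []
    span_min = (config.duration_ms - config.shutter_open_time_ms) / 60_000.0
    k = rng.poisson(config.spontaneous_per_min * span_min)
    on = rng.uniform(config.shutter_open_time_ms, config.duration_ms, size=k)
    return sorted(float(t) for t in on)


# -- video ------------------------------------------------------------------

def render_blob(frame: np.ndarray, x: float, y: float, heading: float,
                axes_px: tuple[float, float], peak: float) -> None:
    """Add an anti-aliased elliptical blob, in place.

    The profile ``peak * max(0, 1 - d^2)`` (d the normalised elliptical
    radius, major axis along ``heading``) is symmetric about the centre,
    so the intensity-weighted centroid of the rendered blob equals
    ``(x, y)`` exactly up to quantization.
    """
    a, b = axes_px[0] / 2.0, axes_px[1] / 2.0
    h, w = frame.shape
    r = int(np.ceil(max(a, b))) + 2
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - x
    dy = yy - y
    c, s = np.cos(heading), np.sin(heading)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    d2 = (u / a) ** 2 + (v / b) ** 2
    frame[y0:y1, x0:x1] += peak * np.clip(1.0 - d2, 0.0, None)


def simulate_video(config: SessionConfig, positions: np.ndarray,
                   headings: np.ndarray, shutter_frame: int,
                   rng: np.random.Generator) -> VideoSequence:
    """Render the dark-field video: dark noisy background, bright larva,
    and the white shutter-marker dot switching on at ``shutter_frame``."""
    config.validate()
    h, w = config.frame_size
    roi = marker_roi(config)
    n = config.n_frames
    frames = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        f = np.full((h, w), float(config.bg_level))
        render_blob(f, positions[i, 0], positions[i, 1], headings[i],
                    config.larva_axes_px, config.blob_peak_intensity)
        if i >= shutter_frame:
            f[roi] = 230.0
        if config.video_noise_sigma > 0:
            f += rng.normal(0.0, config.video_noise_sigma, size=f.shape)
        frames[i] = np.clip(np.round(f), 0, 255).astype(np.uint8)
    return VideoSequence(frames=frames, frame_ms=config.frame_ms, t0_ms=0.0,
                         meta={"marker_roi": [[roi[0].start, roi[0].stop],
                                              [roi[1].start, roi[1].stop]]})


# -- gas --------------------------------------------------------------------

def true_co2_ppm(config: SessionConfig, t_ms) -> np.ndarray:
    """Latent chamber CO2 concentration: 400 ppm baseline, first-order
    accumulation toward the plateau after each CO2 puff (no clearing
    within a session); air puffs change nothing."""
    t_ms = np.asarray(t_ms, dtype=float)
    ppm = np.full(t_ms.shape, 400.0)
    tau_ms = config.gas_rise_tau_s * 1000.0
    for p in config.puff_events:
        if p.kind != "co2":
            continue
        dt = t_ms - p.time_ms
        ppm += np.where(dt >= 0,
                        (config.gas_plateau_ppm - 400.0)
                        * (1.0 - np.exp(-np.clip(dt, 0, None) / tau_ms)), 0.0)
    return ppm


def simulate_gas_trace(config: SessionConfig, rng: np.random.Generator):
    """Sensor voltage log: forward calibration law + noise + ADC quantization.

    Returns ``(GasTrace, true_ppm)``.
    """
    t = np.arange(0.0, config.duration_ms, config.gas_sample_ms)
    ppm = true_co2_ppm(config, t)
    v = np.asarray(ppm_to_voltage(ppm, config.sensor_params), dtype=float)
    if config.gas_noise_V > 0:
        v = v + rng.normal(0.0, config.gas_noise_V, size=v.shape)
    lo, hi = config.sensor_params.v_range
    v = np.clip(v, lo, hi)
    if config.adc_bits:
        levels = 2 ** config.adc_bits - 1
        v = np.round((v - lo) / (hi - lo) * levels) / levels * (hi - lo) + lo
    trace = GasTrace(time_ms=t, voltage_V=v, sample_ms=config.gas_sample_ms)
    return trace, ppm


# -- whole session ----------------------------------------------------------

def simulate_session(config: SessionConfig) -> SimulatedSession:
    """Simulate all three streams plus ground truth from one seed.

    Independent child generators drive path, photons, video noise and
    sensor noise, so identical configs give bit-identical sessions and
    the streams can be perturbed independently.
    """
    config.validate()
    root = np.random.default_rng(config.rng_seed)
    rng_path, rng_phot, rng_vid, rng_gas, rng_spont = root.spawn(5)

    positions, headings, stop_intervals = simulate_larva_path(config, rng_path)
    onsets = _spontaneous_onsets(config, rng_spont)
    pmt = simulate_photon_trace(config, onsets, rng_phot)

    shutter_frame = int(np.ceil(config.shutter_open_time_ms / config.frame_ms))
    shutter_bin = int(np.ceil(
        (config.shutter_open_time_ms - config.pmt_t0_ms) / config.pmt_bin_ms))
    video = simulate_video(config, positions, headings, shutter_frame, rng_vid)
    gas, ppm = simulate_gas_trace(config, rng_gas)

    ca = _ca_rate_fn(config, onsets)
    frame_times = np.arange(config.n_frames) * config.frame_ms
    truth = GroundTruth(
        positions=positions,
        headings=headings,
        stop_intervals=stop_intervals,
        ca_rate_au_s=ca(frame_times),
        transient_onsets=onsets,
        shutter_frame=shutter_frame,
        shutter_bin=shutter_bin,
        co2_ppm=ppm,
        time_mapping=(config.pmt_t0_ms, config.pmt_bin_ms / config.frame_ms),
    )
    return SimulatedSession(config=config, video=video, pmt=pmt, gas=gas,
                            truth=truth)


def amplitude_for_response_ratio(config: SessionConfig, ratio: float,
                                 pre_ms: float = 60_000.0,
                                 post_ms: float = 120_000.0) -> float:
    """Transient amplitude giving an expected post/pre luminescence ratio.

    The pre-puff mean rate (after prior-light correction) is dark +
    resting luminescence; the post window averages the response kernel, so
    the amplitude that yields ``post/pre = ratio`` is
    ``(ratio - 1) * base / mean(kernel over post window)``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    base = config.dark_rate_au_s + config.baseline_lum_au_s
    t = np.arange(0.0, post_ms, 100.0) / 1000.0
    kbar = float(np.mean(ca_kernel(t, config.ca_transient.rise_s,
                                   config.ca_transient.decay_s)))
    return (ratio - 1.0) * base / kbar


# -- session files ----------------------------------------------------------

def write_session(session: SimulatedSession, outdir,
                  video_format: str = "tiff") -> Path:
    """Write the session to disk: video, the two logs, config and truth."""
    from .photon_stream import write_pmt_log
    from .gas_sensor import write_gas_log

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if video_format == "tiff":
        write_video(session.video, out / "video.tif")
    elif video_format == "png":
        write_video(session.video, out / "frames")
    else:
        raise ValueError(f"unknown video format {video_format!r}")
    write_pmt_log(session.pmt, out / "pmt.tsv")
    write_gas_log(session.gas, out / "gas.tsv")
    save_config(session.config, out / "config.yaml")
    session.truth.to_json(out / "truth.json")
    return out


def load_session(session_dir) -> SimulatedSession:
    """Reload a session written by :func:`write_session`."""
    from .photon_stream import read_pmt_log
    from .gas_sensor import read_gas_log

    d = Path(session_dir)
    config = load_config(d / "config.yaml")
    video_path = d / "video.tif" if (d / "video.tif").exists() else d / "frames"
    video = read_video(video_path, frame_ms=config.frame_ms)
    roi = marker_roi(config)
    video.meta["marker_roi"] = [[roi[0].start, roi[0].stop],
                                [roi[1].start, roi[1].stop]]
    pmt = read_pmt_log(d / "pmt.tsv")
    gas = read_gas_log(d / "gas.tsv")
    truth = (GroundTruth.from_json(d / "truth.json")
             if (d / "truth.json").exists() else None)
    return SimulatedSession(config=config, video=video, pmt=pmt, gas=gas,
                            truth=truth)
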