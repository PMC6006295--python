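"""Cross-stream synchronization and fusion.

The PMT and video are started independently, so their clocks differ by an
unknown offset.  The manual shutter provides the anchor: opening it causes
a simultaneous step in PMT counts and the appearance of a white marker dot
in a fixed corner of the video.  Matching the two events yields an affine
map between timebases whose scale is the exact rational ratio of bin to
frame duration (40 video frames per 2000 ms bin at 20 fps).

Fusion annotates every video frame with the luminescence of the PMT bin
covering its mapped time (zero-order hold — a bin is a photon *sum* over
its interval, so interpolating would fabricate sub-bin structure) and the
nearest gas sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .gas_sensor import GasTrace
from .photon_stream import PhotonTrace
from .tracking import Trajectory
from .videoio import VideoSequence

__all__ = [
    "NoMarkerDetected",
    "TimeMapping",
    "detect_shutter_frame",
    "build_time_mapping",
    "fuse",
    "render_trajectory_heatmap",
    "write_fused",
    "read_fused",
    "FUSED_COLUMNS",
]


class NoMarkerDetected(RuntimeError):
    """The shutter-marker ROI never switches to its bright state."""


@dataclass
class TimeMapping:
    """Affine map between PMT-local and video-local time.

    ``t_video = t_pmt + offset_ms``; ``scale`` is the exact rational
    number of video frames per PMT bin, kept as a Fraction so index
    arithmetic is exact.
    """

    offset_ms: float
    scale: Fraction
    anchor: tuple[int, int]  # (shutter_bin, shutter_frame)
    pmt_bin_ms: float
    frame_ms: float

    def pmt_to_video_ms(self, t_pmt_ms):
        return np.asarray(t_pmt_ms, dtype=float) + self.offset_ms

    def video_to_pmt_ms(self, t_video_ms):
        return np.asarray(t_video_ms, dtype=float) - self.offset_ms

    def bin_for_frame(self, frame_index, video_t0_ms: float = 0.0,
                      pmt_t0_ms: float = 0.0) -> np.ndarray:
        """PMT bin index covering each video frame's start time."""
        t_v = video_t0_ms + np.asarray(frame_index) * self.frame_ms
        t_p = self.video_to_pmt_ms(t_v) - pmt_t0_ms
        return np.floor(t_p / self.pmt_bin_ms).astype(int)


def detect_shutter_frame(video: VideoSequence,
                         marker_roi: tuple[slice, slice],
                         sustain_frames: int = 3,
                         min_contrast: float = 30.0) -> int:
    """First frame at which the white shutter dot appears and stays.

    The per-frame ROI mean is compared to the midpoint between its darkest
    and brightest levels; the switch must be sustained ``sustain_frames``
    frames.  A never-switching (or insufficiently contrasted) ROI raises
    :class:`NoMarkerDetected`.
    """
    h, w = video.shape
    rs, cs = marker_roi
    if not (0 <= rs.start < rs.stop <= h and 0 <= cs.start < cs.stop <= w):
        raise ValueError(f"marker ROI {marker_roi} outside frame {video.shape}")
    means = video.frames[:, rs, cs].mean(axis=(1, 2))
    lo, hi = float(means.min()), float(means.max())
    if hi - lo < min_contrast:
        if lo >= 128.0:  # shutter already open before recording started
            return 0
        raise NoMarkerDetected(
            f"marker ROI contrast {hi - lo:.1f} below {min_contrast}")
    bright = means > (lo + hi) / 2.0
    k = max(1, sustain_frames)
    edges = np.diff(np.concatenate([[0], bright.astype(int), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        # a run truncated by the end of the video counts as sustained
        if e - s >= k or e == bright.size:
            return int(s)
    raise NoMarkerDetected("marker ROI never switches to a sustained bright state")


def build_time_mapping(shutter_bin: int, shutter_frame: int,
                       pmt_bin_ms: float, frame_ms: float) -> TimeMapping:
    """Anchor the start of the shutter bin to the start of the shutter frame.

    The residual misalignment is bounded by one video frame plus one PMT
    bin: the true opening happened somewhere inside both the anchor bin
    and the anchor frame.
    """
    scale = Fraction(pmt_bin_ms).limit_denominator(10**6) / \
        Fraction(frame_ms).limit_denominator(10**6)
    offset = shutter_frame * frame_ms - shutter_bin * pmt_bin_ms
    return TimeMapping(offset_ms=float(offset), scale=scale,
                       anchor=(int(shutter_bin), int(shutter_frame)),
                       pmt_bin_ms=pmt_bin_ms, frame_ms=frame_ms)


def fuse(traj: Trajectory, pmt: PhotonTrace, gas: GasTrace | None,
         mapping: TimeMapping, shutter_frame: int,
         puffs: list | None = None) -> pd.DataFrame:
    """Resample all streams onto the video-frame timebase.

    Each frame carries the luminescence of the PMT bin covering its mapped
    time (zero-order hold; NaN where the frame maps outside the PMT span),
    the nearest-in-time gas sample (NaN when no gas log), and a
    ``shutter_open`` flag.  ``puffs`` (list of (time_ms, kind)) is attached
    as ``DataFrame.attrs["puffs"]``.
    """
    df = traj.data.copy()
    n = len(df)
    frame_t = df["time_ms"].to_numpy(dtype=float)

    t_pmt = mapping.video_to_pmt_ms(frame_t) - pmt.t0_ms
    bins = np.floor(t_pmt / pmt.bin_ms).astype(int)
    lum = np.full(n, np.nan)
    ok = (bins >= 0) & (bins < pmt.n_bins)
    lum[ok] = pmt.counts_au[bins[ok]]

    if gas is not None and gas.ppm is not None and gas.time_ms.size:
        idx = np.clip(np.searchsorted(gas.time_ms, frame_t), 0,
                      gas.time_ms.size - 1)
        left = np.clip(idx - 1, 0, gas.time_ms.size - 1)
        use_left = (np.abs(gas.time_ms[left] - frame_t)
                    <= np.abs(gas.time_ms[idx] - frame_t))
        nearest = np.where(use_left, left, idx)
        co2 = gas.ppm[nearest]
    else:
        co2 = np.full(n, np.nan)

    if traj.speed_px_s is None:
        from .tracking import compute_speed
        compute_speed(traj)
    fused = pd.DataFrame({
        "frame": df["frame"].to_numpy(),
        "time_ms": frame_t,
        "x_px": df["x_px"].to_numpy(),
        "y_px": df["y_px"].to_numpy(),
        "valid": df["valid"].to_numpy(dtype=bool),
        "speed_px_s": traj.speed_px_s,
        "lum_au": lum,
        "co2_ppm": co2,
        "shutter_open": df["frame"].to_numpy() >= shutter_frame,
    })
    fused.attrs["puffs"] = [(float(t), str(k)) for t, k in (puffs or [])]
    fused.attrs["offset_ms"] = mapping.offset_ms
    fused.attrs["scale"] = float(mapping.scale)
    return fused


FUSED_COLUMNS = ["frame", "time_ms", "x_px", "y_px", "valid", "speed_px_s",
                 "lum_au", "co2_ppm", "shutter_open"]


def write_fused(fused: pd.DataFrame, path) -> None:
    df = fused.copy()
    df["valid"] = df["valid"].astype(int)
    df["shutter_open"] = df["shutter_open"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f",
              columns=FUSED_COLUMNS)


def read_fused(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["valid"] = df["valid"].astype(bool)
    df["shutter_open"] = df["shutter_open"].astype(bool)
    return df


def render_trajectory_heatmap(fused: pd.DataFrame, max_au: float = 2_000.0,
                              line_width_px: float = 3.0,
                              colormap_name: str = "jet",
                              out_png=None, out_tsv=None):
    """Draw the trajectory as a polyline colour-coded by luminescence.

    Luminescence maps linearly onto the colormap over [0, max_au]; values
    at or above ``max_au`` clamp to the top colour (a deliberately low
    ceiling boosts contrast for dim traces).  Returns the matplotlib
    figure and a per-vertex table (x, y, lum_au, colour hex).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection
    from matplotlib.colors import Normalize, to_hex

    if max_au <= 0:
        raise ValueError("max_au must be positive")
    sel = fused[fused["valid"]].reset_index(drop=True)
    if len(sel) < 2:
        raise ValueError("need at least 2 valid frames to render a trajectory")

    pts = sel[["x_px", "y_px"]].to_numpy(dtype=float)
    lum = np.nan_to_num(sel["lum_au"].to_numpy(dtype=float), nan=0.0)
    segs = np.stack([pts[:-1], pts[1:]], axis=1)
    norm = Normalize(vmin=0.0, vmax=max_au, clip=True)
    cmap = matplotlib.colormaps[colormap_name]
    lc = LineCollection(segs, cmap=cmap, norm=norm, linewidths=line_width_px)
    lc.set_array(lum[:-1])

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.add_collection(lc)
    ax.set_xlim(pts[:, 0].min() - 10, pts[:, 0].max() + 10)
    ax.set_ylim(pts[:, 1].max() + 10, pts[:, 1].min() - 10)  # image convention
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.colorbar(lc, ax=ax, label="luminescence (au)")

    colours = [to_hex(cmap(norm(v))) for v in lum]
    table = pd.DataFrame({
        "x_px": pts[:, 0], "y_px": pts[:, 1], "lum_au": lum, "colour": colours,
    })
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False, float_format="%.3f")
    if out_png is not None:
        fig.savefig(out_png, dpi=120, metadata={"Software": None})
    return fig, table
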