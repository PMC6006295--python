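"""Larva detection and trajectory extraction from dark-field video.

Under FTIR-style side illumination the animal is bright on a dark
background, so segmentation is: subtract a per-pixel temporal-median
background, threshold the (positive) difference, take the largest
plausibly-sized connected component, and report its intensity-weighted
centroid.  Coordinates are sub-pixel, origin at the centre of the top-left
pixel, x rightward along columns and y downward along rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label

from .videoio import VideoSequence

__all__ = [
    "TrackingParams",
    "Trajectory",
    "build_background",
    "segment_larva",
    "track",
    "compute_speed",
    "detect_stops",
    "write_track",
    "read_track",
]

MAD_SCALE = 1.4826


@dataclass
class TrackingParams:
    """Segmentation and bout-detection settings.

    ``thresh`` fixes the foreground threshold in intensity units; when
    None it adapts per frame to ``k_mad`` robust standard deviations of
    the background-subtracted image (floored at ``min_thresh`` so a
    noise-free frame still thresholds sensibly).
    """

    thresh: float | None = None
    k_mad: float = 4.0
    min_thresh: float = 2.0
    min_area: int = 20
    max_area: int = 2_000
    max_gap: int = 5
    smooth_win: int = 5
    stop_thresh_px_s: float = 1.0
    min_stop_ms: float = 2_000.0
    merge_gap_ms: float = 500.0
    n_background: int = 25
    marker_roi: tuple[slice, slice] | None = None
    polarity: str = "bright"  # "bright" (FTIR) or "dark" foreground


@dataclass
class Trajectory:
    """Per-frame larva localisation plus derived kinematics.

    ``data`` has columns frame, time_ms, x_px, y_px, area_px, valid,
    interpolated; positions are NaN on invalid frames.  ``speed_px_s`` and
    ``stop_bouts`` are filled by :func:`compute_speed` and
    :func:`detect_stops`.
    """

    data: pd.DataFrame
    frame_ms: float
    speed_px_s: np.ndarray | None = None
    stop_bouts: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data["valid"].to_numpy(dtype=bool)

    @property
    def positions(self) -> np.ndarray:
        return self.data[["x_px", "y_px"]].to_numpy(dtype=float)


def build_background(video: VideoSequence, n_sample: int = 25) -> np.ndarray:
    """Per-pixel temporal median over frames evenly spaced across the video.

    A crawling larva occupies any given pixel only transiently, so the
    temporal median recovers the empty-arena image without a dedicated
    background recording.
    """
    if n_sample < 3:
        raise ValueError("n_sample must be at least 3")
    n = video.n_frames
    if n < 3:
        raise ValueError(f"need at least 3 frames to build a background, got {n}")
    if n < n_sample:
        warnings.warn(
            f"video has only {n} frames; using all of them for the background",
            stacklevel=2)
        idx = np.arange(n)
    else:
        idx = np.unique(np.linspace(0, n - 1, n_sample).round().astype(int))
    return np.median(video.frames[idx].astype(float), axis=0)


def _difference(frame: np.ndarray, background: np.ndarray, polarity: str):
    """Signed foreground difference (positive where the larva is)."""
    diff = frame.astype(float) - background
    if polarity == "dark":
        diff = -diff
    return diff


def segment_larva(frame: np.ndarray, background: np.ndarray,
                  params: TrackingParams = TrackingParams()):
    """Locate the larva in one frame.

    Returns ``(x, y, area)`` — intensity-weighted centroid of the largest
    connected component with area in ``[min_area, max_area]`` — or None if
    nothing qualifies.  The adaptive threshold sits ``k_mad`` robust
    standard deviations above the median of the *signed* difference image,
    so sensor noise sets the floor.  The shutter-marker region is excluded
    before labelling.
    """
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}")
    diff = _difference(frame, background, params.polarity)
    if params.marker_roi is not None:
        diff[params.marker_roi] = 0.0
    if params.thresh is not None:
        thr = params.thresh
    else:
        med = np.median(diff)
        mad = np.median(np.abs(diff - med))
        thr = max(params.min_thresh, med + params.k_mad * MAD_SCALE * mad)
    pos = np.clip(diff, 0.0, None)
    mask = pos > thr
    if not mask.any():
        return None
    labels = label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0  # background label
    candidates = np.flatnonzero(
        (areas >= params.min_area) & (areas <= params.max_area))
    if candidates.size == 0:
        return None
    best = int(candidates[np.argmax(areas[candidates])])
    rows, cols = np.nonzero(labels == best)
    w = pos[rows, cols]
    total = w.sum()
    cx = float((w * cols).sum() / total)
    cy = float((w * rows).sum() / total)
    return cx, cy, int(areas[best])


def estimate_threshold(video: VideoSequence, background: np.ndarray,
                       params: TrackingParams, n_sample: int = 5) -> float:
    """Adaptive foreground threshold from a few sampled frames.

    Median + ``k_mad`` robust standard deviations of the signed difference
    image, medianed across evenly spaced frames (noise is stationary, so
    one number serves the whole video).
    """
    idx = np.unique(np.linspace(0, video.n_frames - 1, n_sample).astype(int))
    thrs = []
    for i in idx:
        diff = _difference(video.frames[i], background, params.polarity)
        med = np.median(diff)
        mad = np.median(np.abs(diff - med))
        thrs.append(med + params.k_mad * MAD_SCALE * mad)
    return max(params.min_thresh, float(np.median(thrs)))


def track(video: VideoSequence,
          params: TrackingParams = TrackingParams()) -> Trajectory:
    """Segment every frame and bridge short detection gaps.

    Frames with no acceptable component are invalid; runs of at most
    ``max_gap`` invalid frames flanked by detections are filled by linear
    interpolation and flagged ``interpolated``.
    """
    bg = build_background(video, params.n_background)
    if params.thresh is None:
        from dataclasses import replace
        params = replace(params, thresh=estimate_threshold(video, bg, params))
    n = video.n_frames
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    areas = np.zeros(n)
    detected = np.zeros(n, dtype=bool)
    for i in range(n):
        hit = segment_larva(video.frames[i], bg, params)
        if hit is not None:
            xs[i], ys[i], areas[i] = hit
            detected[i] = True

    interpolated = np.zeros(n, dtype=bool)
    det_idx = np.flatnonzero(detected)
    for a, b in zip(det_idx[:-1], det_idx[1:]):
        gap = b - a - 1
        if 0 < gap <= params.max_gap:
            w = (np.arange(a + 1, b) - a) / (b - a)
            xs[a + 1:b] = xs[a] + w * (xs[b] - xs[a])
            ys[a + 1:b] = ys[a] + w * (ys[b] - ys[a])
            interpolated[a + 1:b] = True
    valid = detected | interpolated

    data = pd.DataFrame({
        "frame": np.arange(n),
        "time_ms": video.time_ms,
        "x_px": xs, "y_px": ys, "area_px": areas,
        "valid": valid, "interpolated": interpolated,
    })
    data.loc[~valid, ["x_px", "y_px"]] = np.nan
    return Trajectory(data=data, frame_ms=video.frame_ms)


def compute_speed(traj: Trajectory, smooth_win: int | None = 5) -> np.ndarray:
    """Instantaneous crawling speed (px/s), centred-moving-average smoothed.

    Raw speed at a frame is the Euclidean displacement from the previous
    valid frame divided by the elapsed time; frames without a defined raw
    speed stay missing (NaN) after smoothing.  The result is also stored
    on ``traj.speed_px_s``.
    """
    n = traj.n_frames
    raw = np.full(n, np.nan)
    valid_idx = np.flatnonzero(traj.valid_mask)
    if valid_idx.size >= 2:
        p = traj.positions
        t = traj.data["time_ms"].to_numpy(dtype=float)
        a, b = valid_idx[:-1], valid_idx[1:]
        d = np.hypot(p[b, 0] - p[a, 0], p[b, 1] - p[a, 1])
        raw[b] = d / (t[b] - t[a]) * 1000.0
    if smooth_win and smooth_win > 1:
        half = smooth_win // 2
        smoothed = np.full(n, np.nan)
        defined = np.flatnonzero(~np.isnan(raw))
        for i in defined:
            w = raw[max(0, i - half): i + half + 1]
            smoothed[i] = np.nanmean(w)
        raw = smoothed
    traj.speed_px_s = raw
    return raw


def detect_stops(time_ms: np.ndarray, speed_px_s: np.ndarray,
                 stop_thresh_px_s: float = 1.0,
                 min_stop_ms: float = 2_000.0,
                 merge_gap_ms: float = 500.0) -> list[list[float]]:
    """Maximal sub-threshold intervals lasting at least ``min_stop_ms``.

    NaN speeds are treated as moving (no evidence of a stop).  Bouts
    separated by less than ``merge_gap_ms`` are merged before the duration
    filter is applied.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    speed = np.asarray(speed_px_s, dtype=float)
    below = np.where(np.isnan(speed), False, speed < stop_thresh_px_s)
    edges = np.diff(np.concatenate([[0], below.astype(int), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    dt = float(np.median(np.diff(time_ms))) if time_ms.size > 1 else 0.0
    raw = [[float(time_ms[s]), float(time_ms[e - 1] + dt)]
           for s, e in zip(starts, ends)]
    merged: list[list[float]] = []
    for iv in raw:
        if merged and iv[0] - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = iv[1]
        else:
            merged.append(list(iv))
    return [iv for iv in merged if iv[1] - iv[0] >= min_stop_ms]


# -- track files ------------------------------------------------------------

TRACK_COLUMNS = ["frame", "time_ms", "x_px", "y_px", "area_px",
                 "valid", "interpolated"]


def write_track(traj: Trajectory, path) -> None:
    """Write the per-frame log as TSV (importable into any data tool)."""
    df = traj.data.copy()
    df["valid"] = df["valid"].astype(int)
    df["interpolated"] = df["interpolated"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f",
              columns=TRACK_COLUMNS)


def read_track(path, frame_ms: float | None = None) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    df["interpolated"] = df["interpolated"].astype(bool)
    if frame_ms is None:
        t = df["time_ms"].to_numpy(dtype=float)
        frame_ms = float(np.median(np.diff(t))) if len(t) > 1 else 50.0
    return Trajectory(data=df, frame_ms=frame_ms)
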