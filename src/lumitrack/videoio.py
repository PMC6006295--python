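"""Reading and writing dark-field larva videos.

Supported containers: multipage TIFF (preferred for archival), a directory
of numbered PNG/BMP frames, and AVI where an ffmpeg-backed imageio plugin
is available.  Frames are 8-bit grayscale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["VideoSequence", "read_video", "write_video"]


@dataclass
class VideoSequence:
    """Ordered grayscale frames with a nominal frame duration."""

    frames: np.ndarray  # (n, h, w) uint8
    frame_ms: float
    t0_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) stack")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])

    @property
    def time_ms(self) -> np.ndarray:
        """Start time of each frame."""
        return self.t0_ms + np.arange(self.n_frames) * self.frame_ms


def _to_gray(a: np.ndarray) -> np.ndarray:
    if a.ndim == 3 and a.shape[-1] in (3, 4):  # RGB(A) -> luma
        a = np.round(a[..., :3] @ np.array([0.299, 0.587, 0.114])).astype(np.uint8)
    return a


def read_video(path, frame_ms: float = 50.0, t0_ms: float = 0.0) -> VideoSequence:
    """Load a video from TIFF stack, frame directory, or AVI."""
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir()
                       if f.suffix.lower() in (".png", ".bmp", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"{p}: no image frames found")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
    elif p.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[None]
    elif p.suffix.lower() in (".avi", ".mp4"):
        try:
            frames = np.stack([_to_gray(f) for f in iio.imiter(p)])
        except Exception as exc:  # ffmpeg plugin missing or codec unsupported
            raise RuntimeError(
                f"cannot decode {p}; AVI support requires an ffmpeg-backed "
                f"imageio plugin"
            ) from exc
    else:
        raise ValueError(f"unsupported video container: {p.suffix}")
    return VideoSequence(frames=frames.astype(np.uint8), frame_ms=frame_ms,
                         t0_ms=t0_ms, meta={"source": str(p)})


def write_video(video: VideoSequence, path) -> None:
    """Write as multipage TIFF (``.tif``) or a PNG sequence directory."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, video.frames.astype(np.uint8))
    else:
        p.mkdir(parents=True, exist_ok=True)
        width = len(str(video.n_frames - 1)) if video.n_frames > 1 else 1
        for i, frame in enumerate(video.frames):
            iio.imwrite(p / f"frame_{i:0{width}d}.png", frame.astype(np.uint8))
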