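import numpy as np
import pytest

from lumitrack.config import PuffEvent, SessionConfig
from lumitrack.synthdata import simulate_session


def fast_config(**overrides) -> SessionConfig:
    """A small, quick-to-simulate session used throughout the unit tests."""
    kw = dict(
        arena_radius_px=40.0,
        n_frames=400,                 # 20 s at 20 fps
        shutter_open_time_ms=2_000.0,
        pmt_bin_ms=100.0,
        rng_seed=0,
    )
    kw.update(overrides)
    return SessionConfig(**kw)


@pytest.fixture(scope="session")
def puff_session():
    """One small session with a CO2 puff, shared by recovery tests."""
    cfg = fast_config(
        n_frames=2_400,               # 120 s: the slow CO2 transient develops
        shutter_open_time_ms=4_000.0,
        puff_events=[PuffEvent(time_ms=20_000.0, kind="co2")],
        rng_seed=11,
    )
    cfg.stop_response.duration_ms = 10_000.0
    cfg.stop_response.latency_ms = 1_000.0
    # a strongly supra-baseline evoked transient (~5x peak over resting rate)
    cfg.ca_transient.amplitude_au_s = 600.0
    return simulate_session(cfg)


def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """Brute-force 8-connected component labelling (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0]
                                    and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels


def oracle_largest_component(image: np.ndarray, thresh: float,
                             min_area: int, max_area: int):
    """Brute-force counterpart of segment_larva on a plain image."""
    mask = image > thresh
    labels = flood_fill_label(mask)
    best_label, best_area = None, -1
    for lab in range(1, labels.max() + 1):
        area = int((labels == lab).sum())
        if min_area <= area <= max_area and area > best_area:
            best_label, best_area = lab, area
    if best_label is None:
        return None
    rows, cols = np.nonzero(labels == best_label)
    w = image[rows, cols].astype(float)
    return (float((w * cols).sum() / w.sum()),
            float((w * rows).sum() / w.sum()),
            best_area)
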