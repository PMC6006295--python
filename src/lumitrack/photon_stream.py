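"""Conditioning of the PMT photon-count stream.

The photomultiplier logs photon counts per fixed time bin (100 or 2000 ms
on the rig), in arbitrary units (au) that are raw counts.  Four artefacts
must be handled before any biology can be read off the trace:

* **dark counts** — the PMT's noise floor, present with the shutter closed;
* **the shutter step** — opening the optical shutter lets luminescence
  through and produces a sudden jump in mean count rate, which doubles as
  the synchronization anchor with the video stream;
* **prior-light contamination** — light exposure before the recording
  leaves an elevated background that decays roughly exponentially after
  the shutter opens; it is fitted and subtracted;
* **transients** — minutes-long elevations above baseline, the actual
  calcium-driven signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

__all__ = [
    "PhotonTrace",
    "DecayModel",
    "TransientEvent",
    "NoStepDetected",
    "read_pmt_log",
    "write_pmt_log",
    "detect_shutter_step",
    "fit_prior_light_decay",
    "correct_prior_light",
    "detect_transients",
    "write_transients",
    "summarize_trace",
]

MAD_SCALE = 1.4826  # Gaussian-consistent scaling of the median absolute deviation


@dataclass
class PhotonTrace:
    """Uniformly binned photon counts.

    ``counts_au[i]`` covers local time ``[t0_ms + i*bin_ms, t0_ms + (i+1)*bin_ms)``.
    """

    counts_au: np.ndarray
    bin_ms: float
    t0_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts_au = np.asarray(self.counts_au, dtype=float)
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.counts_au.size and self.counts_au.min() < 0:
            raise ValueError("photon counts cannot be negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts_au.size)

    @property
    def time_ms(self) -> np.ndarray:
        """Start time of each bin (trace-local)."""
        return self.t0_ms + np.arange(self.n_bins) * self.bin_ms

    def copy_with(self, counts_au: np.ndarray) -> "PhotonTrace":
        return PhotonTrace(counts_au=counts_au, bin_ms=self.bin_ms,
                           t0_ms=self.t0_ms, meta=dict(self.meta))


@dataclass
class DecayModel:
    """Fitted prior-light decay: counts ~ amplitude*exp(-(t-t_ref)/tau) + offset."""

    amplitude_au: float
    tau_s: float
    offset_au: float
    t_ref_ms: float
    fit_window: tuple[int, int]
    residual_rms: float

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.offset_au < 0:
            raise ValueError("offset_au must be non-negative")

    def background(self, time_ms: np.ndarray) -> np.ndarray:
        """Decaying background (without offset) at the given trace-local times."""
        dt_s = (np.asarray(time_ms, dtype=float) - self.t_ref_ms) / 1000.0
        bg = self.amplitude_au * np.exp(-dt_s / self.tau_s)
        bg[np.asarray(time_ms) < self.t_ref_ms] = 0.0
        return bg


@dataclass
class TransientEvent:
    """A sustained above-baseline elevation of the photon trace."""

    onset_ms: float
    peak_ms: float
    peak_au: float
    duration_ms: float
    integral_au_ms: float

    def __post_init__(self) -> None:
        if self.onset_ms > self.peak_ms:
            raise ValueError("onset must not follow the peak")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")


class NoStepDetected(RuntimeError):
    """No shutter-like change point found in the trace."""


# -- I/O --------------------------------------------------------------------

def read_pmt_log(path, bin_ms: float | None = None) -> PhotonTrace:
    """Read a 2-column delimited log (time_ms, counts_au).

    Timestamps must be uniform; jitter up to 1% of the bin length is
    snapped to the nominal grid, anything worse is rejected.  If the first
    column is a bare bin index (unit steps), pass ``bin_ms`` explicitly.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     skiprows=_header_rows(path))
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty PMT log")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (time_ms, counts_au)")
    try:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        c = df.iloc[:, 1].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable numeric data: {exc}") from exc
    bad = np.flatnonzero(~np.isfinite(t) | ~np.isfinite(c))
    if bad.size:
        raise ValueError(f"{path}: unparseable row at line {bad[0] + 1}")
    neg = np.flatnonzero(c < 0)
    if neg.size:
        raise ValueError(f"{path}: negative count at line {neg[0] + 1}")
    if t.size == 1:
        nominal = bin_ms or 1.0
        return PhotonTrace(c, bin_ms=nominal, t0_ms=float(t[0]),
                           meta={"source": str(path)})
    steps = np.diff(t)
    nominal = bin_ms if bin_ms is not None else float(np.median(steps))
    if nominal <= 0:
        raise ValueError(f"{path}: non-increasing timestamps")
    jitter = np.abs(t - (t[0] + np.arange(t.size) * nominal))
    if jitter.max() > 0.01 * nominal:
        k = int(np.argmax(jitter))
        raise ValueError(
            f"{path}: timestamp jitter exceeds 1% of bin length at line {k + 1}"
        )
    return PhotonTrace(c, bin_ms=nominal, t0_ms=float(t[0]),
                       meta={"source": str(path)})


def _header_rows(path) -> int:
    """Number of leading non-numeric header lines (0 or 1)."""
    with open(path) as fh:
        first = fh.readline()
    token = first.strip().split("\t")[0].split(",")[0].split()[0] if first.strip() else ""
    try:
        float(token)
        return 0
    except ValueError:
        return 1 if token else 0


def write_pmt_log(trace: PhotonTrace, path) -> None:
    df = pd.DataFrame({"time_ms": trace.time_ms, "counts_au": trace.counts_au})
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


# -- shutter step -----------------------------------------------------------

def detect_shutter_step(trace: PhotonTrace, min_ratio: float = 3.0) -> int:
    """Locate the shutter-opening change point.

    Finds the two-segment split minimising the summed within-segment sum of
    squares (equivalently, maximising the between-segment mean separation)
    and accepts it only when the post/pre mean ratio reaches ``min_ratio``.
    Returns the index of the first post-step bin.
    """
    x = trace.counts_au
    n = x.size
    if n < 10:
        raise NoStepDetected(f"trace too short ({n} bins) for step detection")
    # O(n) scan via prefix sums: SSE(a:b) = sum(x^2) - (sum x)^2 / len
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    ks = np.arange(1, n)
    pre_sse = s2[ks] - s1[ks] ** 2 / ks
    post_sse = (s2[n] - s2[ks]) - (s1[n] - s1[ks]) ** 2 / (n - ks)
    k = int(ks[np.argmin(pre_sse + post_sse)])
    pre_mean = s1[k] / k
    post_mean = (s1[n] - s1[k]) / (n - k)
    if post_mean <= pre_mean:
        raise NoStepDetected("best split is a decrease, not a shutter opening")
    if pre_mean > 0 and post_mean / pre_mean < min_ratio:
        raise NoStepDetected(
            f"step ratio {post_mean / pre_mean:.2f} below min_ratio={min_ratio}"
        )
    return k


# -- prior-light decay ------------------------------------------------------

def fit_prior_light_decay(trace: PhotonTrace,
                          window: tuple[int, int],
                          tau_max_s: float | None = None) -> DecayModel:
    """Least-squares exponential-plus-offset fit on a bin window.

    ``window`` is ``[start_bin, end_bin)``, normally starting at the first
    post-shutter bin.  Time in the model is measured from the window start,
    and ``t_ref_ms`` records that origin so the fitted background can be
    evaluated anywhere later in the trace.

    A decay slower than the window span is not identifiable against the
    constant offset (the fit would trade baseline into a quasi-constant
    "decay" and over-subtract downstream), so tau is bounded above by the
    window duration unless ``tau_max_s`` overrides it.
    """
    a, b = window
    if not (0 <= a < b <= trace.n_bins):
        raise ValueError(f"window {window} outside trace of {trace.n_bins} bins")
    if b - a < 10:
        raise ValueError("decay fit needs at least 10 bins")
    y = trace.counts_au[a:b]
    t_s = (np.arange(b - a) * trace.bin_ms) / 1000.0
    t_ref = trace.t0_ms + a * trace.bin_ms

    flat = float(np.mean(y))
    if np.ptp(y) == 0 or np.std(y) < 1e-12:
        return DecayModel(0.0, tau_s=max(t_s[-1], 1.0), offset_au=flat,
                          t_ref_ms=t_ref, fit_window=(a, b), residual_rms=0.0)

    if tau_max_s is None:
        tau_max_s = max(float(t_s[-1]), 1.0)
    tail = float(np.mean(y[-max(3, y.size // 5):]))
    head = float(np.mean(y[: max(3, y.size // 5)]))
    tau0 = min(max(t_s[-1] / 3.0, 1e-3), 0.9 * tau_max_s)
    p0 = (max(head - tail, 1e-6), tau0, max(tail, 0.0))

    def model(t, amp, tau, off):
        return amp * np.exp(-t / tau) + off

    try:
        popt, _ = curve_fit(
            model, t_s, y, p0=p0,
            bounds=([0.0, 1e-6, 0.0], [np.inf, tau_max_s, np.inf]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.sqrt(np.mean((y - flat) ** 2)))
        raise RuntimeError(
            f"prior-light decay fit failed to converge (flat-residual rms "
            f"{resid:.3g}): {exc}"
        ) from exc
    amp, tau, off = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((y - model(t_s, amp, tau, off)) ** 2)))
    # a fit that collapses to (numerically) zero amplitude is the flat case
    if amp < 1e-9 * max(flat, 1.0):
        return DecayModel(0.0, tau_s=max(t_s[-1], 1.0), offset_au=flat,
                          t_ref_ms=t_ref, fit_window=(a, b), residual_rms=resid)
    return DecayModel(amp, tau_s=tau, offset_au=off, t_ref_ms=t_ref,
                      fit_window=(a, b), residual_rms=resid)


def correct_prior_light(trace: PhotonTrace, model: DecayModel) -> PhotonTrace:
    """Subtract the fitted decaying background, flooring counts at zero."""
    corrected = np.maximum(trace.counts_au - model.background(trace.time_ms), 0.0)
    out = trace.copy_with(corrected)
    out.meta["prior_light_corrected"] = True
    return out


# -- transients -------------------------------------------------------------

def detect_transients(trace: PhotonTrace,
                      baseline_win_ms: float = 600_000.0,
                      k_mad: float = 6.0,
                      min_dur_ms: float = 10_000.0) -> list[TransientEvent]:
    """Find minutes-scale elevations above a rolling-median baseline.

    The baseline is a rolling median over ``baseline_win_ms`` (long relative
    to the transients it must ride under); the threshold sits ``k_mad``
    robust standard deviations (MAD * 1.4826) above it.  An event is a
    maximal run of supra-threshold bins lasting at least ``min_dur_ms``.
    The definition is baseline-relative, so adding a constant to the whole
    trace changes nothing.
    """
    x = trace.counts_au
    if x.size == 0:
        return []
    win = max(3, int(round(baseline_win_ms / trace.bin_ms)) | 1)  # odd
    baseline = median_filter(x, size=min(win, x.size | 1), mode="nearest")
    resid = x - baseline
    sigma = MAD_SCALE * float(np.median(np.abs(resid - np.median(resid))))
    above = resid > k_mad * sigma
    min_bins = max(1, int(np.ceil(min_dur_ms / trace.bin_ms)))

    events: list[TransientEvent] = []
    t = trace.time_ms
    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s < min_bins:
            continue
        seg = resid[s:e]
        p = int(np.argmax(x[s:e]))
        events.append(TransientEvent(
            onset_ms=float(t[s]),
            peak_ms=float(t[s + p]),
            peak_au=float(x[s + p]),
            duration_ms=float((e - s) * trace.bin_ms),
            integral_au_ms=float(np.sum(seg) * trace.bin_ms),
        ))
    return events


def write_transients(events: list[TransientEvent], path) -> None:
    df = pd.DataFrame(
        [(e.onset_ms, e.peak_ms, e.peak_au, e.duration_ms, e.integral_au_ms)
         for e in events],
        columns=["onset_ms", "peak_ms", "peak_au", "duration_ms", "integral_au_ms"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


# -- summary ----------------------------------------------------------------

def summarize_trace(trace: PhotonTrace,
                    duration_min: float | None = None) -> tuple[float, float, int]:
    """Mean and standard error of the per-bin counts over the leading window.

    Returns ``(mean_au, sem_au, n_bins)``; SEM uses the n-1 sample standard
    deviation.  If the trace is shorter than requested, all of it is used.
    """
    if trace.n_bins == 0:
        raise ValueError("cannot summarize an empty trace")
    if duration_min is None:
        x = trace.counts_au
    else:
        n = int(round(duration_min * 60_000.0 / trace.bin_ms))
        if n > trace.n_bins:
            import warnings
            warnings.warn(
                f"trace shorter than {duration_min} min; using all "
                f"{trace.n_bins} bins", stacklevel=2)
        x = trace.counts_au[: max(1, n)]
    mean = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, sem, int(x.size)
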