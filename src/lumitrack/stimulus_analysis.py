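"""Puff-aligned response quantification and pipeline orchestration.

The response statistic is the *percent change*: 100 x (mean luminescence
in a post-stimulus window) / (mean in the pre-stimulus window), both
windows adjacent to the puff.  A ratio (rather than a delta) makes "no
response" read as ~100%, and it is invariant to any overall gain of the
photon channel.  Across trials the group summary is mean +/- SEM (sample
standard deviation, n-1 denominator, over sqrt(n)); no inferential
statistics are produced here.

Behaviour is summarised per trial by whether a crawling stop begins
within a latency window of the puff, and by the pre-to-post drop in mean
speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import photon_stream as ps
from .photon_stream import PhotonTrace
from . import gas_sensor as gs
from . import sync_fusion as sf
from . import tracking as tk
from .config import SessionConfig
from .synthdata import SimulatedSession, marker_roi

__all__ = [
    "StimulusEpoch",
    "GroupSummary",
    "AnalysisParams",
    "extract_epoch",
    "align_and_average",
    "behaviour_response",
    "run_session",
    "analyze_cohort",
]


@dataclass
class StimulusEpoch:
    """Luminescence and behaviour around one puff in one trial."""

    trial_id: str
    kind: str                      # "air" or "co2"
    t_puff_ms: float
    pre_window_ms: float
    post_window_ms: float
    lum_pre_mean_au: float
    lum_post_mean_au: float
    percent_change: float          # 100 * post / pre; NaN if pre <= 0
    speed_pre_mean: float
    speed_post_mean: float
    stopped: bool
    rel_time_ms: np.ndarray = field(repr=False, default=None)
    lum_trace_au: np.ndarray = field(repr=False, default=None)


@dataclass
class GroupSummary:
    """Across-trial aggregate for one stimulus kind."""

    kind: str
    n_trials: int
    mean_percent_change: float
    sem_percent_change: float
    timebase_ms: np.ndarray = field(repr=False, default=None)
    aligned_mean_au: np.ndarray = field(repr=False, default=None)
    aligned_sem_au: np.ndarray = field(repr=False, default=None)


@dataclass
class AnalysisParams:
    """Epoch windows and behavioural criteria (all overridable per run)."""

    pre_ms: float = 60_000.0
    post_ms: float = 120_000.0
    stop_latency_ms: float = 10_000.0
    correct_prior_light: bool = True
    tracking: tk.TrackingParams = field(default_factory=tk.TrackingParams)
    gas_cal: gs.GasCalibration | None = None


def extract_epoch(fused: pd.DataFrame, t_puff_ms: float, kind: str,
                  pre_ms: float = 60_000.0, post_ms: float = 120_000.0,
                  stop_bouts: list | None = None,
                  stop_latency_ms: float = 10_000.0,
                  trial_id: str = "trial") -> StimulusEpoch:
    """Cut one peri-puff epoch out of a fused recording.

    Pre window is [t_puff - pre, t_puff), post window is (t_puff,
    t_puff + post].  Percent change is undefined (NaN) when the pre mean
    is not positive.  ``stopped`` is true when any stop bout begins within
    ``stop_latency_ms`` after the puff.
    """
    t = fused["time_ms"].to_numpy(dtype=float)
    lum = fused["lum_au"].to_numpy(dtype=float)
    speed = fused["speed_px_s"].to_numpy(dtype=float)
    pre_sel = (t >= t_puff_ms - pre_ms) & (t < t_puff_ms)
    post_sel = (t > t_puff_ms) & (t <= t_puff_ms + post_ms)
    if not pre_sel.any() or not post_sel.any():
        raise ValueError("epoch windows fall outside the recording")
    pre = float(np.nanmean(lum[pre_sel]))
    post = float(np.nanmean(lum[post_sel]))
    pct = 100.0 * post / pre if pre > 0 else float("nan")

    stopped = False
    for s, _e in (stop_bouts or []):
        if t_puff_ms <= s <= t_puff_ms + stop_latency_ms:
            stopped = True
            break

    peri = pre_sel | post_sel
    return StimulusEpoch(
        trial_id=trial_id, kind=kind, t_puff_ms=float(t_puff_ms),
        pre_window_ms=float(pre_ms), post_window_ms=float(post_ms),
        lum_pre_mean_au=pre, lum_post_mean_au=post, percent_change=pct,
        speed_pre_mean=float(np.nanmean(speed[pre_sel])),
        speed_post_mean=float(np.nanmean(speed[post_sel])),
        stopped=stopped,
        rel_time_ms=t[peri] - t_puff_ms,
        lum_trace_au=lum[peri],
    )


def align_and_average(epochs: list[StimulusEpoch]) -> GroupSummary:
    """Pointwise mean +/- SEM of puff-aligned traces plus the group statistic.

    All epochs must share the same pre/post window lengths; their traces
    are resampled onto the first epoch's relative timebase (nearest
    sample) before averaging.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    kinds = {e.kind for e in epochs}
    if len(kinds) > 1:
        raise ValueError(f"mixed stimulus kinds in one group: {kinds}")
    wins = {(e.pre_window_ms, e.post_window_ms) for e in epochs}
    if len(wins) > 1:
        raise ValueError(f"mixed epoch window lengths: {wins}")

    base = epochs[0].rel_time_ms
    traces = np.full((len(epochs), base.size), np.nan)
    for i, e in enumerate(epochs):
        idx = np.clip(np.searchsorted(e.rel_time_ms, base), 0,
                      e.rel_time_ms.size - 1)
        traces[i] = e.lum_trace_au[idx]
    mean_tr = np.nanmean(traces, axis=0)
    if len(epochs) > 1:
        sem_tr = np.nanstd(traces, axis=0, ddof=1) / np.sqrt(len(epochs))
    else:
        sem_tr = np.zeros_like(mean_tr)

    pcts = np.array([e.percent_change for e in epochs], dtype=float)
    pcts = pcts[~np.isnan(pcts)]
    if pcts.size == 0:
        raise ValueError("no epoch has a defined percent change")
    mean_pct = float(np.mean(pcts))
    sem_pct = float(np.std(pcts, ddof=1) / np.sqrt(pcts.size)) if pcts.size > 1 else 0.0
    return GroupSummary(
        kind=epochs[0].kind, n_trials=len(epochs),
        mean_percent_change=mean_pct, sem_percent_change=sem_pct,
        timebase_ms=base, aligned_mean_au=mean_tr, aligned_sem_au=sem_tr,
    )


def behaviour_response(epochs: list[StimulusEpoch]) -> dict:
    """Per-stimulus-kind stop fraction and mean pre-to-post speed drop."""
    out: dict[str, dict] = {}
    for kind in sorted({e.kind for e in epochs}):
        grp = [e for e in epochs if e.kind == kind]
        drops = [e.speed_pre_mean - e.speed_post_mean for e in grp]
        out[kind] = {
            "n_trials": len(grp),
            "stop_fraction": float(np.mean([e.stopped for e in grp])),
            "mean_speed_drop_px_s": float(np.nanmean(drops)),
        }
    return out


# -- pipeline ---------------------------------------------------------------

def run_session(session: SimulatedSession,
                params: AnalysisParams | None = None,
                out_dir=None, trial_id: str = "session",
                render: bool = False) -> dict:
    """Full single-session analysis: track -> condition -> sync -> fuse -> epochs.

    Operates on an in-memory session (simulated or loaded from disk).
    Returns a report dict; when ``out_dir`` is given, also writes the
    track, conditioned PMT log, calibrated gas log, fused table, report
    JSON and (optionally) the trajectory heatmap.  Every stage failure is
    re-raised with the stage name attached.
    """
    params = params or AnalysisParams()
    cfg = session.config
    report: dict = {"trial_id": trial_id, "stages": {}}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # tracking
    tparams = params.tracking
    if tparams.marker_roi is None:
        tparams.marker_roi = marker_roi(cfg)
    traj = stage("track", lambda: tk.track(session.video, tparams))
    tk.compute_speed(traj, tparams.smooth_win)
    traj.stop_bouts = tk.detect_stops(
        traj.data["time_ms"].to_numpy(), traj.speed_px_s,
        tparams.stop_thresh_px_s, tparams.min_stop_ms, tparams.merge_gap_ms)
    report["stages"]["track"] = {
        "n_frames": traj.n_frames,
        "n_valid": int(traj.valid_mask.sum()),
        "n_stop_bouts": len(traj.stop_bouts),
    }

    # photon stream conditioning; the shutter is opened before any puff,
    # so the step search is confined to the pre-stimulus portion (a later
    # CO2 response would otherwise dominate the two-segment split)
    pmt_raw = session.pmt
    puff_times = sorted(p.time_ms for p in cfg.puff_events)
    search_end = pmt_raw.n_bins
    if puff_times:
        first_local = puff_times[0] - cfg.pmt_t0_ms
        search_end = min(search_end, int(first_local // pmt_raw.bin_ms))
    pre_stim = PhotonTrace(pmt_raw.counts_au[:search_end],
                           bin_ms=pmt_raw.bin_ms, t0_ms=pmt_raw.t0_ms)
    shutter_bin = stage("pmt_step", lambda: ps.detect_shutter_step(pre_stim))
    pmt = pmt_raw
    decay = None
    if params.correct_prior_light:
        # the decay fit may use every bin free of evoked luminescence:
        # only CO2 puffs inject a response, so air puffs do not shorten
        # the fitting window
        co2_times = sorted(p.time_ms for p in cfg.puff_events
                           if p.kind == "co2")
        end = pmt_raw.n_bins
        if co2_times:
            end = min(end, int((co2_times[0] - cfg.pmt_t0_ms)
                               // pmt_raw.bin_ms))
        if end - shutter_bin >= 10:
            decay = stage("decay_fit", lambda: ps.fit_prior_light_decay(
                pmt_raw, (shutter_bin, end)))
            pmt = ps.correct_prior_light(pmt_raw, decay)
    report["stages"]["pmt"] = {
        "shutter_bin": int(shutter_bin),
        "decay_corrected": decay is not None,
        "decay_tau_s": None if decay is None else round(decay.tau_s, 3),
        "decay_amplitude_au": None if decay is None else round(decay.amplitude_au, 3),
    }

    # gas calibration + onset
    gas_cal = params.gas_cal or cfg.sensor_params
    gas = None
    gas_onsets: dict[str, float] = {}
    if session.gas is not None:
        gas = stage("gas_cal", lambda: gs.calibrate_trace(session.gas, gas_cal))
        try:
            gas_onsets["co2"] = gs.detect_gas_onset(gas)
        except gs.NoOnsetDetected:
            pass
    report["stages"]["gas"] = {
        "present": gas is not None,
        "detected_co2_onset_ms": gas_onsets.get("co2"),
    }

    # synchronization
    shutter_frame = stage("shutter_frame", lambda: sf.detect_shutter_frame(
        session.video, marker_roi(cfg)))
    mapping = sf.build_time_mapping(shutter_bin, shutter_frame,
                                    pmt.bin_ms, cfg.frame_ms)
    report["stages"]["sync"] = {
        "shutter_frame": int(shutter_frame),
        "offset_ms": mapping.offset_ms,
        "scale_frames_per_bin": float(mapping.scale),
    }

    # fusion
    puffs = [(p.time_ms, p.kind) for p in cfg.puff_events]
    fused = stage("fuse", lambda: sf.fuse(traj, pmt, gas, mapping,
                                          shutter_frame, puffs))

    # epochs: use the gas-detected onset for CO2 when available, the
    # scheduled time otherwise (air leaves no trace in the gas channel)
    epochs = []
    for j, (t_puff, kind) in enumerate(puffs):
        t_use = gas_onsets.get(kind, t_puff)
        epochs.append(extract_epoch(
            fused, t_use, kind, params.pre_ms, params.post_ms,
            stop_bouts=traj.stop_bouts, stop_latency_ms=params.stop_latency_ms,
            trial_id=f"{trial_id}/puff{j}"))
    report["epochs"] = [
        {k: v for k, v in asdict(e).items()
         if k not in ("rel_time_ms", "lum_trace_au")}
        for e in epochs
    ]
    report["behaviour"] = behaviour_response(epochs) if epochs else {}
    report["puff_times_used_ms"] = [
        gas_onsets.get(kind, t) for t, kind in puffs]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tk.write_track(traj, out / "track.tsv")
        ps.write_pmt_log(pmt, out / "pmt_conditioned.tsv")
        if gas is not None:
            gs.write_gas_log(gas, out / "gas_ppm.tsv", calibrated=True)
        sf.write_fused(fused, out / "fused.tsv")
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True))
        if render and traj.valid_mask.sum() >= 2:
            import matplotlib.pyplot as plt
            fig, _ = sf.render_trajectory_heatmap(
                fused, out_png=out / "trajectory.png",
                out_tsv=out / "trajectory_colours.tsv")
            plt.close(fig)
    report["_objects"] = {"trajectory": traj, "fused": fused,
                          "epochs": epochs, "mapping": mapping,
                          "decay": decay}
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if not k.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def simulate_cohort(n_co2: int = 7, n_air: int = 7,
                    response_ratio: float = 2.4, seed: int = 0,
                    n_frames: int = 4_200,
                    shutter_ms: float = 10_000.0,
                    puff_ms: float = 80_000.0,
                    pre_ms: float = 60_000.0,
                    post_ms: float = 120_000.0) -> list[SimulatedSession]:
    """Simulate an air-vs-CO2 stimulation cohort, one puff per trial.

    CO2 trials carry an evoked transient whose amplitude is chosen so the
    *expected* post/pre luminescence ratio over the analysis windows equals
    ``response_ratio``; air trials carry none (expected ratio 1).  Trial
    seeds are drawn from one root generator, so the whole cohort is
    reproducible from ``seed``.
    """
    from .config import PuffEvent, SessionConfig
    from .synthdata import amplitude_for_response_ratio, simulate_session

    rng = np.random.default_rng(seed)
    sessions = []
    for kind, n in (("co2", n_co2), ("air", n_air)):
        for _ in range(n):
            cfg = SessionConfig(
                n_frames=n_frames,
                shutter_open_time_ms=shutter_ms,
                puff_events=[PuffEvent(time_ms=puff_ms, kind=kind)],
                rng_seed=int(rng.integers(2**31)),
            )
            cfg.ca_transient.amplitude_au_s = (
                amplitude_for_response_ratio(cfg, response_ratio,
                                             pre_ms, post_ms)
                if kind == "co2" else 0.0)
            sessions.append(simulate_session(cfg))
    return sessions


def analyze_cohort(sessions: list[SimulatedSession],
                   params: AnalysisParams | None = None) -> dict:
    """Analyse a list of single-puff trials and summarise per stimulus kind.

    Returns ``{"epochs": [...], "groups": {kind: GroupSummary},
    "behaviour": {...}}``.
    """
    params = params or AnalysisParams()
    epochs: list[StimulusEpoch] = []
    for i, s in enumerate(sessions):
        rep = run_session(s, params, trial_id=f"trial{i}")
        epochs.extend(rep["_objects"]["epochs"])
    groups = {}
    for kind in sorted({e.kind for e in epochs}):
        groups[kind] = align_and_average([e for e in epochs if e.kind == kind])
    return {
        "epochs": epochs,
        "groups": groups,
        "behaviour": behaviour_response(epochs),
    }
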