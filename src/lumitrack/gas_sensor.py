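"""CO2 sensor calibration and stimulus-onset detection.

A solid-electrolyte CO2 module (MG811 family) reports a voltage in 0-2 V
that *decreases* with CO2 concentration.  Over the datasheet's operating
range the response is well approximated as log-linear (Nernstian):

    V(c) = v_ref + sens * log10(c / c_ref)

with ``sens`` negative.  The calibration is anchored at atmospheric air
(c_ref = 400 ppm by default); ``voltage_to_ppm`` is the exact inverse of
this law and is the same forward model used by the synthetic rig, so the
round trip is an identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GasCalibration",
    "GasTrace",
    "NoOnsetDetected",
    "voltage_to_ppm",
    "ppm_to_voltage",
    "calibrate_trace",
    "detect_gas_onset",
    "read_gas_log",
    "write_gas_log",
    "PPM_VALID_RANGE",
]

#: concentrations outside this window are flagged as out-of-range
PPM_VALID_RANGE = (50.0, 100_000.0)


@dataclass
class GasCalibration:
    """Log-linear voltage <-> ppm law for an MG811-style module.

    The default numbers are placeholders in the datasheet's ballpark and
    MUST be replaced by a per-rig calibration; tests and the simulator
    always pass an explicit calibration.

    Attributes
    ----------
    v_ref_V:
        Module voltage at the reference concentration.
    c_ref_ppm:
        Reference concentration, by convention atmospheric air (400 ppm).
    sens_V_per_decade:
        Voltage change per tenfold concentration increase; negative for
        the MG811's decreasing response.
    v_range:
        Electrical output range of the module.
    """

    v_ref_V: float = 0.30
    c_ref_ppm: float = 400.0
    sens_V_per_decade: float = -0.030
    v_range: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if self.c_ref_ppm <= 0:
            raise ValueError("c_ref_ppm must be positive")
        if self.sens_V_per_decade == 0:
            raise ValueError("sens_V_per_decade must be non-zero")
        lo, hi = self.v_range
        if not (lo <= self.v_ref_V <= hi):
            raise ValueError(
                f"v_ref_V={self.v_ref_V} outside output range {self.v_range}"
            )


@dataclass
class GasTrace:
    """Time series from the gas sensor: raw voltage and/or calibrated ppm."""

    time_ms: np.ndarray
    voltage_V: np.ndarray | None = None
    ppm: np.ndarray | None = None
    sample_ms: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.voltage_V is not None:
            self.voltage_V = np.asarray(self.voltage_V, dtype=float)
        if self.ppm is not None:
            self.ppm = np.asarray(self.ppm, dtype=float)
        if self.time_ms.size > 1 and np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("gas trace timestamps must be strictly increasing")


class NoOnsetDetected(RuntimeError):
    """No sustained concentration rise found in the gas trace."""


def ppm_to_voltage(ppm, cal: GasCalibration):
    """Forward model: concentration (ppm) to module voltage (V), unclipped."""
    ppm = np.asarray(ppm, dtype=float)
    v = cal.v_ref_V + cal.sens_V_per_decade * np.log10(ppm / cal.c_ref_ppm)
    return v if v.ndim else float(v)


def voltage_to_ppm(v, cal: GasCalibration, return_flags: bool = False):
    """Invert the log-linear law; optionally flag out-of-range results.

    The value is always returned, even when it falls outside the sensor's
    plausible range ``PPM_VALID_RANGE``; ``return_flags=True`` additionally
    returns a boolean array marking in-range samples.
    """
    v = np.asarray(v, dtype=float)
    ppm = cal.c_ref_ppm * 10.0 ** ((v - cal.v_ref_V) / cal.sens_V_per_decade)
    in_range = (ppm >= PPM_VALID_RANGE[0]) & (ppm <= PPM_VALID_RANGE[1])
    if ppm.ndim == 0:
        ppm = float(ppm)
        in_range = bool(in_range)
    if return_flags:
        return ppm, in_range
    return ppm


def calibrate_trace(trace: GasTrace, cal: GasCalibration) -> GasTrace:
    """Return a copy of the trace with a calibrated ``ppm`` channel."""
    if trace.voltage_V is None:
        raise ValueError("trace carries no raw voltage channel")
    ppm = voltage_to_ppm(trace.voltage_V, cal)
    return GasTrace(
        time_ms=trace.time_ms.copy(),
        voltage_V=trace.voltage_V.copy(),
        ppm=np.asarray(ppm, dtype=float),
        sample_ms=trace.sample_ms,
        meta=dict(trace.meta),
    )


def detect_gas_onset(
    trace: GasTrace,
    rise_thresh_ppm: float = 100.0,
    sustain_ms: float = 5_000.0,
    baseline_win_ms: float = 30_000.0,
    t_search_from_ms: float | None = None,
) -> float:
    """First time the concentration exceeds baseline + threshold and stays there.

    The baseline is the median ppm over the leading ``baseline_win_ms`` of
    the trace (or of the search window).  Returns the onset time in ms.
    """
    if trace.ppm is None:
        raise ValueError("trace must be calibrated to ppm first")
    t = trace.time_ms
    c = trace.ppm
    if t_search_from_ms is not None:
        sel = t >= t_search_from_ms
        t, c = t[sel], c[sel]
    if t.size == 0:
        raise NoOnsetDetected("empty gas trace")
    base_sel = t <= t[0] + baseline_win_ms
    baseline = float(np.median(c[base_sel]))
    above = c > baseline + rise_thresh_ppm
    # first index i such that every sample in [t[i], t[i] + sustain_ms] is above
    idx = np.flatnonzero(above)
    for i in idx:
        j = np.searchsorted(t, t[i] + sustain_ms, side="right")
        if j > i and above[i:j].all() and t[min(j, t.size) - 1] - t[i] >= sustain_ms - (
            trace.sample_ms or 0.0
        ):
            return float(t[i])
    raise NoOnsetDetected(
        f"no rise of {rise_thresh_ppm} ppm sustained {sustain_ms} ms"
    )


def read_gas_log(path) -> GasTrace:
    """Read a 2-column delimited log (time_ms, voltage_V)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (time_ms, voltage_V)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    sample = float(np.median(np.diff(t))) if t.size > 1 else None
    return GasTrace(time_ms=t, voltage_V=v, sample_ms=sample, meta={"source": str(path)})


def write_gas_log(trace: GasTrace, path, calibrated: bool = False) -> None:
    """Write the trace as TSV: raw (time_ms, voltage_V) or calibrated (time_ms, ppm)."""
    if calibrated:
        if trace.ppm is None:
            raise ValueError("trace has no ppm channel")
        df = pd.DataFrame({"time_ms": trace.time_ms, "ppm": trace.ppm})
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    else:
        if trace.voltage_V is None:
            raise ValueError("trace has no voltage channel")
        df = pd.DataFrame({"time_ms": trace.time_ms, "voltage_V": trace.voltage_V})
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
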