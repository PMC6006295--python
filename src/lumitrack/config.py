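"""Session configuration: the rig constants and stimulus schedule of one recording.

All durations are in milliseconds, positions in pixels, and photon rates in
arbitrary units (au, raw PMT counts) per second.  The same configuration
object drives both the synthetic rig and the analysis defaults, so every
simulated session is fully described by one YAML file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .gas_sensor import GasCalibration

__all__ = [
    "PuffEvent",
    "StopResponse",
    "CaTransientParams",
    "PriorLight",
    "SessionConfig",
    "load_config",
    "save_config",
]

PUFF_KINDS = ("air", "co2")


@dataclass
class PuffEvent:
    """A bolus gas delivery into the chamber."""

    time_ms: float
    kind: str  # "air" or "co2"
    volume_label: str = "200ml"

    def __post_init__(self) -> None:
        if self.kind not in PUFF_KINDS:
            raise ValueError(f"puff kind must be one of {PUFF_KINDS}, got {self.kind!r}")


@dataclass
class StopResponse:
    """Crawling arrest triggered by a CO2 step.

    ``prob`` is the per-trial probability that the animal stops; the stop
    begins ``latency_ms`` after the puff and lasts ``duration_ms``.  Air
    puffs never trigger it.
    """

    prob: float = 1.0
    latency_ms: float = 2_000.0
    duration_ms: float = 20_000.0


@dataclass
class CaTransientParams:
    """Calcium-driven luminescence transient injected by a CO2 puff.

    The kernel is a difference of exponentials normalised to unit peak,
    ``(exp(-t/decay) - exp(-t/rise)) / peak``, scaled by ``amplitude_au_s``
    (added emission rate, au/s, at the kernel peak).  With the default
    rise/decay constants the peak occurs ~73 s after the puff, i.e. slower
    than a minute, matching the slow CO2-evoked rise seen in vivo.
    """

    amplitude_au_s: float = 250.0
    rise_s: float = 60.0
    decay_s: float = 90.0


@dataclass
class PriorLight:
    """Residual PMT contamination from light exposure before the recording.

    Appears as an elevated background that decays exponentially once the
    shutter opens: ``amplitude_au_s * exp(-(t - t_shutter)/tau_s)``.
    """

    amplitude_au_s: float = 60.0
    tau_s: float = 40.0


@dataclass
class SessionConfig:
    """Complete description of one simulated recording session.

    Geometry is in pixels with the arena centred in the frame; the video
    runs at ``1000/frame_ms`` fps and the PMT bins photons every
    ``pmt_bin_ms`` (100 or 2000 ms on the real rig).  ``pmt_t0_ms`` is the
    session time at which PMT logging started — the PMT log's own
    timestamps begin at zero, so a non-zero value creates the inter-stream
    offset that shutter synchronization must recover.
    """

    # geometry / video
    arena_radius_px: float = 100.0
    frame_ms: float = 50.0
    n_frames: int = 2_400
    larva_axes_px: tuple[float, float] = (12.0, 5.0)  # full ellipse axes
    blob_peak_intensity: float = 180.0
    bg_level: float = 10.0
    video_noise_sigma: float = 2.0
    marker_size_px: int = 8
    # photon stream
    pmt_bin_ms: float = 100.0
    pmt_t0_ms: float = 0.0
    dark_rate_au_s: float = 40.0
    baseline_lum_au_s: float = 100.0
    prior_light: PriorLight = field(default_factory=PriorLight)
    ca_transient: CaTransientParams = field(default_factory=CaTransientParams)
    spontaneous_per_min: float = 0.0  # rate of spontaneous transients
    # events
    shutter_open_time_ms: float = 10_000.0
    puff_events: list[PuffEvent] = field(default_factory=list)
    # kinematics
    larva_speed_px_s: float = 6.0
    turn_sigma_rad: float = 0.25  # heading noise per frame
    stop_response: StopResponse = field(default_factory=StopResponse)
    # gas channel
    gas_sample_ms: float = 100.0
    gas_noise_V: float = 0.005
    gas_plateau_ppm: float = 5_000.0
    gas_rise_tau_s: float = 20.0
    adc_bits: int = 10
    sensor_params: GasCalibration = field(
        default_factory=lambda: GasCalibration(
            v_ref_V=1.60, c_ref_ppm=400.0, sens_V_per_decade=-0.60
        )
    )
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_ms

    @property
    def frame_size(self) -> tuple[int, int]:
        """(height, width) of a video frame; arena plus a small margin."""
        side = int(2 * self.arena_radius_px) + 20
        return side, side

    @property
    def arena_center(self) -> tuple[float, float]:
        h, w = self.frame_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)  # (x, y)

    def validate(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if self.n_frames <= 0:
            raise ValueError("session must contain at least one frame")
        if self.pmt_bin_ms <= 0:
            raise ValueError("pmt_bin_ms must be positive")
        ratio = self.pmt_bin_ms / self.frame_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"pmt_bin_ms ({self.pmt_bin_ms}) must be an integer multiple "
                f"of frame_ms ({self.frame_ms})"
            )
        for rate in (
            self.dark_rate_au_s,
            self.baseline_lum_au_s,
            self.prior_light.amplitude_au_s,
            self.ca_transient.amplitude_au_s,
            self.spontaneous_per_min,
        ):
            if rate < 0:
                raise ValueError("all emission rates must be non-negative")
        for p in self.puff_events:
            if not (0 <= p.time_ms <= self.duration_ms):
                raise ValueError(
                    f"puff at {p.time_ms} ms lies outside the session "
                    f"(0..{self.duration_ms} ms)"
                )
        if not (0 <= self.shutter_open_time_ms <= self.duration_ms):
            raise ValueError("shutter_open_time_ms outside the session")
        a, b = self.larva_axes_px
        if max(a, b) / 2.0 >= self.arena_radius_px:
            raise ValueError("larva does not fit in the arena")


# -- YAML round trip --------------------------------------------------------

def _to_plain(cfg: SessionConfig) -> dict:
    d = asdict(cfg)
    d["larva_axes_px"] = list(cfg.larva_axes_px)
    d["sensor_params"]["v_range"] = list(cfg.sensor_params.v_range)
    return d


def save_config(cfg: SessionConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_config(path) -> SessionConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["puff_events"] = [PuffEvent(**p) for p in d.get("puff_events", [])]
    d["stop_response"] = StopResponse(**d.get("stop_response", {}))
    d["ca_transient"] = CaTransientParams(**d.get("ca_transient", {}))
    d["prior_light"] = PriorLight(**d.get("prior_light", {}))
    sp = d.get("sensor_params", {})
    if "v_range" in sp:
        sp["v_range"] = tuple(sp["v_range"])
    d["sensor_params"] = GasCalibration(**sp)
    d["larva_axes_px"] = tuple(d["larva_axes_px"])
    return SessionConfig(**d)
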