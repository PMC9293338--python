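"""Synthetic acquisition generator with known ground truth.

Emulates the structure of the study's raw recordings so every estimator in
the pipeline can be exercised against a known answer:

* side-scatter acquisitions — trains of 92-95 windowed tone bursts sampled
  at 25 MHz, 250 us silence between pulses, with prescribed linear amplitude
  ratios at the harmonics k*f0 (and optionally the subharmonic f0/2) plus an
  additive white Gaussian noise floor;
* through-transmission pairs — a reference (saline) record and a medium
  record whose amplitude is scaled by 10**(-alpha_true*d/20);
* DCE-US clips — per-frame three-pulse responses of a scatter field whose
  nonlinear component follows a triangular bolus-dilution concentration
  curve modulated by pulsatile-flow fluctuation.

Harmonic content is prescribed, not emergent: no bubble-dynamics ODE is
solved and no acoustic field is modelled.  Replicate-to-replicate amplitude
scatter is lognormal multiplicative, which keeps amplitudes positive and
makes the dB statistics approximately Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.signal.windows import gaussian as _gaussian_window

from .dceus import ContrastFrameSet, PulseScheme
from .records import AcquisitionRecord
from .roi import Rect

__all__ = [
    "SimulationConfig",
    "BolusConfig",
    "simulate_scatter_acquisition",
    "simulate_scatter_replicates",
    "simulate_transmission_pair",
    "simulate_transmission_replicates",
    "simulate_reflector_stacks",
    "concentration_curve",
    "simulate_dceus_clip",
    "load_config",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic acquisition.

    Defaults follow the acquisition protocol: 93 tone bursts (92-95
    transmitted per acquisition), 25 MHz sampling, 250 us inter-pulse
    silence, 20-cycle bursts, 15 replicate acquisitions per agent.

    Attributes
    ----------
    f0 : float
        Transmit frequency, MHz.
    n_cycles : int
        Cycles per tone burst (10-20 in the protocol).
    fs : float
        Sampling rate, MHz.
    n_pulses : int
        Tone bursts per acquisition; the protocol transmitted 92-95.
    silence_us : float
        Inter-pulse silence, microseconds.
    harmonic_ratios : dict[int, float]
        Linear amplitude at harmonic order k relative to the fundamental;
        order 1 must map to 1.
    subharmonic_ratio : float
        Amplitude at f0/2 relative to the fundamental.
    noise_rms : float
        RMS of the additive white Gaussian noise floor (same linear units
        as the unit-amplitude fundamental).
    alpha_true : float
        Attenuation coefficient of the simulated medium, dB/cm.
    d : float
        One-way path length in the medium, cm.
    n_replicates : int
        Replicate acquisitions per agent.
    replicate_cv : float
        Coefficient of variation of per-harmonic amplitudes across
        replicates (lognormal multiplicative scatter).
    envelope : str
        Tone-burst envelope, ``"rect"`` (default) or ``"gaussian"``.
    randomize_phases : bool
        Draw harmonic phases uniformly instead of fixing them at zero.
        Amplitude spectra are phase-blind, so this does not move outputs.
    seed : int
        RNG seed; fixes all outputs bit-for-bit.
    """

    f0: float = 2.25
    n_cycles: int = 20
    fs: float = 25.0
    n_pulses: int = 93
    silence_us: float = 250.0
    harmonic_ratios: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    subharmonic_ratio: float = 0.0
    noise_rms: float = 0.01
    alpha_true: float = 0.0
    d: float = 1.0
    n_replicates: int = 15
    replicate_cv: float = 0.1
    envelope: str = "rect"
    randomize_phases: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.fs <= 0:
            raise ValueError("f0 and fs must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 92 <= self.n_pulses <= 95:
            raise ValueError("n_pulses must lie in 92..95 (protocol range)")
        if self.silence_us <= 0:
            raise ValueError("silence_us must be positive")
        self.harmonic_ratios = {int(k): float(v) for k, v in self.harmonic_ratios.items()}
        if self.harmonic_ratios.get(1) != 1.0:
            raise ValueError("harmonic_ratios[1] must equal 1 (fundamental)")
        if any(k < 1 for k in self.harmonic_ratios):
            raise ValueError("harmonic orders must be >= 1")
        if any(v < 0 for v in self.harmonic_ratios.values()) or self.subharmonic_ratio < 0:
            raise ValueError("amplitude ratios must be >= 0")
        k_max = max(k for k, v in self.harmonic_ratios.items() if v > 0)
        if self.fs <= 2 * k_max * self.f0:
            raise ValueError(
                f"aliasing: fs={self.fs} MHz must exceed twice the highest "
                f"harmonic frequency {k_max * self.f0} MHz"
            )
        if self.noise_rms < 0 or self.alpha_true < 0 or self.replicate_cv < 0:
            raise ValueError("noise_rms, alpha_true and replicate_cv must be >= 0")
        if self.d <= 0:
            raise ValueError("path length d must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.envelope not in ("rect", "gaussian"):
            raise ValueError("envelope must be 'rect' or 'gaussian'")

    # --- derived sizes -------------------------------------------------
    @property
    def burst_samples(self) -> int:
        return int(round(self.n_cycles / self.f0 * self.fs))

    @property
    def pulse_period_samples(self) -> int:
        return self.burst_samples + int(round(self.silence_us * self.fs))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)


@dataclass
class BolusConfig:
    """Parameters of a simulated contrast-agent bolus passage.

    The concentration at the imaging plane follows a triangular
    indicator-dilution curve: zero before ``arrival_time``, a linear rise
    to the peak at ``arrival_time + peak_fraction*transit_duration``, and
    a linear fall back to zero over the remaining base.  Conservation
    fixes the peak: integral C dt = dose/flow, so
    C_peak = 2*dose/(flow*transit_duration) with flow in mL/s.

    Defaults: 0.5 mg bolus into a 36 mL/min flow, 40 s clip covering the
    complete wash-in and wash-out, 1 Hz pulsatile-flow fluctuation of the
    peristaltic pump.
    """

    dose: float = 0.5          # mg (or bubble count, any linear quantity)
    flow: float = 36.0         # mL/min
    transit_duration: float = 25.0  # s, triangle base
    arrival_time: float = 5.0  # s
    peak_fraction: float = 0.35    # apex position along the base
    pulsatility_amp: float = 0.1   # relative flow fluctuation
    pulsatility_freq: float = 1.0  # Hz
    frame_rate: float = 10.0   # frames/s
    clip_duration: float = 40.0    # s

    def __post_init__(self) -> None:
        if min(self.dose, self.flow, self.transit_duration) < 0 or self.flow == 0 or self.transit_duration == 0:
            raise ValueError("dose must be >= 0; flow and transit_duration must be > 0")
        if not 0 < self.peak_fraction < 1:
            raise ValueError("peak_fraction must lie in (0, 1)")
        if self.arrival_time < 0 or self.pulsatility_amp < 0:
            raise ValueError("arrival_time and pulsatility_amp must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.clip_duration < self.arrival_time + self.transit_duration:
            raise ValueError("clip_duration must cover arrival_time + transit_duration")

    @property
    def flow_ml_per_s(self) -> float:
        return self.flow / 60.0

    @property
    def peak_concentration(self) -> float:
        """C_peak such that the triangle integrates to dose/flow."""
        return 2.0 * self.dose / (self.flow_ml_per_s * self.transit_duration)

    @property
    def apex_time(self) -> float:
        return self.arrival_time + self.peak_fraction * self.transit_duration

    def to_dict(self) -> dict:
        return asdict(self)


# ----------------------------------------------------------------------
# Side-scatter acquisitions
# ----------------------------------------------------------------------

def _burst(cfg: SimulationConfig, amps: dict[float, float], phases: dict[float, float]) -> np.ndarray:
    """One windowed tone burst with components at the given frequencies (as
    multiples of f0) and linear amplitudes."""
    n = cfg.burst_samples
    t = np.arange(n) / cfg.fs  # microseconds
    sig = np.zeros(n)
    for order, amp in amps.items():
        if amp > 0:
            sig += amp * np.sin(2 * np.pi * order * cfg.f0 * t + phases.get(order, 0.0))
    if cfg.envelope == "gaussian":
        sig *= _gaussian_window(n, std=n / 6.0)
    return sig


def _component_amps(cfg: SimulationConfig, scale: dict[float, float] | float = 1.0) -> dict[float, float]:
    amps: dict[float, float] = {float(k): v for k, v in cfg.harmonic_ratios.items()}
    if cfg.subharmonic_ratio > 0:
        amps[0.5] = cfg.subharmonic_ratio
    if isinstance(scale, dict):
        amps = {k: v * scale.get(k, 1.0) for k, v in amps.items()}
    else:
        amps = {k: v * scale for k, v in amps.items()}
    return amps


def simulate_scatter_acquisition(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    medium: str = "agent",
    amplitude_scale: dict[float, float] | float = 1.0,
    replicate_id: int = 0,
    pressure_kPa: float | None = None,
) -> AcquisitionRecord:
    """Generate one side-scatter acquisition record.

    Each pulse segment is the same windowed tone burst (components at k*f0
    with the configured linear amplitude ratios, optional f0/2 component),
    embedded in seeded white Gaussian noise.  ``amplitude_scale`` scales
    components globally (scalar) or per order (dict keyed like the
    component frequencies in units of f0).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    amps = _component_amps(cfg, amplitude_scale)
    phases: dict[float, float] = {}
    if cfg.randomize_phases:
        phases = {k: rng.uniform(0, 2 * np.pi) for k in amps}
    burst = _burst(cfg, amps, phases)
    period = cfg.pulse_period_samples
    n_total = cfg.n_pulses * period
    samples = np.zeros(n_total)
    pulse_starts = np.arange(cfg.n_pulses) * period
    for start in pulse_starts:
        samples[start : start + burst.size] += burst
    if cfg.noise_rms > 0:
        samples += rng.normal(0.0, cfg.noise_rms, n_total)
    return AcquisitionRecord(
        samples=samples,
        fs=cfg.fs,
        f0=cfg.f0,
        pulse_starts=pulse_starts,
        medium=medium,
        pressure_kPa=pressure_kPa,
        replicate_id=replicate_id,
        n_cycles=cfg.n_cycles,
        travel_time_us=0.0,
    )


def simulate_scatter_replicates(
    cfg: SimulationConfig,
    medium: str = "agent",
    pressure_kPa: float | None = None,
) -> list[AcquisitionRecord]:
    """Generate ``cfg.n_replicates`` acquisitions with lognormal
    per-harmonic amplitude scatter of coefficient of variation
    ``cfg.replicate_cv``."""
    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    component_keys = sorted(_component_amps(cfg).keys())
    records = []
    for r in range(cfg.n_replicates):
        if sigma > 0:
            factors = {
                k: float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
                for k in component_keys
            }
        else:
            factors = {k: 1.0 for k in component_keys}
        records.append(
            simulate_scatter_acquisition(
                cfg, rng=rng, medium=medium, amplitude_scale=factors,
                replicate_id=r, pressure_kPa=pressure_kPa,
            )
        )
    return records


# ----------------------------------------------------------------------
# Through-transmission pairs
# ----------------------------------------------------------------------

def simulate_transmission_pair(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
) -> tuple[AcquisitionRecord, AcquisitionRecord]:
    """Generate a (reference, medium) through-transmission pair.

    The medium record's amplitude is the reference's scaled by
    ``10**(-alpha_true*d/20)``; both share the same noise model with
    independent noise realizations.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    attn = 10.0 ** (-cfg.alpha_true * cfg.d / 20.0)
    ref = simulate_scatter_acquisition(
        cfg, rng=rng, medium="saline", amplitude_scale=amplitude_scale
    )
    med = simulate_scatter_acquisition(
        cfg, rng=rng, medium="agent", amplitude_scale=amplitude_scale * attn
    )
    return ref, med


def simulate_transmission_replicates(
    cfg: SimulationConfig,
) -> list[tuple[AcquisitionRecord, AcquisitionRecord]]:
    """Replicate transmission pairs with common-mode (source-amplitude)
    lognormal scatter per replicate; the common factor cancels in the
    attenuation estimate, as in the physical insertion-loss measurement."""
    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    pairs = []
    for r in range(cfg.n_replicates):
        factor = float(rng.lognormal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0
        ref, med = simulate_transmission_pair(cfg, rng=rng, amplitude_scale=factor)
        ref.replicate_id = med.replicate_id = r
        pairs.append((ref, med))
    return pairs


def simulate_reflector_stacks(
    cfg: SimulationConfig,
    n_frames: int = 100,
    shape: tuple[int, int] = (24, 32),
    plate_rows: tuple[int, int] = (18, 22),
) -> tuple[np.ndarray, np.ndarray]:
    """Echo-mode reflector clips: (saline stack, agent stack) of envelope
    images of a plate behind the cuvette.

    The plate band carries a static speckle pattern whose amplitude in the
    agent clip is reduced by the two-way path loss
    ``10**(-alpha_true*2*d/20)``; per-frame noise uses ``cfg.noise_rms``.
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.full(shape, 0.05)
    r0, r1 = plate_rows
    plate = rng.rayleigh(scale=1.0, size=(r1 - r0, shape[1]))
    two_way = 10.0 ** (-cfg.alpha_true * 2 * cfg.d / 20.0)
    stacks = []
    for gain in (1.0, two_way):
        img = base.copy()
        img[r0:r1, :] = gain * plate
        stack = np.repeat(img[None, :, :], n_frames, axis=0)
        if cfg.noise_rms > 0:
            stack = np.abs(stack + rng.normal(0.0, cfg.noise_rms, stack.shape))
        stacks.append(stack)
    return stacks[0], stacks[1]


# ----------------------------------------------------------------------
# DCE-US clips
# ----------------------------------------------------------------------

def concentration_curve(bolus: BolusConfig, t: np.ndarray) -> np.ndarray:
    """Triangular indicator-dilution concentration at the imaging plane.

    Zero outside [arrival_time, arrival_time + transit_duration]; linear up
    to ``bolus.peak_concentration`` at the apex and linearly back to zero.
    The time integral equals dose/flow exactly (conservation).
    """
    t = np.asarray(t, dtype=float)
    nodes = [bolus.arrival_time, bolus.apex_time, bolus.arrival_time + bolus.transit_duration]
    vals = [0.0, bolus.peak_concentration, 0.0]
    return np.interp(t, nodes, vals, left=0.0, right=0.0)


def _default_response(c: np.ndarray) -> np.ndarray:
    """Concentration -> nonlinear RF amplitude; sqrt so that backscattered
    energy (squared envelope) is proportional to bubble concentration."""
    return np.sqrt(np.asarray(c, dtype=float))


def simulate_dceus_clip(
    cfg: SimulationConfig,
    bolus: BolusConfig,
    response: Callable[[np.ndarray], np.ndarray] | None = None,
    scheme: PulseScheme | None = None,
    shape: tuple[int, int] = (32, 48),
    lumen: Rect | None = None,
    linear_level: float = 1.0,
) -> list[ContrastFrameSet]:
    """Simulate a DCE-US clip as a sequence of three-pulse frame sets.

    Per frame, the three per-pulse RF-like images are::

        p_i = a_i * L + a_i*|a_i| * response(C(t)) * NL + noise_i

    where ``a_i`` are the scheme's relative transmit amplitudes, ``L`` is a
    static linear speckle field covering the whole image, and ``NL`` is a
    static speckle field restricted to the lumen region.  The linear term
    is strictly proportional to transmit amplitude, so the default
    [1, -0.5, -0.5] combination cancels it exactly; the nonlinear term
    carries the transmit sign with a quadratic magnitude (sign-preserving
    quadratic distortion) and survives combination with weight 1/2.

    ``response`` maps local concentration to nonlinear RF amplitude and
    must be monotone nondecreasing; the default is sqrt, making squared-
    envelope intensity proportional to concentration.
    """
    scheme = PulseScheme() if scheme is None else scheme
    response = _default_response if response is None else response
    # monotonicity spot-check of the response curve
    c_probe = np.linspace(0.0, max(bolus.peak_concentration, 1e-12), 17)
    r_probe = np.asarray(response(c_probe), dtype=float)
    if np.any(np.diff(r_probe) < -1e-12):
        raise ValueError("response curve must be monotone nondecreasing")

    rng = np.random.default_rng(cfg.seed)
    ny, nx = shape
    lumen = Rect(0, ny // 3, nx, 2 * ny // 3) if lumen is None else lumen
    lumen.validate_within(shape)

    linear_field = linear_level * rng.rayleigh(scale=1.0, size=shape)
    nl_field = np.zeros(shape)
    ys, xs = lumen.slice()
    nl_field[ys, xs] = rng.rayleigh(scale=1.0, size=(ys.stop - ys.start, xs.stop - xs.start))

    n_frames = int(round(bolus.clip_duration * bolus.frame_rate))
    times = (np.arange(n_frames) + 0.5) / bolus.frame_rate
    conc = concentration_curve(bolus, times)
    if bolus.pulsatility_amp > 0:
        conc = conc * np.clip(
            1.0 + bolus.pulsatility_amp * np.sin(2 * np.pi * bolus.pulsatility_freq * times),
            0.0, None,
        )
    nl_amp = np.asarray(response(conc), dtype=float)

    frames: list[ContrastFrameSet] = []
    for i, t in enumerate(times):
        pulses = []
        for a in scheme.amplitudes:
            img = a * linear_field + a * abs(a) * nl_amp[i] * nl_field
            if cfg.noise_rms > 0:
                img = img + rng.normal(0.0, cfg.noise_rms, shape)
            pulses.append(img)
        frames.append(ContrastFrameSet(p1=pulses[0], p2=pulses[1], p3=pulses[2], timestamp=float(t)))
    return frames


# ----------------------------------------------------------------------
# Configuration files
# ----------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[SimulationConfig, BolusConfig | None]:
    """Load a YAML or JSON configuration mirroring the config field names.

    A top-level ``bolus`` mapping, if present, is returned as a
    :class:`BolusConfig`.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    bolus_data = data.pop("bolus", None)
    cfg = SimulationConfig.from_dict(data)
    bolus = BolusConfig(**bolus_data) if bolus_data is not None else None
    return cfg, bolus
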