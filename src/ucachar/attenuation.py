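"""Attenuation estimation and linear-backscatter analysis.

Through-transmission (insertion-loss) method: the attenuation coefficient
of an agent dispersion over a path of length d cm is

    alpha(f) = (20/d) * log10(T * A_sal(f) / A_CA(f))   [dB/cm]

where A_sal and A_CA are the average fundamental amplitudes with saline and
with the agent in the cuvette and T is the transmit coefficient (default 1,
neglecting reflection losses).  The echo-mode variant reflects the beam off
a plate behind the cuvette, doubling the path (path_factor 2).  The linear
backscatter fraction S_lin = 100 * A_backsc / A_transmit compares the
backscattered to the (reflection-corrected) transmitted amplitude.  A
sound-speed sanity check converts an arrival-time delay into a percent
speed difference versus the reference medium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .records import AcquisitionRecord
from .roi import Rect
from . import spectral

__all__ = [
    "CuvetteGeometry",
    "AttenuationResult",
    "BackscatterRatio",
    "attenuation_through_transmission",
    "attenuation_echo_mode",
    "attenuation_from_records",
    "attenuation_from_replicates",
    "mean_reflector_level",
    "linear_backscatter_fraction",
    "reflection_coefficient",
    "reflection_corrected_transmit",
    "sound_speed_difference",
    "LinearRegimeWarning",
]

WATER_IMPEDANCE_MRAYL = 1.48
ALUMINUM_IMPEDANCE_MRAYL = 17.3
HARMONIC_LINEARITY_LIMIT = 0.05  # 2nd harmonic / fundamental QC threshold


class LinearRegimeWarning(UserWarning):
    """Raised-to-warn when a record's second harmonic exceeds 5% of the
    fundamental, i.e. the linear-oscillation assumption of the attenuation
    measurement is questionable."""


@dataclass
class CuvetteGeometry:
    """Path geometry of the cuvette measurement.

    d is the one-way path length in the agent medium (cm), T the transmit
    coefficient (1 neglects all reflection losses), and path_factor 1 for
    through-transmission or 2 for echo mode (forward and backward pass).
    """

    d: float = 1.0
    T: float = 1.0
    path_factor: int = 1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("path length d must be positive")
        if not 0 < self.T <= 1:
            raise ValueError("transmit coefficient T must lie in (0, 1]")
        if self.path_factor not in (1, 2):
            raise ValueError("path_factor must be 1 (transmission) or 2 (echo)")


@dataclass
class AttenuationResult:
    """Replicate-aggregated attenuation estimate at one frequency."""

    f: float              # MHz
    alpha: np.ndarray     # per-replicate estimates, dB/cm
    mean: float
    std: float
    n_replicates: int

    @classmethod
    def from_values(cls, f: float, values: np.ndarray | list[float]) -> "AttenuationResult":
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("attenuation estimates must be finite")
        std = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return cls(f=f, alpha=values, mean=float(values.mean()), std=std,
                   n_replicates=int(values.size))


@dataclass
class BackscatterRatio:
    """Linear backscatter fraction at one frequency."""

    f: float
    s_lin: float          # percent
    a_backsc: float
    a_transmit: float

    def __post_init__(self) -> None:
        if self.a_transmit <= 0:
            raise ValueError("a_transmit must be positive")
        if self.s_lin < 0:
            raise ValueError("s_lin must be >= 0")


def attenuation_through_transmission(
    a_sal: float, a_ca: float, geom: CuvetteGeometry | None = None
) -> float:
    """Insertion-loss attenuation coefficient in dB/cm,
    (20/(path_factor*d)) * log10(T * a_sal / a_ca)."""
    geom = CuvetteGeometry() if geom is None else geom
    if a_sal <= 0 or a_ca <= 0:
        raise ValueError("amplitudes must be positive")
    return (20.0 / (geom.path_factor * geom.d)) * math.log10(geom.T * a_sal / a_ca)


def attenuation_echo_mode(
    gray_sal: float, gray_ca: float, geom: CuvetteGeometry | None = None
) -> float:
    """Echo-mode attenuation from mean reflector gray levels; the beam
    crosses the agent twice, so the effective path is 2d."""
    geom = CuvetteGeometry(path_factor=2) if geom is None else geom
    if geom.path_factor != 2:
        raise ValueError("echo mode uses path_factor=2 (forward and backward pass)")
    if gray_sal <= 0 or gray_ca <= 0:
        raise ValueError("gray levels must be positive")
    return attenuation_through_transmission(gray_sal, gray_ca, geom)


def _fundamental_amplitude(rec: AcquisitionRecord, window_us: float | None, qc: bool) -> float:
    """Average spectral amplitude at f0 (and the 5%-harmonic linearity QC)."""
    if window_us is None:
        n_cycles = rec.n_cycles if rec.n_cycles else 16
        window_us = n_cycles / rec.f0
    orders = [1.0, 2.0] if qc else [1.0]
    table = spectral.harmonic_response(rec, orders=orders, window_us=window_us)
    a_f0 = table.value_at(1.0)
    if qc:
        ratio = table.value_at(2.0) / a_f0
        if ratio > HARMONIC_LINEARITY_LIMIT:
            warnings.warn(
                f"record (medium={rec.medium!r}, replicate={rec.replicate_id}) has a "
                f"2nd-harmonic/fundamental ratio of {ratio:.3f} > "
                f"{HARMONIC_LINEARITY_LIMIT}; the linear-regime assumption of the "
                "attenuation measurement may not hold",
                LinearRegimeWarning,
                stacklevel=3,
            )
    return a_f0


def attenuation_from_records(
    ref: AcquisitionRecord,
    agent: AcquisitionRecord,
    geom: CuvetteGeometry | None = None,
    window_us: float | None = None,
    qc: bool = True,
) -> float:
    """Estimate alpha from a (saline, agent) record pair.

    The fundamental amplitude of each record is extracted from its averaged
    amplitude spectrum at f0 (not from the time-domain peak), then fed to
    the insertion-loss formula.  The analysis window defaults to the burst
    duration n_cycles/f0.  With ``qc`` enabled, a warning flags agent
    records whose second harmonic exceeds 5% of the fundamental.
    """
    if ref.f0 != agent.f0 or ref.fs != agent.fs:
        raise ValueError("reference and agent records must share f0 and fs")
    a_sal = _fundamental_amplitude(ref, window_us, qc=False)
    a_ca = _fundamental_amplitude(agent, window_us, qc=qc)
    return attenuation_through_transmission(a_sal, a_ca, geom)


def attenuation_from_replicates(
    pairs: list[tuple[AcquisitionRecord, AcquisitionRecord]],
    geom: CuvetteGeometry | None = None,
    window_us: float | None = None,
    qc: bool = True,
) -> AttenuationResult:
    """Replicate protocol: one alpha per (saline, agent) pair, aggregated
    as mean +/- sample standard deviation."""
    if len(pairs) == 0:
        raise ValueError("need at least one record pair")
    values = [
        attenuation_from_records(ref, agent, geom=geom, window_us=window_us, qc=qc)
        for ref, agent in pairs
    ]
    return AttenuationResult.from_values(f=pairs[0][0].f0, values=values)


def mean_reflector_level(frames: np.ndarray, roi: Rect) -> float:
    """Mean gray level of an envelope-image stack over the ROI and all
    frames (e.g. the reflector plate over 100 frames)."""
    stack = np.asarray(frames, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("frames must be a non-empty stack of 2-d images")
    roi.validate_within(stack.shape[1:])
    ys, xs = roi.slice()
    return float(stack[:, ys, xs].mean())


def linear_backscatter_fraction(a_backsc: float, a_transmit: float) -> float:
    """S_lin in percent: 100 * a_backsc / a_transmit."""
    if a_transmit <= 0:
        raise ValueError("transmit amplitude must be positive")
    if a_backsc < 0:
        raise ValueError("backscatter amplitude must be >= 0")
    return 100.0 * a_backsc / a_transmit


def reflection_coefficient(
    z1: float = WATER_IMPEDANCE_MRAYL, z2: float = ALUMINUM_IMPEDANCE_MRAYL
) -> float:
    """Pressure reflection coefficient (Z2-Z1)/(Z2+Z1) of a planar
    interface at normal incidence; defaults: water into aluminum."""
    if z1 <= 0 or z2 <= 0:
        raise ValueError("acoustic impedances must be positive")
    return (z2 - z1) / (z2 + z1)


def reflection_corrected_transmit(gray_plate: float, r_interface: float) -> float:
    """Sonicating amplitude from the plate gray level: the plate reflects
    only a fraction r of the incident pressure, so divide by r."""
    if not 0 < r_interface <= 1:
        raise ValueError("reflection coefficient must lie in (0, 1]")
    if gray_plate < 0:
        raise ValueError("gray level must be >= 0")
    return gray_plate / r_interface


def sound_speed_difference(delay_us: float, d_cm: float, c_ref: float = 1480.0) -> float:
    """Percent sound-speed difference implied by an arrival-time delay.

    A pulse covering d cm at the reference speed c_ref (m/s) arrives after
    t_ref = d/c_ref; an extra delay means the medium speed is
    c = d/(t_ref + delay).  Returns 100*(c_ref - c)/c_ref (positive for a
    slower medium).
    """
    if d_cm <= 0 or c_ref <= 0:
        raise ValueError("path length and reference speed must be positive")
    t_ref_s = (d_cm / 100.0) / c_ref
    t_s = t_ref_s + delay_us * 1e-6
    if t_s <= 0:
        raise ValueError("total travel time must be positive")
    c = (d_cm / 100.0) / t_s
    return 100.0 * (c_ref - c) / c_ref
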