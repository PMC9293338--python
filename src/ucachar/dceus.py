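"""Contrast-specific three-pulse imaging and bolus time-intensity analysis.

Implements the pulse-inversion + amplitude-modulation (PI+AM) scheme: three
pulses with relative transmit amplitudes [1, -0.5, -0.5] (the second and
third half the amplitude of the first and phase-shifted by 180 degrees).
Summing the three received responses cancels any echo that is linear in
transmit amplitude and retains nonlinear scattering.  Downstream tools
form maximum-intensity projections, extract linearized (squared-envelope)
ROI time-intensity curves, compare their peaks, and apply the triangular
indicator-dilution model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .roi import Rect

__all__ = [
    "PulseScheme",
    "ContrastFrameSet",
    "TIC",
    "TriangularBolus",
    "combine_pulses",
    "combine_frames",
    "max_intensity_projection",
    "extract_tic",
    "smooth_tic",
    "peak_percent_difference",
    "triangular_peak_concentration",
    "normalize_tics",
]


@dataclass
class PulseScheme:
    """PI+AM transmit scheme: one full-amplitude pulse and two half-amplitude
    inverted pulses, three cycles at 3.5 MHz, MI 0.2 by default."""

    amplitudes: tuple[float, float, float] = (1.0, -0.5, -0.5)
    f0: float = 3.5      # MHz
    n_cycles: int = 3
    mi: float = 0.2

    def __post_init__(self) -> None:
        if len(self.amplitudes) != 3:
            raise ValueError("the scheme uses exactly three pulses")
        a1, a2, a3 = self.amplitudes
        if not (abs(abs(a2) - abs(a1) / 2) < 1e-12 and abs(abs(a3) - abs(a1) / 2) < 1e-12):
            raise ValueError("pulses 2 and 3 must have half the amplitude of pulse 1")
        if abs(sum(self.amplitudes)) > 1e-12:
            raise ValueError("scheme amplitudes must sum to zero (linear cancellation)")


@dataclass
class ContrastFrameSet:
    """Per-frame responses of the three-pulse scheme.

    ``p1``..``p3`` are the RF-like signed response images of the three
    pulses; ``pnonl`` is the combined nonlinear image, defined once
    :func:`combine_pulses` has run.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    pnonl: np.ndarray | None = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if not (self.p1.shape == self.p2.shape == self.p3.shape):
            raise ValueError("p1, p2, p3 must have identical shapes")
        if self.pnonl is not None and self.pnonl.shape != self.p1.shape:
            raise ValueError("pnonl shape must match the pulse images")

    def combine(self) -> np.ndarray:
        self.pnonl = combine_pulses(self.p1, self.p2, self.p3)
        return self.pnonl


@dataclass
class TIC:
    """ROI time-intensity curve on a linear intensity scale."""

    t: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def peak_value(self) -> float:
        return float(np.max(self.intensity))

    @property
    def peak_time(self) -> float:
        return float(self.t[int(np.argmax(self.intensity))])


@dataclass(frozen=True)
class TriangularBolus:
    """Triangular indicator-dilution summary: peak concentration and the
    mixing volume implied by conservation (integral C dt = dose/flow)."""

    dose: float              # mg or bubbles
    flow: float              # mL/min
    duration: float          # s, triangle base
    peak_concentration: float  # quantity per mL
    mixing_volume: float     # mL


def combine_pulses(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Combine the three pulse responses into the nonlinear image.

    The sum ``p1 + p2 + p3`` is computed on the RF-like signed responses
    (before envelope detection), so any response that is linear in transmit
    amplitude cancels exactly under the [1, -0.5, -0.5] scheme.  Take the
    envelope (absolute value) after summation.
    """
    p1, p2, p3 = (np.asarray(p) for p in (p1, p2, p3))
    if not (p1.shape == p2.shape == p3.shape):
        raise ValueError("pulse responses must have identical shapes")
    return p1 + p2 + p3


def combine_frames(frames: Sequence[ContrastFrameSet]) -> tuple[np.ndarray, np.ndarray]:
    """Combine every frame set of a clip; returns (times, envelope images).

    Envelopes are the absolute value of the summed RF-like responses.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    times = np.array([f.timestamp for f in frames])
    env = np.stack([np.abs(f.combine()) for f in frames])
    return times, env


def max_intensity_projection(frames: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum over the frames of a clip."""
    stack = np.asarray(frames)
    if stack.ndim < 3 or stack.shape[0] == 0:
        raise ValueError("need at least one frame of equal shape")
    return stack.max(axis=0)


def extract_tic(
    frames: np.ndarray | Sequence[np.ndarray],
    roi: Rect,
    frame_times: np.ndarray,
) -> TIC:
    """Extract the linearized ROI time-intensity curve from envelope images.

    Intensity per frame is the ROI mean of the squared envelope: the
    recordings use no log compression, gray levels are signal envelopes,
    so the linear (energy) scale is the square.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("frames must be a non-empty stack of 2-d images")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.shape[0] != stack.shape[0]:
        raise ValueError("frame_times must match the number of frames")
    roi.validate_within(stack.shape[1:])
    ys, xs = roi.slice()
    intensity = np.mean(stack[:, ys, xs] ** 2, axis=(1, 2))
    return TIC(t=frame_times, intensity=intensity)


def smooth_tic(tic: TIC, window_s: float) -> TIC:
    """Moving-average smoother; window of one pulsation period suppresses
    the periodic pulsatile-flow fluctuation."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    dt = float(np.median(np.diff(tic.t)))
    n = max(1, int(round(window_s / dt)))
    kernel = np.ones(n) / n
    padded = np.pad(tic.intensity, (n // 2, n - 1 - n // 2), mode="edge")
    return TIC(t=tic.t, intensity=np.convolve(padded, kernel, mode="valid"))


def peak_percent_difference(tic_a: TIC, tic_b: TIC) -> float:
    """Percent difference of peak intensities, 100*(peak_a - peak_b)/peak_b.

    Positive when A's peak exceeds B's; -23 means "23% lower".
    """
    if tic_a.peak_value <= 0 or tic_b.peak_value <= 0:
        raise ValueError("both TIC peaks must be positive")
    return 100.0 * (tic_a.peak_value - tic_b.peak_value) / tic_b.peak_value


def triangular_peak_concentration(dose: float, flow: float, duration: float) -> TriangularBolus:
    """Peak concentration and mixing volume of the triangular bolus model.

    Only conservation is assumed (no isoceles shape): the time integral of
    a triangle of base ``duration`` and height ``C_peak`` equals
    ``C_peak*duration/2``, and it must equal ``dose/flow``, giving
    ``C_peak = 2*dose/(flow*duration)`` with flow converted to mL/s.
    The mixing volume is ``dose/C_peak``.

    Parameters
    ----------
    dose : injected quantity (mg or bubbles)
    flow : volumetric flow, mL/min
    duration : triangle base duration, s
    """
    if dose <= 0 or flow <= 0 or duration <= 0:
        raise ValueError("dose, flow and duration must be positive")
    q = flow / 60.0  # mL/s
    c_peak = 2.0 * dose / (q * duration)
    return TriangularBolus(
        dose=dose, flow=flow, duration=duration,
        peak_concentration=c_peak, mixing_volume=dose / c_peak,
    )


def normalize_tics(tics: Sequence[TIC]) -> list[TIC]:
    """Normalize a family of TICs to the maximum peak among them; the
    largest resulting peak is exactly 1."""
    if len(tics) == 0:
        raise ValueError("need at least one TIC")
    max_peak = max(t.peak_value for t in tics)
    if max_peak <= 0:
        raise ValueError("all TICs are zero; nothing to normalize")
    return [TIC(t=t.t, intensity=t.intensity / max_peak) for t in tics]
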