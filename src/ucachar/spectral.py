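"""Averaged amplitude spectra, harmonic extraction and nonlinear-scatter
statistics.

The scattered signal of each acquisition is cut into one fixed-length
segment per pulse (9 us by default), each segment is tapered with a Hanning
window to reduce spectral leakage, and the amplitude (not power) spectra
are averaged over the pulses.  Harmonic amplitudes are read off the
averaged spectrum as local maxima around k*f0.  Two dB statistics quantify
nonlinear scatter:

* relative to the saline (noise) reference, S_nonl(f) = 10*log10(A_CA/A_sal);
* relative to the fundamental,              S_nonl(f) = 10*log10(A_CA(f)/A_CA(f0)).

Both use the 10*log10 amplitude-ratio form as published; pass
``db_factor=20`` for the conventional amplitude-dB scale.  Replicates are
summarized as mean +/- sample standard deviation, and agents are compared
per harmonic with a two-tailed Student t-test at the 0.05 level (no
multiple-testing correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window

from .records import AcquisitionRecord

__all__ = [
    "Spectrum",
    "HarmonicTable",
    "ReplicateSummary",
    "segment_pulses",
    "averaged_amplitude_spectrum",
    "extract_harmonics",
    "snonl_vs_saline",
    "snonl_vs_fundamental",
    "harmonic_table_vs_saline",
    "harmonic_response",
    "summarize_replicates",
    "compare_agents_ttest",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05
DEFAULT_WINDOW_US = 9.0
DEFAULT_PAD_FACTOR = 8


@dataclass
class Spectrum:
    """Averaged amplitude spectrum of the pulse segments of one acquisition."""

    freqs: np.ndarray            # MHz, uniform, nonnegative
    amplitude: np.ndarray        # mean linear amplitude per frequency
    n_pulses_averaged: int
    segment_length_us: float = DEFAULT_WINDOW_US
    window: str = "hann"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.freqs.shape != self.amplitude.shape:
            raise ValueError("freqs and amplitude must have equal length")
        if self.n_pulses_averaged < 1:
            raise ValueError("n_pulses_averaged must be >= 1")
        if np.any(self.amplitude < 0) or np.any(self.freqs < 0):
            raise ValueError("freqs and amplitude must be nonnegative")

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class HarmonicTable:
    """Per-order harmonic amplitudes of one acquisition, with the dB
    statistics filled in where their references are available.

    Orders support 0.5 (subharmonic) and the integers 1..K.  The
    fundamental-normalized statistic is exactly 0 at order 1.
    """

    f0: float
    orders: np.ndarray
    amplitude: np.ndarray
    snonl_saline_dB: np.ndarray | None = None
    snonl_fund_dB: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.orders.shape != self.amplitude.shape:
            raise ValueError("orders and amplitude must align")

    def value_at(self, order: float, which: str = "amplitude") -> float:
        idx = np.flatnonzero(np.isclose(self.orders, order))
        if idx.size == 0:
            raise KeyError(f"order {order} not in table")
        return float(getattr(self, which)[idx[0]])


@dataclass
class ReplicateSummary:
    """Mean and sample standard deviation of a per-order dB statistic over
    replicate acquisitions, with optional pairwise-comparison p-values."""

    orders: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_replicates: int
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be >= 0")
        if self.p_values is not None:
            p = np.asarray(self.p_values, dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValueError("p-values must lie in [0, 1]")
            self.p_values = p


def segment_pulses(
    rec: AcquisitionRecord,
    window_us: float = DEFAULT_WINDOW_US,
    offset_us: float | None = None,
) -> np.ndarray:
    """Cut one fixed-length analysis segment per pulse.

    The segment starts ``offset_us`` after each pulse start (default: the
    record's stored acoustic travel time, a deterministic stand-in for the
    manual window placement) and is exactly ``round(window_us*fs)`` samples
    long.  Raises if the window overruns the inter-pulse spacing.
    """
    if window_us <= 0:
        raise ValueError("window_us must be positive")
    offset_us = rec.travel_time_us if offset_us is None else offset_us
    n_win = int(round(window_us * rec.fs))
    n_off = int(round(offset_us * rec.fs))
    starts = rec.pulse_starts + n_off
    ends = starts + n_win
    limits = np.append(rec.pulse_starts[1:], rec.samples.size)
    if np.any(ends > limits):
        raise ValueError(
            f"analysis window of {window_us} us (+{offset_us} us offset) "
            "overruns the inter-pulse spacing"
        )
    return np.stack([rec.samples[s:e] for s, e in zip(starts, ends)])


def averaged_amplitude_spectrum(
    segments: np.ndarray,
    window: str = "hann",
    fs: float = 25.0,
    nfft: int | None = None,
) -> Spectrum:
    """Average the amplitude spectra of tapered, equal-length segments.

    The amplitude at each frequency is the mean over segments of the
    magnitude of the discrete Fourier transform of the tapered segment,
    normalized so a unit-amplitude tone at a bin center reads 1.  ``nfft``
    zero-pads the transform onto a finer grid (default: the segment
    length, i.e. the native grid fs/len(segment)).
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim == 1:
        segments = segments[None, :]
    if segments.size == 0 or segments.shape[0] == 0:
        raise ValueError("empty segment list")
    m = segments.shape[1]
    taper = get_window(window, m, fftbins=True)
    nfft = m if nfft is None else int(nfft)
    if nfft < m:
        raise ValueError("nfft must be >= segment length")
    spectra = np.abs(rfft(segments * taper, n=nfft, axis=1))
    amplitude = spectra.mean(axis=0) * (2.0 / taper.sum())
    freqs = rfftfreq(nfft, d=1.0 / fs)
    return Spectrum(
        freqs=freqs,
        amplitude=amplitude,
        n_pulses_averaged=segments.shape[0],
        segment_length_us=m / fs,
        window=window,
    )


def extract_harmonics(
    spec: Spectrum,
    f0: float,
    orders: np.ndarray | list[float],
    search_halfwidth: float,
) -> HarmonicTable:
    """Read per-order harmonic amplitudes off an averaged spectrum.

    The amplitude at order k is the maximum spectrum amplitude within
    +/- ``search_halfwidth`` (MHz) of k*f0; a zero halfwidth degenerates
    to the nearest grid bin.  The fundamental-normalized dB statistic is
    filled when order 1 is requested.
    """
    orders = np.asarray(orders, dtype=float)
    if np.max(orders) * f0 >= spec.nyquist:
        raise ValueError(
            f"order {np.max(orders)} at f0={f0} MHz exceeds the Nyquist "
            f"frequency {spec.nyquist} MHz"
        )
    if search_halfwidth < 0:
        raise ValueError("search_halfwidth must be >= 0")
    amps = np.empty_like(orders)
    for i, k in enumerate(orders):
        target = k * f0
        mask = np.abs(spec.freqs - target) <= search_halfwidth
        if not np.any(mask):
            mask = np.zeros_like(mask)
            mask[np.argmin(np.abs(spec.freqs - target))] = True
        amps[i] = spec.amplitude[mask].max()
    table = HarmonicTable(f0=f0, orders=orders, amplitude=amps)
    fund_idx = np.flatnonzero(np.isclose(orders, 1.0))
    if fund_idx.size:
        a_f0 = amps[fund_idx[0]]
        table.snonl_fund_dB = np.array(
            [snonl_vs_fundamental(a, a_f0) for a in amps]
        )
        table.snonl_fund_dB[fund_idx[0]] = 0.0
    return table


def snonl_vs_saline(a_ca: float, a_sal: float, db_factor: float = 10.0) -> float:
    """Nonlinear scatter relative to the saline reference,
    ``db_factor*log10(a_ca/a_sal)``; the published form uses 10*log10 on
    amplitudes (pass ``db_factor=20`` for the conventional amplitude dB)."""
    if a_sal <= 0:
        raise ValueError("saline reference amplitude must be positive")
    if a_ca < 0:
        raise ValueError("agent amplitude must be nonnegative")
    return db_factor * math.log10(a_ca / a_sal)


def snonl_vs_fundamental(a_f: float, a_f0: float, db_factor: float = 10.0) -> float:
    """Nonlinear scatter relative to the fundamental,
    ``db_factor*log10(a_f/a_f0)``; 0 at f = f0 by construction."""
    if a_f0 <= 0:
        raise ValueError("fundamental amplitude must be positive")
    if a_f < 0:
        raise ValueError("amplitude must be nonnegative")
    return db_factor * math.log10(a_f / a_f0)


def harmonic_table_vs_saline(
    agent: HarmonicTable, saline: HarmonicTable, db_factor: float = 10.0
) -> HarmonicTable:
    """Fill the saline-normalized dB statistic of an agent table using a
    saline table extracted at the same orders."""
    if not np.allclose(agent.orders, saline.orders):
        raise ValueError("agent and saline tables must share the same orders")
    agent.snonl_saline_dB = np.array(
        [
            snonl_vs_saline(a, s, db_factor=db_factor)
            for a, s in zip(agent.amplitude, saline.amplitude)
        ]
    )
    return agent


def harmonic_response(
    rec: AcquisitionRecord,
    orders: np.ndarray | list[float],
    window_us: float = DEFAULT_WINDOW_US,
    offset_us: float | None = None,
    search_halfwidth: float | None = None,
    pad_factor: int = DEFAULT_PAD_FACTOR,
    taper: str = "hann",
) -> HarmonicTable:
    """Full spectral pipeline for one record: segment, average, extract.

    ``search_halfwidth`` defaults to f0/n_cycles (half the transmit -6 dB
    bandwidth of an n_cycles burst).  The spectrum is zero-padded by
    ``pad_factor`` so sub-bin frequency offsets cost well under 0.1 dB in
    peak amplitude.
    """
    if search_halfwidth is None:
        n_cycles = rec.n_cycles if rec.n_cycles else 16
        search_halfwidth = rec.f0 / n_cycles
    segments = segment_pulses(rec, window_us=window_us, offset_us=offset_us)
    nfft = segments.shape[1] * max(1, int(pad_factor))
    spec = averaged_amplitude_spectrum(segments, window=taper, fs=rec.fs, nfft=nfft)
    return extract_harmonics(spec, rec.f0, orders, search_halfwidth)


def summarize_replicates(
    tables: list[HarmonicTable], statistic: str = "snonl_fund_dB"
) -> ReplicateSummary:
    """Per-order mean and sample standard deviation (ddof=1) of a dB
    statistic over replicate tables (15 acquisitions in the protocol)."""
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    orders = tables[0].orders
    for t in tables[1:]:
        if not np.allclose(t.orders, orders):
            raise ValueError("replicate tables must share the same orders")
    values = []
    for t in tables:
        v = getattr(t, statistic)
        if v is None:
            raise ValueError(f"statistic {statistic!r} not filled in a table")
        values.append(np.asarray(v, dtype=float))
    stacked = np.stack(values)
    return ReplicateSummary(
        orders=orders,
        mean=stacked.mean(axis=0),
        std=stacked.std(axis=0, ddof=1),
        n_replicates=len(tables),
    )


def compare_agents_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, bool]:
    """Two-sided two-sample t-test between per-replicate values of two
    agents; returns (p, significant at 0.05).

    Pooled-variance Student test by default (``equal_var=False`` for
    Welch).  Two identical zero-variance groups return p = 1; zero
    variance with different means returns p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
        return p, p < SIGNIFICANCE_LEVEL
    p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return p, p < SIGNIFICANCE_LEVEL
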