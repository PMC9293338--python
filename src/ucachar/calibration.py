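"""Calibration and protocol arithmetic: MI <-> pressure, dilutions.

The mechanical index uses the standard regulatory definition with no
derating: MI = PNP[MPa] / sqrt(f[MHz]).  Reported pressures round to the
nearest 10 kPa by default.  Dilution arithmetic converts a stock mass and
volume plus an aliquot/diluent step into a final concentration and, given
a user-supplied per-mg bubble count, into a number density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CalibrationPoint",
    "DilutionSpec",
    "mi_to_pressure",
    "pressure_to_mi",
    "dilution_concentration",
    "number_density",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One transducer calibration point: transmit frequency, mechanical
    index and the corresponding peak negative pressure."""

    f: float      # MHz
    mi: float     # dimensionless
    pnp: float    # kPa

    def __post_init__(self) -> None:
        if min(self.f, self.mi, self.pnp) <= 0:
            raise ValueError("f, mi and pnp must be positive")
        # MI definition must hold within reporting precision (10 kPa rounding)
        if abs(self.pnp - self.mi * math.sqrt(self.f) * 1000.0) > 5.0 + 1e-9:
            raise ValueError(
                f"inconsistent calibration point: MI {self.mi} at {self.f} MHz "
                f"implies {self.mi * math.sqrt(self.f) * 1000.0:.1f} kPa, got {self.pnp}"
            )


@dataclass(frozen=True)
class DilutionSpec:
    """A two-step dilution: stock_mass mg in stock_volume mL, then an
    aliquot diluted into a diluent volume."""

    stock_mass: float   # mg
    stock_volume: float  # mL
    aliquot: float      # mL
    diluent: float      # mL

    def __post_init__(self) -> None:
        if min(self.stock_mass, self.stock_volume, self.aliquot) <= 0 or self.diluent < 0:
            raise ValueError("masses and volumes must be positive (diluent >= 0)")

    @property
    def final_concentration(self) -> float:
        return dilution_concentration(self)


def mi_to_pressure(mi: float, f: float, round_to: float | None = 10.0) -> float:
    """Peak negative pressure in kPa for a mechanical index at frequency f
    (MHz): mi * sqrt(f) * 1000, rounded to the nearest ``round_to`` kPa
    (default 10; pass None for the unrounded value)."""
    if mi <= 0 or f <= 0:
        raise ValueError("mi and f must be positive")
    pnp = mi * math.sqrt(f) * 1000.0
    if round_to is not None:
        pnp = round(pnp / round_to) * round_to
    return pnp


def pressure_to_mi(pnp_kPa: float, f: float) -> float:
    """Mechanical index of a peak negative pressure (kPa) at frequency f
    (MHz): (pnp/1000)/sqrt(f)."""
    if pnp_kPa <= 0 or f <= 0:
        raise ValueError("pressure and frequency must be positive")
    return (pnp_kPa / 1000.0) / math.sqrt(f)


def dilution_concentration(spec: DilutionSpec, ndigits: int | None = None) -> float:
    """Final concentration in mg/mL:
    (stock_mass/stock_volume) * aliquot/(aliquot + diluent), optionally
    rounded to ``ndigits`` decimals."""
    conc = (spec.stock_mass / spec.stock_volume) * spec.aliquot / (spec.aliquot + spec.diluent)
    return round(conc, ndigits) if ndigits is not None else conc


def number_density(concentration_mg_per_mL: float, bubbles_per_mg: float) -> float:
    """Bubble number density (bubbles/mL) from a mass concentration and a
    user-supplied per-mg bubble count."""
    if concentration_mg_per_mL < 0 or bubbles_per_mg <= 0:
        raise ValueError("concentration must be >= 0 and bubbles_per_mg > 0")
    return concentration_mg_per_mL * bubbles_per_mg
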