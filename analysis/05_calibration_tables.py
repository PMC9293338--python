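#!/usr/bin/env python
"""Calibration and protocol arithmetic tables.

MI <-> peak-negative-pressure pairs for the three transducers, the agent
dilution chain with number densities, and the sound-speed sanity check of
the transmission measurement.  Writes results/calibration.csv and
results/dilution.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from ucachar.attenuation import sound_speed_difference
from ucachar.calibration import DilutionSpec, dilution_concentration, mi_to_pressure, number_density, pressure_to_mi

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)

    rows = []
    for f in (1.0, 2.25, 3.5):
        for mi in (0.2, 0.3):
            rows.append({
                "f_MHz": f, "mi": mi,
                "pnp_kPa": mi_to_pressure(mi, f),
                "pnp_kPa_unrounded": mi_to_pressure(mi, f, round_to=None),
            })
    # low-pressure attenuation settings
    for f, pnp in ((1.0, 13.0), (2.25, 55.0), (3.5, 50.0)):
        rows.append({"f_MHz": f, "mi": pressure_to_mi(pnp, f), "pnp_kPa": pnp,
                     "pnp_kPa_unrounded": pnp})
    calib = pd.DataFrame(rows)
    calib.to_csv(out_dir / "calibration.csv", index=False)
    print("MI / peak-negative-pressure table:")
    print(calib.to_string(index=False))

    # silica-shelled agents: 10 mg in 12 mL, 0.35 mL into 3.35 mL
    silica = DilutionSpec(stock_mass=10.0, stock_volume=12.0, aliquot=0.35, diluent=3.35)
    conc = dilution_concentration(silica)
    dil = pd.DataFrame([
        {
            "agent": "antibubble/reference", "concentration_mg_per_mL": round(conc, 2),
            "bubbles_per_mL": number_density(round(conc, 2), 1.25e6),
        },
        {
            "agent": "sonovue-like", "concentration_mg_per_mL": 1e-3,
            "bubbles_per_mL": number_density(1e-3, 8e7),
        },
    ])
    dil.to_csv(out_dir / "dilution.csv", index=False)
    print(f"\nDilution: {conc:.4f} mg/mL -> {round(conc, 2):.2f} at 2 d.p.")
    print(f"Sound-speed check: 0.6 us delay over 1 cm -> "
          f"{sound_speed_difference(0.6, 1.0, 1480.0):.1f}% vs water")
    print(f"wrote {out_dir / 'calibration.csv'} and dilution.csv")


if __name__ == "__main__":
    sys.exit(main())
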