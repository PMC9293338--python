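#!/usr/bin/env python
"""DCE-US bolus passage of the three agents through the vascular phantom.

Simulates 40 s three-pulse (PI+AM) clips per agent with nonlinear response
strengths set so the expected TIC peak ordering matches the measured one
(antibubble peak 31% above the reference agent, 23% below high-
concentration SonoVue), then recomputes the peak percent differences from
the extracted TICs, the normalized TIC family, the maximum-intensity
projection, and the triangular-model mixing volume.

Writes results/tic_summary.csv, results/tics_normalized.csv and
results/mip_antibubble.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ucachar.dceus import (
    combine_frames,
    extract_tic,
    max_intensity_projection,
    normalize_tics,
    peak_percent_difference,
    triangular_peak_concentration,
)
from ucachar.roi import Rect
from ucachar.synthetic import BolusConfig, SimulationConfig, simulate_dceus_clip

ROOT = Path(__file__).resolve().parents[1]

# relative nonlinear *intensity* at the TIC peak (reference agent = 1);
# response amplitude scales with the square root of these
PEAK_INTENSITY = {"antibubble": 1.31, "reference": 1.00, "sonovue30": 1.31 / 0.77}
ROI = Rect(8, 12, 40, 20)  # middle of the phantom


N_ACQUISITIONS = 4  # TICs are averaged over four bolus injections per agent


def agent_mean_tic(agent: str, base_seed: int):
    """Mean TIC over four simulated bolus acquisitions, plus the envelope
    stack of the first acquisition (for the MIP).

    The seeds are shared across agents: every agent flows through the same
    phantom, so the scatterer field per acquisition is the same realization
    and only the nonlinear response strength differs.
    """
    bolus = BolusConfig(dose=0.5)
    gain = np.sqrt(PEAK_INTENSITY[agent])
    intensities, first_env, times = [], None, None
    for rep in range(N_ACQUISITIONS):
        cfg = SimulationConfig(f0=3.5, n_cycles=3, noise_rms=0.01, seed=base_seed + rep)
        frames = simulate_dceus_clip(
            cfg, bolus, response=lambda c: gain * np.sqrt(np.asarray(c, dtype=float))
        )
        times, env = combine_frames(frames)
        if first_env is None:
            first_env = env
        intensities.append(extract_tic(env, ROI, times).intensity)
    from ucachar.dceus import TIC

    return bolus, TIC(t=times, intensity=np.mean(intensities, axis=0)), first_env


def main() -> None:
    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)

    tics, rows = {}, []
    for agent in PEAK_INTENSITY:
        bolus, tic, env = agent_mean_tic(agent, base_seed=500)
        tics[agent] = tic
        rows.append({
            "agent": agent, "peak_intensity": tic.peak_value,
            "peak_time_s": tic.peak_time, "n_acquisitions": N_ACQUISITIONS,
        })
        if agent == "antibubble":
            mip = max_intensity_projection(env)
            np.savetxt(out_dir / "mip_antibubble.csv", mip, delimiter=",")

    d_ref = peak_percent_difference(tics["antibubble"], tics["reference"])
    d_sv = peak_percent_difference(tics["antibubble"], tics["sonovue30"])
    print("TIC peak comparison (middle-of-phantom ROI, linearized):")
    print(f"  antibubble vs reference bubbles: {d_ref:+.1f}%")
    print(f"  antibubble vs SonoVue-like (30x concentration): {d_sv:+.1f}%")

    normalized = normalize_tics(list(tics.values()))
    norm_frame = pd.DataFrame({"t_s": normalized[0].t})
    for agent, tic in zip(tics, normalized):
        norm_frame[agent] = tic.intensity
    norm_frame.to_csv(out_dir / "tics_normalized.csv", index=False)

    model = triangular_peak_concentration(dose=0.5, flow=36.0, duration=25.0)
    print(
        f"  triangular model: C_peak = {model.peak_concentration:.4f} mg/mL, "
        f"mixing volume = {model.mixing_volume:.2f} mL"
    )
    summary = pd.DataFrame(rows)
    summary["pct_vs_reference"] = [
        peak_percent_difference(tics[a], tics["reference"]) for a in tics
    ]
    summary.to_csv(out_dir / "tic_summary.csv", index=False)
    print(f"wrote {out_dir / 'tic_summary.csv'}, tics_normalized.csv, mip_antibubble.csv")


if __name__ == "__main__":
    sys.exit(main())
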