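"""Containers and on-disk formats for raw acquisition records.

An :class:`AcquisitionRecord` holds one acquisition: the sampled waveform
(a train of tone-burst echoes separated by silence) plus the transmit and
medium metadata needed by the downstream estimators.  Records are stored
as raw little-endian float32 samples next to a JSON sidecar carrying the
metadata, or as a two-column CSV for small fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionRecord",
    "write_record",
    "read_record",
    "write_record_csv",
    "read_record_csv",
]


@dataclass
class AcquisitionRecord:
    """One acquisition: waveform plus transmit/medium metadata.

    Parameters
    ----------
    samples
        Waveform amplitude versus time, arbitrary linear units.
    fs
        Sampling rate in MHz.
    f0
        Transmit (fundamental) frequency in MHz.
    pulse_starts
        Sample index at which each transmitted pulse (and hence each echo
        window) begins; strictly increasing.
    medium
        Label of the scattering/propagation medium, e.g. ``"saline"`` or
        an agent name.
    pressure_kPa
        Nominal peak-negative transmit pressure.
    replicate_id
        Index of the replicate acquisition (agents are re-injected per
        replicate).
    n_cycles
        Cycles per transmitted tone burst, when known.
    travel_time_us
        Acoustic travel delay (microseconds) from the pulse start to the
        onset of the analyzed echo; used as the default analysis-window
        offset.
    """

    samples: np.ndarray
    fs: float
    f0: float
    pulse_starts: np.ndarray
    medium: str = "saline"
    pressure_kPa: float | None = None
    replicate_id: int = 0
    n_cycles: int | None = None
    travel_time_us: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.pulse_starts = np.asarray(self.pulse_starts, dtype=int)
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.f0 <= 0:
            raise ValueError("transmit frequency f0 must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.pulse_starts.ndim != 1 or self.pulse_starts.size == 0:
            raise ValueError("pulse_starts must be a non-empty 1-d array")
        if np.any(np.diff(self.pulse_starts) <= 0):
            raise ValueError("pulse_starts must be strictly increasing")
        if self.pulse_starts[0] < 0 or self.pulse_starts[-1] >= self.samples.size:
            raise ValueError("pulse_starts must index into samples")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_starts.size)

    @property
    def duration_us(self) -> float:
        """Record duration in microseconds."""
        return self.samples.size / self.fs

    def metadata(self) -> dict:
        return {
            "fs": self.fs,
            "f0": self.f0,
            "pulse_starts": self.pulse_starts.tolist(),
            "medium": self.medium,
            "pressure_kPa": self.pressure_kPa,
            "replicate_id": self.replicate_id,
            "n_cycles": self.n_cycles,
            "travel_time_us": self.travel_time_us,
        }


def write_record(rec: AcquisitionRecord, stem: str | Path) -> tuple[Path, Path]:
    """Write a record as ``<stem>.bin`` (little-endian float32) + ``<stem>.json``."""
    stem = Path(stem)
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    rec.samples.astype("<f4").tofile(bin_path)
    json_path.write_text(json.dumps(rec.metadata(), indent=2))
    return bin_path, json_path


def read_record(stem: str | Path) -> AcquisitionRecord:
    """Read a record written by :func:`write_record`."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    samples = np.fromfile(stem.with_suffix(".bin"), dtype="<f4").astype(float)
    return AcquisitionRecord(
        samples=samples,
        fs=meta["fs"],
        f0=meta["f0"],
        pulse_starts=np.asarray(meta["pulse_starts"], dtype=int),
        medium=meta.get("medium", "saline"),
        pressure_kPa=meta.get("pressure_kPa"),
        replicate_id=meta.get("replicate_id", 0),
        n_cycles=meta.get("n_cycles"),
        travel_time_us=meta.get("travel_time_us", 0.0),
    )


def write_record_csv(rec: AcquisitionRecord, path: str | Path) -> Path:
    """Two-column CSV export (time_us, amplitude); metadata in ``<path>.json``."""
    path = Path(path)
    t_us = np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_us": t_us, "amplitude": rec.samples}).to_csv(path, index=False)
    Path(str(path) + ".json").write_text(json.dumps(rec.metadata(), indent=2))
    return path


def read_record_csv(path: str | Path) -> AcquisitionRecord:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    frame = pd.read_csv(path)
    return AcquisitionRecord(
        samples=frame["amplitude"].to_numpy(dtype=float),
        fs=meta["fs"],
        f0=meta["f0"],
        pulse_starts=np.asarray(meta["pulse_starts"], dtype=int),
        medium=meta.get("medium", "saline"),
        pressure_kPa=meta.get("pressure_kPa"),
        replicate_id=meta.get("replicate_id", 0),
        n_cycles=meta.get("n_cycles"),
        travel_time_us=meta.get("travel_time_us", 0.0),
    )
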