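"""Per-minute vital-sign records and their on-disk representation.

A :class:`VitalsRecord` holds one patient's mean arterial pressure (MAP,
mmHg), heart rate (HR, bpm) and peripheral oxygen saturation (SpO2, %) as
per-minute series. Missing samples are NaN. Records shorter than two hours
of MAP are considered uninformative for episode annotation and are rejected
at construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("map", "hr", "spo2")

#: Minimum record length in minutes (two hours of MAP recordings).
MIN_RECORD_MINUTES = 120


@dataclass
class VitalsRecord:
    """One patient's per-minute multivariate vital-sign series.

    Parameters
    ----------
    patient_id
        Stable identifier used for patient-level data splitting.
    map_series, hr_series, spo2_series
        Float arrays of equal length; NaN marks a missing sample.
    sampling_period
        Minutes between consecutive samples (fixed at 1).
    """

    patient_id: str
    map_series: np.ndarray
    hr_series: np.ndarray
    spo2_series: np.ndarray
    sampling_period: float = 1.0

    def __post_init__(self) -> None:
        self.map_series = np.asarray(self.map_series, dtype=float)
        self.hr_series = np.asarray(self.hr_series, dtype=float)
        self.spo2_series = np.asarray(self.spo2_series, dtype=float)
        n = len(self.map_series)
        if len(self.hr_series) != n or len(self.spo2_series) != n:
            raise ValueError("all three series must have identical length")
        if n < MIN_RECORD_MINUTES:
            raise ValueError(
                f"record must span >= {MIN_RECORD_MINUTES} minutes, got {n}"
            )
        for series in (self.map_series, self.hr_series, self.spo2_series):
            observed = series[~np.isnan(series)]
            if observed.size and not np.all(np.isfinite(observed)):
                raise ValueError("non-missing values must be finite")

    @property
    def length(self) -> int:
        """Record length in minutes."""
        return len(self.map_series)

    def features(self) -> np.ndarray:
        """Stack the three channels as a [length, 3] matrix (MAP, HR, SpO2)."""
        return np.column_stack(
            [self.map_series, self.hr_series, self.spo2_series]
        )

    def copy(self) -> "VitalsRecord":
        return VitalsRecord(
            patient_id=self.patient_id,
            map_series=self.map_series.copy(),
            hr_series=self.hr_series.copy(),
            spo2_series=self.spo2_series.copy(),
            sampling_period=self.sampling_period,
        )


@dataclass
class PlantedEvent:
    """Ground-truth log entry for one synthetically planted episode."""

    patient_id: str
    onset: int
    duration: int
    depth_fraction: float


@dataclass
class Cohort:
    """A list of records plus the ground-truth log of planted events."""

    records: list[VitalsRecord]
    planted_events: list[PlantedEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def events_for(self, patient_id: str) -> list[PlantedEvent]:
        return [e for e in self.planted_events if e.patient_id == patient_id]


def write_record_csv(record: VitalsRecord, path: str | Path) -> None:
    """Write one record as CSV with columns minute,map,hr,spo2 (empty = missing)."""
    df = pd.DataFrame(
        {
            "minute": np.arange(record.length),
            "map": record.map_series,
            "hr": record.hr_series,
            "spo2": record.spo2_series,
        }
    )
    df.to_csv(path, index=False, na_rep="")


def read_record_csv(path: str | Path, patient_id: str | None = None) -> VitalsRecord:
    """Read a record written by :func:`write_record_csv`."""
    df = pd.read_csv(path)
    pid = patient_id if patient_id is not None else Path(path).stem
    return VitalsRecord(
        patient_id=pid,
        map_series=df["map"].to_numpy(dtype=float),
        hr_series=df["hr"].to_numpy(dtype=float),
        spo2_series=df["spo2"].to_numpy(dtype=float),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one CSV per patient plus a JSON manifest with the planted-event log.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for record in cohort.records:
        fname = f"{record.patient_id}.csv"
        write_record_csv(record, out / fname)
        entries.append({"patient_id": record.patient_id, "file": fname})
    manifest = {
        "patients": entries,
        "planted_events": [
            {
                "patient_id": e.patient_id,
                "onset": e.onset,
                "duration": e.duration,
                "depth_fraction": e.depth_fraction,
            }
            for e in cohort.planted_events
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    base = Path(in_dir)
    manifest = json.loads((base / "manifest.json").read_text())
    records = [
        read_record_csv(base / entry["file"], patient_id=entry["patient_id"])
        for entry in manifest["patients"]
    ]
    events = [
        PlantedEvent(
            patient_id=e["patient_id"],
            onset=int(e["onset"]),
            duration=int(e["duration"]),
            depth_fraction=float(e["depth_fraction"]),
        )
        for e in manifest.get("planted_events", [])
    ]
    return Cohort(records=records, planted_events=events)
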