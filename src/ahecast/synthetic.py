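"""Synthetic per-minute vital-sign cohorts with plantable hypotensive episodes.

The generator emulates the statistical structure the downstream analysis
assumes: per-minute MAP/HR/SpO2 records at least two hours long,
inter-patient baseline variability, white measurement noise plus a slow
sinusoidal drift, missing-completely-at-random samples, isolated
out-of-physiological-range artifact spikes, a low (~3%) prevalence of
episodes, and a controllable pre-event precursor (a linear HR ramp and a
gentle MAP down-trend) that makes forecasting skill learnable with a
lead-time-decaying signal.

Planted episodes follow the relative definition the annotator detects: the
MAP is depressed by a configurable fraction of its immediately pre-onset
level, entering and leaving a plateau through a smooth 2-3 minute sigmoid
transition rather than an instantaneous step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .records import Cohort, PlantedEvent, VitalsRecord

logger = logging.getLogger(__name__)

#: Artifact spike values per channel, all outside physiological ranges.
#: MAP/HR artifacts are high-side spikes (e.g. a flushed or kinked line);
#: the SpO2 artifact is a low-side probe drop-off.
ARTIFACT_VALUES = {"map": 250.0, "hr": 300.0, "spo2": 10.0}

#: Logistic time-scale (minutes) of the episode on/offset transition.
_TRANSITION_SCALE = 0.6


@dataclass
class PrecursorAmplitude:
    """Effect sizes of the pre-event precursor.

    ``hr_ramp_bpm`` is the HR increase reached at episode onset;
    ``map_drift_mmhg`` is the MAP decrease reached at onset. Both ramp
    linearly from zero starting ``precursor_lead`` minutes before onset and
    relax back to zero over the episode itself.
    """

    hr_ramp_bpm: float = 20.0
    map_drift_mmhg: float = 8.0


@dataclass
class GeneratorConfig:
    """Cohort-level generation parameters (defaults are the study conditions)."""

    n_patients: int = 100
    record_length_range: tuple[int, int] = (360, 720)
    baseline_map_mean_range: tuple[float, float] = (75.0, 105.0)
    baseline_hr_mean_range: tuple[float, float] = (60.0, 100.0)
    baseline_spo2_mean_range: tuple[float, float] = (94.0, 99.0)
    noise_sd: tuple[float, float, float] = (2.0, 3.0, 0.8)  # MAP, HR, SpO2
    drift_amplitude_mmhg: float = 2.0
    ahe_prevalence: float = 0.03
    event_depth_fraction: float = 0.25
    event_deepening_slope: float = 0.4  # mmHg/min across the plateau
    event_duration_range: tuple[int, int] = (20, 40)
    precursor_lead: int = 90
    precursor_amplitude: PrecursorAmplitude = field(
        default_factory=PrecursorAmplitude
    )
    missing_rate: float = 0.02
    artifact_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "record_length_range",
            "baseline_map_mean_range",
            "baseline_hr_mean_range",
            "baseline_spo2_mean_range",
            "event_duration_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        for name in ("ahe_prevalence", "missing_rate", "artifact_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        if any(sd < 0 for sd in self.noise_sd):
            raise ValueError("noise_sd entries must be non-negative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.record_length_range[0] < 120:
            raise ValueError("records must be at least 120 minutes long")
        if self.ahe_prevalence > 0 and self.event_depth_fraction <= 0.20:
            logger.warning(
                "event_depth_fraction %.2f <= 0.20: planted events may fall "
                "below the 20%% annotation threshold",
                self.event_depth_fraction,
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def inject_ahe(
    record: VitalsRecord,
    onset: int,
    depth_fraction: float,
    duration: int,
    precursor_lead: int = 0,
    precursor_amplitude: PrecursorAmplitude | None = None,
    deepening_slope: float = 0.4,
    enforce_floor: bool = True,
    floor: float = 20.0,
) -> VitalsRecord:
    """Superimpose one episode (and its precursor) on a copy of ``record``.

    The MAP is depressed by ``depth_fraction`` of its pre-onset level over
    ``[onset, onset + duration)``, entering through a sigmoid transition
    that completes just after the onset and recovering through one at the
    offset. Across the plateau the depression deepens by ``deepening_slope``
    mmHg per minute, mimicking untreated hypotension drifting further down;
    this also keeps the moving-average gap of a 25%-deep episode open well
    past the 10-minute validity horizon instead of letting the 60-min
    average catch up and close it at the margin. The precursor ramps
    linearly over ``[onset - precursor_lead, onset)`` and relaxes back to
    zero across the episode. Unless ``enforce_floor`` is disabled, the
    depressed MAP is kept above the validity floor (20 mmHg).
    """
    if onset < 60:
        raise IndexError("onset must be >= 60 (the annotator needs MA history)")
    if onset + duration > record.length:
        raise IndexError("onset + duration exceeds record length")
    amp = precursor_amplitude or PrecursorAmplitude(0.0, 0.0)
    out = record.copy()
    t = np.arange(out.length, dtype=float)

    # precursor: 0 -> full amplitude over the lead, back to 0 over the episode
    ramp = np.zeros(out.length)
    if precursor_lead > 0:
        lead_lo = max(0, onset - precursor_lead)
        ramp[lead_lo:onset] = (t[lead_lo:onset] - (onset - precursor_lead)) / (
            precursor_lead
        )
        end = min(out.length, onset + duration)
        if end > onset and duration > 0:
            ramp[onset:end] = 1.0 - (t[onset:end] - onset) / duration
        ramp = np.clip(ramp, 0.0, 1.0)
        out.hr_series = out.hr_series + amp.hr_ramp_bpm * ramp
        out.map_series = out.map_series - amp.map_drift_mmhg * ramp

    # reference level: mean observed MAP just before onset (after precursor)
    pre = out.map_series[max(0, onset - 10) : onset]
    ref = float(np.nanmean(pre)) if np.any(~np.isnan(pre)) else float(
        np.nanmean(out.map_series)
    )

    if depth_fraction != 0.0:
        profile = _sigmoid((t - (onset - 1)) / _TRANSITION_SCALE) - _sigmoid(
            (t - (onset + duration)) / _TRANSITION_SCALE
        )
        deepening = deepening_slope * np.clip(t - onset, 0.0, duration)
        depressed = out.map_series - (depth_fraction * ref + deepening) * profile
        if enforce_floor:
            observed = ~np.isnan(depressed)
            depressed[observed] = np.maximum(depressed[observed], floor + 1.0)
        out.map_series = depressed
    return out


def inject_missingness(
    record: VitalsRecord, missing_rate: float, seed: int
) -> VitalsRecord:
    """Replace each sample independently with NaN with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    out = record.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for series in (out.map_series, out.hr_series, out.spo2_series):
        drop = rng.random(len(series)) < missing_rate
        series[drop] = np.nan
    return out


def _base_signal(
    rng: np.random.Generator,
    length: int,
    mean: float,
    noise_sd: float,
    drift_amplitude: float,
) -> np.ndarray:
    t = np.arange(length, dtype=float)
    period = rng.uniform(180.0, 360.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = drift_amplitude * np.sin(2.0 * np.pi * t / period + phase)
    return mean + drift + rng.normal(0.0, noise_sd, size=length)


def _generate_record(
    rng: np.random.Generator, config: GeneratorConfig, patient_id: str
) -> tuple[VitalsRecord, PlantedEvent | None]:
    length = int(rng.integers(*config.record_length_range, endpoint=True))
    base_map = rng.uniform(*config.baseline_map_mean_range)
    base_hr = rng.uniform(*config.baseline_hr_mean_range)
    base_spo2 = rng.uniform(*config.baseline_spo2_mean_range)
    sd_map, sd_hr, sd_spo2 = config.noise_sd

    map_s = _base_signal(rng, length, base_map, sd_map, config.drift_amplitude_mmhg)
    hr_s = _base_signal(rng, length, base_hr, sd_hr, config.drift_amplitude_mmhg)
    spo2_s = np.minimum(
        _base_signal(rng, length, base_spo2, sd_spo2, 0.0), 100.0
    )
    record = VitalsRecord(
        patient_id=patient_id,
        map_series=map_s,
        hr_series=hr_s,
        spo2_series=spo2_s,
    )

    planted: PlantedEvent | None = None
    if rng.random() < config.ahe_prevalence:
        duration = int(rng.integers(*config.event_duration_range, endpoint=True))
        onset_lo = max(150, config.precursor_lead + 61)
        onset_hi = length - duration - 10
        if onset_hi > onset_lo:
            onset = int(rng.integers(onset_lo, onset_hi, endpoint=True))
            record = inject_ahe(
                record,
                onset=onset,
                depth_fraction=config.event_depth_fraction,
                duration=duration,
                precursor_lead=config.precursor_lead,
                precursor_amplitude=config.precursor_amplitude,
                deepening_slope=config.event_deepening_slope,
            )
            planted = PlantedEvent(
                patient_id=patient_id,
                onset=onset,
                duration=duration,
                depth_fraction=config.event_depth_fraction,
            )
        else:
            logger.warning(
                "record %s too short (%d min) to place an event; skipping",
                patient_id,
                length,
            )

    # artifacts: isolated non-physiological spikes, per channel
    if config.artifact_rate > 0:
        for name, series in (
            ("map", record.map_series),
            ("hr", record.hr_series),
            ("spo2", record.spo2_series),
        ):
            spikes = rng.random(length) < config.artifact_rate
            series[spikes] = ARTIFACT_VALUES[name]

    # missingness last: a sample can be missing instead of artifactual
    if config.missing_rate > 0:
        for series in (record.map_series, record.hr_series, record.spo2_series):
            drop = rng.random(length) < config.missing_rate
            series[drop] = np.nan
    return record, planted


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate ``config.n_patients`` records plus the planted-event log.

    The cohort is a pure function of the config (including its seed): each
    patient consumes an independent child stream of the seeded generator, so
    identical configs yield bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_patients)
    records: list[VitalsRecord] = []
    planted: list[PlantedEvent] = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        record, event = _generate_record(rng, config, patient_id=f"p{i:04d}")
        records.append(record)
        if event is not None:
            planted.append(event)
    return Cohort(records=records, planted_events=planted)


def null_config(n_patients: int = 100, seed: int = 0) -> GeneratorConfig:
    """An event-free cohort with bounded noise (annotator false-positive check)."""
    return GeneratorConfig(
        n_patients=n_patients,
        ahe_prevalence=0.0,
        missing_rate=0.0,
        artifact_rate=0.0,
        seed=seed,
    )


def recovery_config(n_patients: int = 100, seed: int = 0) -> GeneratorConfig:
    """Low-noise cohort of detectable planted events (round-trip check).

    Every record carries one 25%-deep episode of 20-40 min, with noise
    small enough that detection timing is dominated by the event shape.
    """
    return GeneratorConfig(
        n_patients=n_patients,
        ahe_prevalence=1.0,
        noise_sd=(1.0, 2.0, 0.5),
        missing_rate=0.0,
        artifact_rate=0.0,
        seed=seed,
    )


def learnable_config(n_patients: int = 300, seed: int = 0) -> GeneratorConfig:
    """Cohort with a strong precursor so forecasting skill is learnable.

    Half the records carry an episode; the precursor starts 90 min before
    onset (beyond the largest studied gap of 60 min) with a +20 bpm HR ramp
    and a -8 mmHg MAP drift, so the predictive signal weakens but does not
    vanish as the forecasting gap grows.
    """
    return GeneratorConfig(
        n_patients=n_patients,
        record_length_range=(360, 540),
        ahe_prevalence=0.5,
        precursor_lead=90,
        precursor_amplitude=PrecursorAmplitude(
            hr_ramp_bpm=20.0, map_drift_mmhg=8.0
        ),
        seed=seed,
    )


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
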