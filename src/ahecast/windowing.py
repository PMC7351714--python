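"""Extraction of labeled observation windows for episode forecasting.

A *positive* sample is an observation window whose episode onsets exactly
``gap_length`` minutes after the window ends; when a prior episode exists,
a two-hour buffer is required between its end and the window start, to keep
successive positives approximately independent. A *negative* sample is a
window with no annotated episode within two hours on either side; negatives
are packed greedily left to right without overlap and do not depend on the
gap length. Windows with more than 10% erroneous samples (missing or
outside physiological range, counted jointly over all channels) are
discarded by the quality filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import AHEEvent
from .preprocessing import (
    DecayInputs,
    NormalizationRanges,
    PhysiologicalRanges,
    FullyMissingChannelError,
    impute,
    normalize,
    prepare_decay_inputs,
    remove_nonphysiological,
)
from .records import Cohort, VitalsRecord

logger = logging.getLogger(__name__)

#: The studied grids of observation-window and gap lengths (minutes).
OBS_LENGTHS = (10, 20, 30, 40, 50, 60)
GAP_LENGTHS = (10, 20, 30, 40, 50, 60)

#: Required event-free margin (minutes) on each side of a negative window,
#: and the required buffer after a prior episode before the next positive.
INDEPENDENCE_MARGIN = 120


@dataclass
class SampleWindow:
    """One labeled observation window.

    ``features_raw`` is the pre-imputation [obs_length x 3] slice (NaN where
    missing or non-physiological); ``features_filled`` the imputed,
    [0, 1]-normalized matrix used by dense-input models; ``mask`` marks
    samples that were observed and in physiological range; ``decay`` carries
    the triple-input representation for the missing-data-tolerant model.
    """

    patient_id: str
    start_index: int
    obs_length: int
    gap_length: int
    label: int
    features_raw: np.ndarray
    features_filled: np.ndarray | None = None
    mask: np.ndarray | None = None
    decay: DecayInputs | None = None


def _event_end(event: AHEEvent, record_length: int) -> int:
    return event.end_index if event.end_index is not None else record_length


def validate_grid_value(value: int, grid: tuple[int, ...], name: str) -> None:
    if value not in grid:
        raise ValueError(f"{name}={value} not in studied grid {grid}")


def extract_positive_windows(
    record: VitalsRecord,
    events: list[AHEEvent],
    obs_length: int,
    gap_length: int,
    grid_check: bool = True,
) -> list[SampleWindow]:
    """One window per episode, ending exactly ``gap_length`` min before onset.

    A window for the episode with onset ``o`` occupies
    ``[o - gap_length - obs_length, o - gap_length)`` and is emitted only if
    it lies fully inside the record and, when a prior episode exists, starts
    at least two hours after that episode's end.
    """
    if grid_check:
        validate_grid_value(obs_length, OBS_LENGTHS, "obs_length")
        validate_grid_value(gap_length, GAP_LENGTHS, "gap_length")
    windows: list[SampleWindow] = []
    ordered = sorted(events, key=lambda e: e.onset_index)
    for i, event in enumerate(ordered):
        start = event.onset_index - gap_length - obs_length
        stop = event.onset_index - gap_length
        if start < 0:
            continue
        if i > 0:
            prior_end = _event_end(ordered[i - 1], record.length)
            if start < prior_end + INDEPENDENCE_MARGIN:
                continue
        windows.append(
            SampleWindow(
                patient_id=record.patient_id,
                start_index=start,
                obs_length=obs_length,
                gap_length=gap_length,
                label=1,
                features_raw=record.features()[start:stop].copy(),
            )
        )
    return windows


def extract_negative_windows(
    record: VitalsRecord,
    events: list[AHEEvent],
    obs_length: int,
    grid_check: bool = True,
) -> list[SampleWindow]:
    """Greedy non-overlapping event-free windows.

    A start ``s`` is feasible when no annotated episode intersects
    ``[s - 120, s + obs_length + 120)``; the margin constrains events only,
    so windows near the record edge qualify if the in-record part of the
    margin is event-free. Scanning left to right, each accepted window
    advances the cursor by ``obs_length``; an infeasible start advances it
    to the next feasible position.
    """
    if grid_check:
        validate_grid_value(obs_length, OBS_LENGTHS, "obs_length")
    n = record.length
    intervals = [
        (e.onset_index, _event_end(e, n))
        for e in sorted(events, key=lambda e: e.onset_index)
    ]

    def first_blocking(s: int) -> tuple[int, int] | None:
        lo, hi = s - INDEPENDENCE_MARGIN, s + obs_length + INDEPENDENCE_MARGIN
        for onset, end in intervals:
            if onset < hi and end > lo:
                return onset, end
        return None

    windows: list[SampleWindow] = []
    s = 0
    while s + obs_length <= n:
        blocker = first_blocking(s)
        if blocker is None:
            windows.append(
                SampleWindow(
                    patient_id=record.patient_id,
                    start_index=s,
                    obs_length=obs_length,
                    gap_length=0,
                    label=0,
                    features_raw=record.features()[s : s + obs_length].copy(),
                )
            )
            s += obs_length
        else:
            # earliest start clearing this episode's guard region
            _, end = blocker
            s = max(s + 1, end + INDEPENDENCE_MARGIN)
    return windows


def quality_filter(
    window: SampleWindow,
    max_erroneous_fraction: float = 0.10,
    ranges: PhysiologicalRanges | None = None,
) -> bool:
    """Keep a window unless strictly more than 10% of its samples are erroneous.

    Erroneous samples are those missing or outside physiological range,
    counted jointly across all channels of the pre-imputation matrix.
    """
    ranges = ranges or PhysiologicalRanges()
    raw = window.features_raw
    missing = np.isnan(raw)
    lows, highs = ranges.bounds()
    out_of_range = ~missing & ((raw < lows) | (raw > highs))
    fraction = float((missing | out_of_range).mean())
    return fraction <= max_erroneous_fraction


@dataclass
class WindowDataset:
    """Processed windows stacked into model-ready arrays."""

    obs_length: int
    gap_length: int
    X: np.ndarray  # [n, obs, 3] imputed + normalized
    X_raw: np.ndarray  # [n, obs, 3] normalized, zero-filled where unobserved
    mask: np.ndarray  # [n, obs, 3]
    delta: np.ndarray  # [n, obs, 3] minutes since last observation
    x_last: np.ndarray  # [n, obs, 3] last observed value (NaN if none yet)
    y: np.ndarray  # [n]
    patient_ids: np.ndarray  # [n] strings
    start_indices: np.ndarray  # [n]
    n_rejected_quality: int = 0
    n_rejected_impute: int = 0
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.y) - self.y.sum())

    def subset(self, idx: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            obs_length=self.obs_length,
            gap_length=self.gap_length,
            X=self.X[idx],
            X_raw=self.X_raw[idx],
            mask=self.mask[idx],
            delta=self.delta[idx],
            x_last=self.x_last[idx],
            y=self.y[idx],
            patient_ids=self.patient_ids[idx],
            start_indices=self.start_indices[idx],
        )


def build_dataset(
    cohort: Cohort,
    events_per_record: dict[str, list[AHEEvent]],
    obs_length: int,
    gap_length: int,
    phys_ranges: PhysiologicalRanges | None = None,
    norm_ranges: NormalizationRanges | None = None,
    grid_check: bool = True,
) -> WindowDataset:
    """Extract, filter and preprocess all windows of a cohort.

    Positives and negatives are concatenated across records; the quality
    filter runs on the raw slices; surviving windows are range-filtered,
    imputed (backfill then forward-fill, inside the window only) and
    normalized to [0, 1] with the static per-channel ranges. The unfilled
    variant (values, mask, time-delta) is prepared for the decay model.
    """
    phys_ranges = phys_ranges or PhysiologicalRanges()
    norm_ranges = norm_ranges or NormalizationRanges()
    if len(cohort.records) == 0:
        logger.warning("empty cohort: returning empty dataset")

    kept: list[SampleWindow] = []
    n_quality = 0
    n_impute = 0
    for record in cohort.records:
        events = events_per_record.get(record.patient_id, [])
        windows = extract_positive_windows(
            record, events, obs_length, gap_length, grid_check=grid_check
        ) + extract_negative_windows(
            record, events, obs_length, grid_check=grid_check
        )
        for window in windows:
            if not quality_filter(window, ranges=phys_ranges):
                n_quality += 1
                continue
            cleaned, _ = remove_nonphysiological(window.features_raw, phys_ranges)
            try:
                filled = impute(cleaned)
            except FullyMissingChannelError:
                n_impute += 1
                logger.warning(
                    "window %s@%d rejected: fully-missing channel",
                    window.patient_id,
                    window.start_index,
                )
                continue
            window.features_filled = normalize(filled, norm_ranges)
            window.mask = (~np.isnan(cleaned)).astype(float)
            window.decay = prepare_decay_inputs(normalize(cleaned, norm_ranges))
            kept.append(window)

    n = len(kept)
    obs = obs_length
    if n == 0:
        empty = np.zeros((0, obs, 3))
        return WindowDataset(
            obs_length=obs_length,
            gap_length=gap_length,
            X=empty,
            X_raw=empty.copy(),
            mask=empty.copy(),
            delta=empty.copy(),
            x_last=empty.copy(),
            y=np.zeros(0, dtype=int),
            patient_ids=np.array([], dtype=object),
            start_indices=np.zeros(0, dtype=int),
            n_rejected_quality=n_quality,
            n_rejected_impute=n_impute,
        )
    return WindowDataset(
        obs_length=obs_length,
        gap_length=gap_length,
        X=np.stack([w.features_filled for w in kept]),
        X_raw=np.stack([w.decay.values_raw for w in kept]),
        mask=np.stack([w.decay.mask for w in kept]),
        delta=np.stack([w.decay.time_delta for w in kept]),
        x_last=np.stack([w.decay.last_observed for w in kept]),
        y=np.array([w.label for w in kept], dtype=int),
        patient_ids=np.array([w.patient_id for w in kept], dtype=object),
        start_indices=np.array([w.start_index for w in kept], dtype=int),
        n_rejected_quality=n_quality,
        n_rejected_impute=n_impute,
    )
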