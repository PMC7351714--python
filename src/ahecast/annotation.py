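"""Acute hypotensive episode (AHE) annotation.

Two definitions are implemented:

* A **patient-specific, relative** definition: an episode begins when the
  trailing 5-minute moving average of MAP falls 20% or more below the
  trailing 60-minute moving average, and is valid only if every MAP sample
  in the 10 minutes after detection is non-missing and above 20 mmHg. The
  episode ends when the two moving averages are again within 20% of each
  other. Because of the validity horizon, the minimum duration of a valid
  episode is 10 minutes.
* The **conventional threshold** definition used for comparison: an interval
  of at least 30 minutes in which at least 90% of non-missing MAP readings
  are below 60 mmHg.

The relative definition adapts to each patient's own baseline: multiplying a
MAP series by a positive constant leaves the set of candidate onsets
unchanged, which is not true of the fixed-threshold definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .records import VitalsRecord

logger = logging.getLogger(__name__)


class AHEDefinition(str, Enum):
    PATIENT_SPECIFIC = "patient_specific"
    CONVENTIONAL = "conventional_physionet"


@dataclass
class AHEEvent:
    """One annotated episode, as a half-open interval [onset_index, end_index).

    ``end_index`` is None for an episode still open at the end of the record.
    ``drop_fraction_at_onset`` is 1 - short_MA/long_MA at the onset index
    (only meaningful for the patient-specific definition).
    """

    onset_index: int
    end_index: int | None
    drop_fraction_at_onset: float
    definition: AHEDefinition = AHEDefinition.PATIENT_SPECIFIC

    def __post_init__(self) -> None:
        if self.end_index is not None and self.end_index <= self.onset_index:
            raise ValueError("end_index must exceed onset_index when closed")

    @property
    def closed(self) -> bool:
        return self.end_index is not None

    def duration(self, record_length: int | None = None) -> int | None:
        if self.end_index is not None:
            return self.end_index - self.onset_index
        if record_length is not None:
            return record_length - self.onset_index
        return None


@dataclass
class AnnotationConfig:
    """Parameters of the patient-specific episode definition.

    Defaults encode the definition itself: a 20% drop of the 5-min trailing
    mean below the 60-min trailing mean, confirmed by 10 minutes of
    non-missing MAP above 20 mmHg.
    """

    long_ma_width: int = 60
    short_ma_width: int = 5
    drop_threshold: float = 0.20
    validity_horizon: int = 10
    validity_floor: float = 20.0

    def __post_init__(self) -> None:
        if not self.long_ma_width > self.short_ma_width > 0:
            raise ValueError("require long_ma_width > short_ma_width > 0")
        if not 0.0 < self.drop_threshold < 1.0:
            raise ValueError("drop_threshold must be in (0, 1)")
        if self.validity_horizon < 1:
            raise ValueError("validity_horizon must be >= 1 minute")


def moving_average(series: np.ndarray, width: int) -> np.ndarray:
    """Trailing (right-aligned) moving average tolerant of missing samples.

    The value at index ``t`` is the mean of the available (non-NaN) samples
    among ``series[t-width+1 .. t]``. Indices with fewer than ``width`` prior
    samples, or whose whole trailing window is missing, are NaN.
    """
    if width <= 0:
        raise ValueError("moving-average width must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    out = s.rolling(window=width, min_periods=1).mean().to_numpy()
    out[: width - 1] = np.nan
    return out


def minimum_event_duration(config: AnnotationConfig) -> int:
    """Definitional lower bound (minutes) on a valid episode's duration.

    Episodes whose moving-average gap re-closes before the validity horizon
    elapses are discarded outright, so no emitted closed event is shorter.
    """
    return config.validity_horizon


def annotate_record(
    record: VitalsRecord, config: AnnotationConfig | None = None
) -> list[AHEEvent]:
    """Scan one record sequentially for patient-specific episodes.

    A candidate onset is the first index t outside any open episode where
    both trailing averages are defined and
    ``short_MA(t) <= (1 - drop_threshold) * long_MA(t)`` (ties count as a
    drop: "20% or greater"). The candidate is confirmed only if every MAP
    sample in ``(t, t + validity_horizon]`` is non-missing and above the
    validity floor; a record ending inside the horizon cannot confirm. The
    episode closes at the first later index where both averages are defined
    and the gap is again below the threshold; closed episodes shorter than
    the validity horizon are discarded. Episodes never overlap.
    """
    config = config or AnnotationConfig()
    map_s = record.map_series
    n = record.length
    if n < config.long_ma_width + config.validity_horizon:
        logger.warning(
            "record %s too short to annotate (%d < %d); returning no events",
            record.patient_id,
            n,
            config.long_ma_width + config.validity_horizon,
        )
        return []

    short_ma = moving_average(map_s, config.short_ma_width)
    long_ma = moving_average(map_s, config.long_ma_width)
    ratio_ok = ~np.isnan(short_ma) & ~np.isnan(long_ma)
    dropped = ratio_ok & (short_ma <= (1.0 - config.drop_threshold) * long_ma)
    recovered = ratio_ok & (short_ma > (1.0 - config.drop_threshold) * long_ma)

    events: list[AHEEvent] = []
    t = config.long_ma_width - 1  # earliest index with a defined long MA
    while t < n:
        if not dropped[t]:
            t += 1
            continue
        # validity: horizon must fit in the record, be non-missing, above floor
        horizon = map_s[t + 1 : t + 1 + config.validity_horizon]
        valid = (
            len(horizon) == config.validity_horizon
            and not np.any(np.isnan(horizon))
            and np.all(horizon > config.validity_floor)
        )
        if not valid:
            t += 1
            continue
        # find the end: first index after t where the MA gap re-closes
        end: int | None = None
        for u in range(t + 1, n):
            if recovered[u]:
                end = u
                break
        if end is not None and end - t < config.validity_horizon:
            # gap closed before the horizon elapsed: not a real episode
            t = end
            continue
        drop_fraction = 1.0 - short_ma[t] / long_ma[t]
        events.append(
            AHEEvent(
                onset_index=t,
                end_index=end,
                drop_fraction_at_onset=float(drop_fraction),
                definition=AHEDefinition.PATIENT_SPECIFIC,
            )
        )
        if end is None:
            break
        t = end
    return events


def annotate_conventional(
    record: VitalsRecord,
    window: int = 30,
    fraction: float = 0.9,
    threshold: float = 60.0,
) -> list[AHEEvent]:
    """Flag episodes under the fixed-threshold definition.

    Maximal intervals of length >= ``window`` minutes in which at least
    ``fraction`` of the non-missing MAP readings are below ``threshold``
    mmHg. Qualifying windows are merged into maximal intervals.
    """
    map_s = record.map_series
    n = record.length
    if n < window:
        return []
    observed = (~np.isnan(map_s)).astype(int)
    below = (np.nan_to_num(map_s, nan=np.inf) < threshold).astype(int)
    cum_obs = np.concatenate([[0], np.cumsum(observed)])
    cum_below = np.concatenate([[0], np.cumsum(below)])

    qualifying = []
    for s in range(n - window + 1):
        n_obs = cum_obs[s + window] - cum_obs[s]
        n_below = cum_below[s + window] - cum_below[s]
        if n_obs > 0 and n_below >= fraction * n_obs:
            qualifying.append(s)

    events: list[AHEEvent] = []
    for s in qualifying:
        lo, hi = s, s + window
        if events and lo <= events[-1].end_index:
            events[-1].end_index = max(events[-1].end_index, hi)
        else:
            events.append(
                AHEEvent(
                    onset_index=lo,
                    end_index=hi,
                    drop_fraction_at_onset=float("nan"),
                    definition=AHEDefinition.CONVENTIONAL,
                )
            )
    return events


def events_to_frame(
    events_by_patient: dict[str, list[AHEEvent]]
) -> pd.DataFrame:
    """Tabulate events as patient_id, onset_minute, end_minute, definition."""
    rows = []
    for pid, events in events_by_patient.items():
        for ev in events:
            rows.append(
                {
                    "patient_id": pid,
                    "onset_minute": ev.onset_index,
                    "end_minute": -1 if ev.end_index is None else ev.end_index,
                    "definition": ev.definition.value,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "onset_minute", "end_minute", "definition"]
    )
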