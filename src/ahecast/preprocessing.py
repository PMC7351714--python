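"""Window-level cleaning, imputation, normalization and decay-model inputs.

All preprocessing operates on the extracted observation window in isolation,
never on the surrounding record, so no information can leak across the
window boundary. The sequence is: (1) values outside normal physiological
ranges are set to NaN; (2) missing values are imputed by backfilling (the
next observed value propagates backwards) followed by forward-filling for a
trailing missing run; (3) each channel is scaled to [0, 1] with a static
range (40-160 mmHg for MAP, 40-160 bpm for HR, 60-100% for SpO2).

For the missing-data-tolerant recurrent model the window is additionally
represented unfilled, as (values, observation mask, time-since-last-
observation), with the per-channel last-observed value carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class FullyMissingChannelError(ValueError):
    """A window channel has no observed sample at all and cannot be imputed."""


@dataclass
class PhysiologicalRanges:
    """Per-channel plausibility bounds; values outside are treated as artifacts."""

    map: tuple[float, float] = (40.0, 160.0)
    hr: tuple[float, float] = (40.0, 160.0)
    spo2: tuple[float, float] = (60.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("map", "hr", "spo2"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: low {lo} must be < high {hi}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lows, highs) arrays ordered (MAP, HR, SpO2) for broadcasting."""
        lows = np.array([self.map[0], self.hr[0], self.spo2[0]])
        highs = np.array([self.map[1], self.hr[1], self.spo2[1]])
        return lows, highs


class NormalizationRanges(PhysiologicalRanges):
    """Static per-channel scaling ranges; they coincide with the
    physiological bounds by default but are configurable separately."""


def resample_to_per_minute(series: np.ndarray, source_rate_hz: float) -> np.ndarray:
    """Down-sample a higher-frequency series to per-minute means.

    Each output minute is the mean of the available source samples whose
    timestamps fall in that minute; an all-missing minute is NaN.
    """
    if source_rate_hz < 1.0 / 60.0:
        raise ValueError("source rate must be at least one sample per minute")
    series = np.asarray(series, dtype=float)
    minutes = (np.arange(len(series)) / source_rate_hz // 60.0).astype(int)
    grouped = pd.Series(series).groupby(minutes).mean()
    n_minutes = int(minutes[-1]) + 1 if len(series) else 0
    out = np.full(n_minutes, np.nan)
    out[grouped.index.to_numpy()] = grouped.to_numpy()
    return out


def remove_nonphysiological(
    window: np.ndarray, ranges: PhysiologicalRanges | None = None
) -> tuple[np.ndarray, int]:
    """Set out-of-range samples to NaN; return (cleaned copy, n replaced)."""
    ranges = ranges or PhysiologicalRanges()
    lows, highs = ranges.bounds()
    out = np.asarray(window, dtype=float).copy()
    offending = ~np.isnan(out) & ((out < lows) | (out > highs))
    out[offending] = np.nan
    return out, int(offending.sum())


def impute(window: np.ndarray) -> np.ndarray:
    """Backfill, then forward-fill the trailing remainder, per channel.

    Uses only values inside the window. A channel with no observed sample
    raises :class:`FullyMissingChannelError`.
    """
    arr = np.asarray(window, dtype=float)
    if np.any(np.all(np.isnan(arr), axis=0)):
        raise FullyMissingChannelError(
            "cannot impute a window with a fully-missing channel"
        )
    df = pd.DataFrame(arr)
    return df.bfill().ffill().to_numpy()


def normalize(
    window: np.ndarray, ranges: NormalizationRanges | None = None
) -> np.ndarray:
    """Scale each channel to [0, 1] with its static range, clipping outliers.

    NaNs pass through unchanged (the unfilled decay-model path normalizes
    before imputation).
    """
    ranges = ranges or NormalizationRanges()
    lows, highs = ranges.bounds()
    out = (np.asarray(window, dtype=float) - lows) / (highs - lows)
    return np.clip(out, 0.0, 1.0)


def denormalize(
    window: np.ndarray, ranges: NormalizationRanges | None = None
) -> np.ndarray:
    """Inverse of :func:`normalize` on values inside [0, 1]."""
    ranges = ranges or NormalizationRanges()
    lows, highs = ranges.bounds()
    return np.asarray(window, dtype=float) * (highs - lows) + lows


@dataclass
class DecayInputs:
    """Triple-input representation of an unfilled window.

    ``values_raw`` is zero-filled at unobserved positions (the model
    substitutes its training-set channel mean there via the decay
    mechanism); ``mask[t, c]`` is 1 iff channel c was observed (and in
    physiological range) at step t; ``time_delta[t, c]`` is the number of
    minutes since channel c was last observed (0 at the first step);
    ``last_observed`` carries the most recent observed value, NaN while a
    channel has not yet been observed within the window.
    """

    values_raw: np.ndarray
    mask: np.ndarray
    time_delta: np.ndarray
    last_observed: np.ndarray


def prepare_decay_inputs(window: np.ndarray, sampling_period: float = 1.0) -> DecayInputs:
    """Build (values, mask, time-delta, last-observed) from an unfilled window.

    The time delta follows the standard decay-model recurrence: delta_1 = 0
    and, for t > 1, delta_t = s + delta_{t-1} if the previous step was
    unobserved, else s (with s the sampling period in minutes).
    """
    arr = np.asarray(window, dtype=float)
    T, C = arr.shape
    mask = (~np.isnan(arr)).astype(float)
    delta = np.zeros((T, C))
    for t in range(1, T):
        delta[t] = np.where(
            mask[t - 1] > 0, sampling_period, sampling_period + delta[t - 1]
        )
    last = np.full((T, C), np.nan)
    current = np.full(C, np.nan)
    for t in range(T):
        observed = mask[t] > 0
        current = np.where(observed, arr[t], current)
        last[t] = current
    return DecayInputs(
        values_raw=np.nan_to_num(arr, nan=0.0),
        mask=mask,
        time_delta=delta,
        last_observed=last,
    )
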