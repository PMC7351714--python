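"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (explicit loops, no shared helpers from
the package) so that agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def trailing_mean(series, width):
    """Naive trailing moving average: loop over indices, mean of available."""
    series = list(series)
    out = []
    for t in range(len(series)):
        if t < width - 1:
            out.append(math.nan)
            continue
        window = [v for v in series[t - width + 1 : t + 1] if not math.isnan(v)]
        out.append(sum(window) / len(window) if window else math.nan)
    return np.array(out)


def annotate_bruteforce(
    map_series,
    long_width=60,
    short_width=5,
    drop=0.20,
    horizon=10,
    floor=20.0,
):
    """Naive episode scan recomputing both trailing means at every index.

    Returns a list of (onset, end) tuples with end None for an open episode.
    """
    x = list(map_series)
    n = len(x)
    if n < long_width + horizon:
        return []

    def mean_at(t, width):
        if t < width - 1:
            return math.nan
        vals = [v for v in x[t - width + 1 : t + 1] if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else math.nan

    def is_drop(t):
        s, lo = mean_at(t, short_width), mean_at(t, long_width)
        if math.isnan(s) or math.isnan(lo):
            return None
        return bool(s <= (1.0 - drop) * lo)

    events = []
    t = long_width - 1
    while t < n:
        d = is_drop(t)
        if d is not True:
            t += 1
            continue
        future = x[t + 1 : t + 1 + horizon]
        ok = len(future) == horizon and all(
            (not math.isnan(v)) and v > floor for v in future
        )
        if not ok:
            t += 1
            continue
        end = None
        for u in range(t + 1, n):
            if is_drop(u) is False:
                end = u
                break
        if end is not None and end - t < horizon:
            t = end
            continue
        events.append((t, end))
        if end is None:
            break
        t = end
    return events


def pairwise_auroc(scores, labels):
    """All-pairs concordance count with ties worth half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def per_minute_means(series, rate_hz):
    """Naive per-minute down-sampling by mean of each minute's samples."""
    n = len(series)
    out = []
    minute = 0
    while True:
        vals = []
        for i in range(n):
            if int((i / rate_hz) // 60) == minute and not math.isnan(series[i]):
                vals.append(series[i])
        in_minute = [i for i in range(n) if int((i / rate_hz) // 60) == minute]
        if not in_minute:
            break
        out.append(sum(vals) / len(vals) if vals else math.nan)
        minute += 1
    return np.array(out)
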