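"""Single-cell trace quantification: normalization, peak detection,
first-peak alignment and the 20-minute peak-interval histogram."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PeakSet",
    "IntervalHistogram",
    "normalize_trace",
    "detect_peaks",
    "align_first_peak",
    "interval_histogram",
    "DEFAULT_BIN_EDGES",
]

#: Interval histogram bin edges in minutes; half-open [lower, upper) bins
#: anchored at 40 with width 20.  Guard bins below 40 and at/above 140 are
#: added by :func:`interval_histogram` so out-of-range intervals stay visible.
DEFAULT_BIN_EDGES = (40.0, 60.0, 80.0, 100.0, 120.0, 140.0)


@dataclass
class PeakSet:
    peak_times_min: np.ndarray
    peak_heights: np.ndarray
    intervals_min: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.peak_times_min = np.asarray(self.peak_times_min, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)
        if len(self.peak_times_min) != len(self.peak_heights):
            raise ValueError("times and heights must share length")
        if np.any(np.diff(self.peak_times_min) <= 0):
            raise ValueError("peak times must be strictly increasing")
        self.intervals_min = np.diff(self.peak_times_min)

    def __len__(self) -> int:
        return len(self.peak_times_min)


@dataclass
class IntervalHistogram:
    bin_edges_min: np.ndarray  # includes the -inf / +inf guard edges
    counts: np.ndarray
    modal_bin: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges_min) - 1:
            raise ValueError("counts/edges length mismatch")


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window in samples)."""
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def normalize_trace(raw: Sequence[float], smooth_window: int = 3) -> np.ndarray:
    """Min-max normalize an intensity series to [0, 1].

    A centered moving average (default 3 frames, i.e. 6 min at 2-min
    sampling) is applied first; set ``smooth_window=1`` to disable.
    Raises ``ValueError`` for series shorter than 2 points or with zero range.
    """
    y = np.asarray(raw, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need a 1-D series with >= 2 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    y = moving_average(y, smooth_window)
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise ValueError("constant series cannot be normalized")
    return (y - lo) / (hi - lo)


def detect_peaks(
    t_min: Sequence[float],
    series: Sequence[float],
    min_prominence: float = 0.2,
    min_separation_min: float = 20.0,
) -> PeakSet:
    """Detect local maxima passing prominence and separation filters.

    ``min_prominence`` is a fraction of the series range.  Peaks closer than
    ``min_separation_min`` are resolved by keeping the higher one; equal
    heights keep the earlier peak.  Endpoints are never peaks.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(series, dtype=float)
    if len(t) != len(y):
        raise ValueError("t_min and series must share length")
    rng = float(y.max() - y.min()) if len(y) else 0.0
    if rng == 0.0:
        return PeakSet(np.array([]), np.array([]))
    idx, _ = find_peaks(y, prominence=min_prominence * rng)
    if len(idx) == 0:
        return PeakSet(np.array([]), np.array([]))
    # separation filter: greedy by height, ties to the earlier peak
    order = sorted(range(len(idx)), key=lambda i: (-y[idx[i]], t[idx[i]]))
    kept: list[int] = []
    for i in order:
        if all(abs(t[idx[i]] - t[idx[j]]) >= min_separation_min for j in kept):
            kept.append(i)
    kept_idx = np.sort(idx[kept])
    return PeakSet(t[kept_idx], y[kept_idx])


def align_first_peak(
    t_min: Sequence[float],
    traces: Sequence[Sequence[float]],
    **peak_kwargs,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, list[int]]:
    """Shift each trace so its first detected peak sits at t = 0.

    Returns ``(shifted_times, mean_t, mean_curve, excluded_indices)`` where
    ``shifted_times[i]`` is the time vector of trace i after alignment, and
    the mean curve is computed on the overlapping support only (the common
    time grid shared by every aligned trace).  Traces without a detected peak
    are excluded and their indices reported.
    """
    t = np.asarray(t_min, dtype=float)
    shifted: list[np.ndarray] = []
    arrays: list[np.ndarray] = []
    excluded: list[int] = []
    for i, tr in enumerate(traces):
        y = np.asarray(tr, dtype=float)
        peaks = detect_peaks(t, y, **peak_kwargs)
        if len(peaks) == 0:
            excluded.append(i)
            continue
        shifted.append(t - peaks.peak_times_min[0])
        arrays.append(y)
    if not shifted:
        raise ValueError("no trace has a detectable peak")
    lo = max(s[0] for s in shifted)
    hi = min(s[-1] for s in shifted)
    dt = float(np.median(np.diff(t)))
    mean_t = np.arange(np.ceil(lo / dt), np.floor(hi / dt) + 1) * dt
    stack = np.vstack([np.interp(mean_t, s, y) for s, y in zip(shifted, arrays)])
    return shifted, mean_t, stack.mean(axis=0), excluded


def interval_histogram(
    intervals_min: Sequence[float],
    bin_edges_min: Sequence[float] = DEFAULT_BIN_EDGES,
) -> IntervalHistogram:
    """Histogram of peak-to-peak intervals in fixed half-open bins.

    Guard bins (-inf, first_edge) and [last_edge, +inf) are prepended and
    appended so every interval is counted.  The modal bin is the bin with the
    largest count; ties go to the lower bin.
    """
    iv = np.asarray(intervals_min, dtype=float)
    if len(iv) == 0:
        raise ValueError("need at least one interval")
    edges = np.concatenate([[-np.inf], np.asarray(bin_edges_min, dtype=float), [np.inf]])
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts = np.array(
        [np.count_nonzero((iv >= lo) & (iv < hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    modal = int(np.argmax(counts))  # argmax takes the first (= lower) bin on ties
    return IntervalHistogram(
        bin_edges_min=edges,
        counts=counts,
        modal_bin=(float(edges[modal]), float(edges[modal + 1])),
    )
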