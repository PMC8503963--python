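"""Event characterization: oscillation peaks, average frequency, cycles.

The average frequency of an event is the sampling rate divided by the mean
peak-to-peak distance of the bandpass-filtered signal inside the event
window; the number of cycles is the event duration divided by the mean
peak-to-peak interval (and so may be fractional). The peak z-score is the
maximum of the normalized envelope over the event interval.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "InsufficientPeaksError",
    "oscillation_peaks",
    "average_frequency",
    "cycle_count",
    "peak_zscore",
]


class InsufficientPeaksError(ValueError):
    """Fewer than two oscillation peaks: no peak-to-peak interval exists."""


def oscillation_peaks(segment: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a 1-D segment.

    A sample is a peak when it exceeds both neighbors; for a flat plateau
    preceded by a rise and followed by a fall, the first plateau sample is
    taken. Endpoints are never peaks.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or x.size < 3:
        return np.empty(0, dtype=int)
    d = np.sign(np.diff(x))
    # back-fill zero slopes with the next nonzero slope so that a
    # rise-plateau-fall pattern registers a fall at the plateau's first sample
    filled = d.copy()
    nz = filled != 0
    if not nz.any():
        return np.empty(0, dtype=int)
    idx = np.where(nz, np.arange(d.size), d.size)
    nxt = np.minimum.accumulate(idx[::-1])[::-1]
    valid = nxt < d.size
    filled[valid] = d[nxt[valid]]
    peaks = np.flatnonzero((d[:-1] > 0) & (filled[1:] < 0)) + 1
    return peaks.astype(int)


def _mean_p2p(peaks: np.ndarray) -> float:
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise InsufficientPeaksError(
            f"need >= 2 peaks, got {peaks.size}"
        )
    return float(np.mean(np.diff(peaks)))


def average_frequency(peaks: np.ndarray, srate: float) -> float:
    """Average frequency in Hz: srate / mean successive peak distance."""
    return srate / _mean_p2p(peaks)


def cycle_count(duration_s: float, peaks: np.ndarray, srate: float) -> float:
    """Number of cycles: event duration over the mean peak-to-peak interval.

    Equals ``duration_s * average_frequency(peaks, srate)``; fractional
    values are meaningful and kept.
    """
    return duration_s * srate / _mean_p2p(peaks)


def peak_zscore(z: np.ndarray, interval: tuple[int, int]) -> float:
    """Maximum of the z-scored envelope over a half-open sample interval."""
    start, end = interval
    if end <= start:
        raise ValueError("interval must be non-empty")
    return float(np.max(np.asarray(z)[start:end]))
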