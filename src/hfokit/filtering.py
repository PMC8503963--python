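"""Zero-phase bandpass and notch filtering for the detector front end.

Two filter kinds are offered, matching common practice in clinical iEEG
pipelines: a fourth-order Butterworth (IIR) and a window-based FIR whose
order is three times the sampling rate divided by the low cutoff. Both are
applied forward-backward (zero phase), so envelope timing is preserved and
the effective stopband attenuation is doubled relative to a single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["FilterSpec", "fir_order", "bandpass", "notch"]


@dataclass
class FilterSpec:
    """Bandpass filter choice: kind, band edges, optional mains notch."""

    kind: str = "fir_window"
    band: tuple[float, float] = (80.0, 250.0)
    notch_freq: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fir_window", "butterworth4"):
            raise ValueError("kind must be 'fir_window' or 'butterworth4'")
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.notch_freq not in (None, 50, 60):
            raise ValueError("notch_freq must be None, 50, or 60")


def fir_order(srate: float, low_cutoff: float) -> int:
    """FIR filter order: floor(3 * srate / low_cutoff).

    The fractional quotient is floored to an integer tap count.
    """
    if low_cutoff <= 0:
        raise ValueError("low_cutoff must be positive")
    if srate <= 0:
        raise ValueError("srate must be positive")
    return math.floor(3.0 * srate / low_cutoff)


def _check_band(band: tuple[float, float], srate: float) -> None:
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}: need 0 < low < high")
    if high >= srate / 2:
        raise ValueError(
            f"band high edge {high} Hz >= Nyquist ({srate / 2} Hz)"
        )


def bandpass(
    x: np.ndarray, srate: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase bandpass filter of a 1-D series.

    FIR kind: Hamming-window design of order ``fir_order(srate, low)``.
    IIR kind: fourth-order Butterworth, applied as second-order sections.
    Both run forward-backward with reflect padding of one filter length to
    suppress boundary transients.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass expects a 1-D series")
    _check_band(spec.band, srate)
    low, high = spec.band

    if spec.kind == "fir_window":
        order = fir_order(srate, low)
        if x.size <= 3 * order:
            raise ValueError(
                f"signal of {x.size} samples too short for FIR order {order}"
            )
        ntaps = order + 1
        if ntaps % 2 == 0:  # odd tap count keeps a well-defined passband
            ntaps += 1
        b = sps.firwin(ntaps, [low, high], pass_zero=False, fs=srate)
        y = sps.filtfilt(b, [1.0], x, padtype="even",
                         padlen=min(ntaps, x.size - 1))
    else:
        sos = sps.butter(4, [low, high], btype="bandpass", fs=srate,
                         output="sos")
        y = sps.sosfiltfilt(sos, x)
    if spec.notch_freq is not None:
        y = notch(y, srate, spec.notch_freq)
    return y


def notch(x: np.ndarray, srate: float, line_freq: int) -> np.ndarray:
    """Remove 50/60 Hz mains interference with a zero-phase IIR notch.

    The notch is narrow (quality factor 35), so tones 20 Hz or more from
    the line frequency pass essentially unchanged.
    """
    if line_freq not in (50, 60):
        raise ValueError("line_freq must be 50 or 60 Hz")
    if line_freq >= srate / 2:
        raise ValueError("line_freq must be below Nyquist")
    x = np.asarray(x, dtype=float)
    b, a = sps.iirnotch(line_freq, Q=35.0, fs=srate)
    return sps.filtfilt(b, a, x)
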