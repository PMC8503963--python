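"""Gabor-wavelet time-frequency maps and click-guided narrow-band detection.

The time-frequency map is a continuous wavelet transform with a Gabor
wavelet — a Gaussian-windowed complex exponential

    psi(t) = (sigma^2 pi)^(-1/4) exp(-t^2 / (2 sigma^2)) exp(i eta t),

where eta = 2*pi*f is the angular frequency of the analyzed scale and the
Gaussian SD defaults to sigma = 6 / eta. Each scale is normalized by
1/sqrt(s) with scale s = 1/f. The transform is evaluated one frequency row
at a time by FFT convolution.

Click-guided detection averages the map over a short time window around a
cursor, takes the peak frequency, derives a narrow band around it (fixed
width, or the crossings where the spectrum falls to a percentage of its
peak), bandpasses the raw series in that band, and hands off to the
cursor-mode Hilbert detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .data_model import EventRecord, HilbertConfig
from .detector import detect_at_cursor, envelope, zscore_envelope
from .filtering import FilterSpec, bandpass

__all__ = [
    "SpectrogramConfig",
    "TimeFrequencyMap",
    "DegenerateBandError",
    "gabor_cwt",
    "averaged_spectrum_at",
    "peak_frequency_at",
    "band_from_peak",
    "spectrogram_guided_detect",
]

logger = logging.getLogger(__name__)


class DegenerateBandError(ValueError):
    """The derived narrow band is empty or outside (0, Nyquist)."""


def _default_freqs() -> np.ndarray:
    return np.arange(60.0, 500.0 + 1e-9, 5.0)


@dataclass
class SpectrogramConfig:
    """Time-frequency analysis and narrow-band derivation parameters.

    ``sigma_factor`` sets the Gaussian window SD per scale as
    sigma = sigma_factor / (2*pi*f); the default 6 trades ~1 cycle of time
    resolution for narrow frequency ridges. ``bandwidth`` is a width in Hz
    in fixed mode, or a percentage of the spectral peak in (0, 100) when
    ``percentage_mode`` is set. ``time_window`` (s) is the averaging window
    around a click.
    """

    freqs: np.ndarray = field(default_factory=_default_freqs)
    sigma_factor: float = 6.0
    time_window: float = 0.2
    bandwidth: float = 20.0
    percentage_mode: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.size == 0:
            raise ValueError("freqs must be a non-empty 1-D grid")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[0] <= 0:
            raise ValueError("freqs must be positive")
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")
        if self.percentage_mode and not 0 < self.bandwidth < 100:
            raise ValueError("percentage bandwidth must lie in (0, 100)")


@dataclass
class TimeFrequencyMap:
    """Magnitude of the wavelet transform: one row per frequency."""

    magnitude: np.ndarray
    freqs: np.ndarray
    srate: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.magnitude.shape[0] != self.freqs.size:
            raise ValueError("one magnitude row per frequency required")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.magnitude.shape[1]


def _gabor_kernel(f: float, srate: float, sigma_factor: float) -> np.ndarray:
    eta = 2.0 * np.pi * f
    sigma = sigma_factor / eta
    half = int(np.ceil(5.0 * sigma * srate))
    t = np.arange(-half, half + 1) / srate
    gauss = (sigma**2 * np.pi) ** -0.25 * np.exp(-(t**2) / (2.0 * sigma**2))
    return gauss * np.exp(1j * eta * t)


def gabor_cwt(
    x: np.ndarray, srate: float, cfg: SpectrogramConfig | None = None
) -> TimeFrequencyMap:
    """Continuous Gabor-wavelet transform magnitude of a 1-D series.

    Rows follow ``cfg.freqs``; each row is the magnitude of the FFT
    convolution of the signal with the scale's wavelet (kernel truncated at
    five Gaussian SDs), scaled by sqrt(f) (the 1/sqrt(s) normalization with
    s = 1/f).
    """
    cfg = cfg or SpectrogramConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("gabor_cwt expects a 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    nyq = srate / 2.0
    if cfg.freqs[-1] >= nyq:
        raise ValueError(
            f"max analysis frequency {cfg.freqs[-1]} Hz >= Nyquist ({nyq} Hz)"
        )
    mag = np.empty((cfg.freqs.size, x.size))
    dt = 1.0 / srate
    for i, f in enumerate(cfg.freqs):
        kern = _gabor_kernel(f, srate, cfg.sigma_factor)
        conv = sps.fftconvolve(x, np.conj(kern[::-1]), mode="same") * dt
        mag[i] = np.sqrt(f) * np.abs(conv)
    return TimeFrequencyMap(mag, cfg.freqs.copy(), srate)


def averaged_spectrum_at(
    tfm: TimeFrequencyMap, click_sample: int, time_window_s: float
) -> np.ndarray:
    """Time-averaged magnitude spectrum in a window centered at a click.

    The window is clipped at the series edges.
    """
    if not 0 <= click_sample < tfm.n_samples:
        raise ValueError("click outside the series")
    half = int(round(time_window_s / 2.0 * tfm.srate))
    lo = max(0, click_sample - half)
    hi = min(tfm.n_samples, click_sample + half + 1)
    return tfm.magnitude[:, lo:hi].mean(axis=1)


def peak_frequency_at(
    tfm: TimeFrequencyMap, click_sample: int, time_window_s: float
) -> float:
    """Peak frequency of the time-averaged spectrum around a click."""
    spec = averaged_spectrum_at(tfm, click_sample, time_window_s)
    return float(tfm.freqs[int(np.argmax(spec))])


def band_from_peak(
    avg_spectrum: np.ndarray,
    freqs: np.ndarray,
    peak_freq: float,
    cfg: SpectrogramConfig,
    nyquist: float | None = None,
) -> tuple[float, float]:
    """Derive the narrow bandpass band around a spectral peak.

    Fixed mode: (peak - bandwidth/2, peak + bandwidth/2). Percentage mode:
    on each side of the peak, the nearest grid frequency where the spectrum
    has fallen to (bandwidth/100) of the peak magnitude; if the spectrum
    never falls that low on a side, the grid end is used.
    """
    freqs = np.asarray(freqs, dtype=float)
    avg_spectrum = np.asarray(avg_spectrum, dtype=float)
    idx = int(np.argmin(np.abs(freqs - peak_freq)))
    if not np.isclose(freqs[idx], peak_freq):
        raise ValueError(f"peak_freq {peak_freq} not on the frequency grid")

    if not cfg.percentage_mode:
        low = peak_freq - cfg.bandwidth / 2.0
        high = peak_freq + cfg.bandwidth / 2.0
    else:
        cutoff = cfg.bandwidth / 100.0 * avg_spectrum[idx]
        below = avg_spectrum <= cutoff
        lows = np.flatnonzero(below[:idx])
        highs = np.flatnonzero(below[idx + 1 :]) + idx + 1
        low = freqs[lows[-1]] if lows.size else freqs[0]
        high = freqs[highs[0]] if highs.size else freqs[-1]

    if nyquist is None:
        nyquist = freqs[-1] * 2.0
    if not 0 < low < high < nyquist:
        raise DegenerateBandError(
            f"derived band ({low:.1f}, {high:.1f}) Hz is empty or outside "
            f"(0, {nyquist:.0f}) Hz"
        )
    return (float(low), float(high))


def spectrogram_guided_detect(
    signal: np.ndarray,
    srate: float,
    click_sample: int,
    spec_cfg: SpectrogramConfig | None = None,
    det_cfg: HilbertConfig | None = None,
    tfm: TimeFrequencyMap | None = None,
    label: str = "",
) -> EventRecord | None:
    """Detect an event at a spectrogram click via a narrow peak-guided band.

    Composes the peak frequency at the click, the narrow band around it,
    a bandpass of the raw series in that band, and cursor-mode detection at
    the click. The returned event's band is the narrow band. A degenerate
    band yields ``None`` with a logged reason. Pass a precomputed ``tfm``
    to avoid recomputing the transform for repeated clicks.
    """
    spec_cfg = spec_cfg or SpectrogramConfig()
    det_cfg = det_cfg or HilbertConfig()
    x = np.asarray(signal, dtype=float)
    if tfm is None:
        tfm = gabor_cwt(x, srate, spec_cfg)
    spectrum = averaged_spectrum_at(tfm, click_sample, spec_cfg.time_window)
    peak = float(tfm.freqs[int(np.argmax(spectrum))])
    try:
        band = band_from_peak(spectrum, tfm.freqs, peak, spec_cfg,
                              nyquist=srate / 2.0)
    except DegenerateBandError as exc:
        logger.info("spectrogram-guided detection aborted: %s", exc)
        return None
    narrow_cfg = replace(det_cfg, band=band)
    bp = bandpass(x, srate, FilterSpec(kind=narrow_cfg.filter_kind, band=band,
                                       notch_freq=narrow_cfg.notch))
    z = zscore_envelope(envelope(bp), narrow_cfg.baseline, srate)
    return detect_at_cursor(z, bp, srate, click_sample, narrow_cfg,
                            label=label)
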