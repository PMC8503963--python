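"""Two-threshold Hilbert envelope detection of high-frequency oscillations.

The pipeline: bandpass filter the raw series (optionally notch-filtered),
take the Hilbert envelope, z-score it against a baseline (the whole series
or fixed-length epochs), find clusters of samples at or above the *onset*
threshold, and accept a cluster as an event when (1) its maximal z-score
reaches the *inclusion* threshold and (2) the number of oscillation cycles
measured between the onset crossings reaches the configured minimum. Event
boundaries are exactly the onset-threshold crossings.

A single-threshold comparator in the style of RIPPLELAB is also provided:
one SD threshold plus a minimum duration in milliseconds, on the same
per-epoch z-scored envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from . import features
from .data_model import EventRecord, HilbertConfig, Recording, classify_frequency
from .filtering import FilterSpec, bandpass

__all__ = [
    "ClusterInterval",
    "DegenerateBaselineError",
    "envelope",
    "zscore_envelope",
    "find_clusters",
    "qualify",
    "detect_channel",
    "detect_at_cursor",
    "ripplelab_hilbert",
]

logger = logging.getLogger(__name__)


class DegenerateBaselineError(ValueError):
    """The baseline segment has zero variance; z-scoring is undefined."""


@dataclass(frozen=True)
class ClusterInterval:
    """A maximal run of supra-onset-threshold envelope samples.

    Half-open sample interval; ``peak_z`` is the maximum z-score inside.
    """

    start_sample: int
    end_sample: int
    peak_z: float


def envelope(bp_signal: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic signal.

    Computed with a Hilbert transform on an FFT length padded to a fast
    composite size, then truncated back.
    """
    x = np.asarray(bp_signal, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    nfft = sfft.next_fast_len(n)
    return np.abs(sps.hilbert(x, N=nfft)[:n])


def _epoch_bounds(n: int, baseline: float | str, srate: float) -> list[tuple[int, int]]:
    if baseline == "whole":
        return [(0, n)]
    epoch = int(round(float(baseline) * srate))
    if epoch <= 0:
        raise ValueError("epoch length must be positive")
    bounds = [(s, min(s + epoch, n)) for s in range(0, n, epoch)]
    return bounds


def zscore_envelope(
    env: np.ndarray, baseline: float | str, srate: float
) -> np.ndarray:
    """Z-score the envelope against its baseline mean and SD.

    ``baseline`` is either ``"whole"`` (one global normalization) or an
    epoch length in seconds: each epoch is normalized by its own mean and
    SD, with a trailing partial epoch normalized by its own statistics.
    """
    env = np.asarray(env, dtype=float)
    out = np.empty_like(env)
    for s, e in _epoch_bounds(env.size, baseline, srate):
        seg = env[s:e]
        sd = seg.std()
        if sd == 0:
            raise DegenerateBaselineError(
                f"zero-variance baseline in samples [{s}, {e})"
            )
        out[s:e] = (seg - seg.mean()) / sd
    return out


def find_clusters(z: np.ndarray, onset_threshold: float) -> list[ClusterInterval]:
    """Maximal runs of ``z >= onset_threshold``, in temporal order."""
    z = np.asarray(z, dtype=float)
    mask = z >= onset_threshold
    if not mask.any():
        return []
    edges = np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        ClusterInterval(int(s), int(e), float(z[s:e].max()))
        for s, e in zip(starts, ends)
    ]


def qualify(
    interval: ClusterInterval,
    z: np.ndarray,
    bp_signal: np.ndarray,
    srate: float,
    cfg: HilbertConfig,
    label: str = "",
) -> EventRecord | None:
    """Accept or reject a cluster; characterize it on acceptance.

    A cluster becomes an event iff its maximal z-score reaches
    ``cfg.inclusion_threshold`` and the cycle count measured between its
    onset-threshold boundaries reaches ``cfg.min_cycles``. A cluster whose
    bandpassed segment has fewer than two oscillation peaks has no defined
    cycle count and is rejected.
    """
    s, e = interval.start_sample, interval.end_sample
    pz = features.peak_zscore(z, (s, e))
    if pz < cfg.inclusion_threshold:
        return None
    peaks = features.oscillation_peaks(np.asarray(bp_signal)[s:e])
    if peaks.size < 2:
        return None
    duration_s = (e - s) / srate
    n_cycles = features.cycle_count(duration_s, peaks, srate)
    if n_cycles < cfg.min_cycles:
        return None
    avg_freq = features.average_frequency(peaks, srate)
    return EventRecord(
        label=label,
        start_sample=s,
        end_sample=e,
        type=classify_frequency(avg_freq),
        avg_freq=avg_freq,
        n_cycles=n_cycles,
        peak_zscore=pz,
        bp_freq=cfg.band,
    )


def _prepare(signal: np.ndarray, srate: float, cfg: HilbertConfig):
    """Bandpass (+ optional notch), envelope, per-baseline z-score."""
    spec = FilterSpec(kind=cfg.filter_kind, band=cfg.band,
                      notch_freq=cfg.notch)
    bp = bandpass(signal, srate, spec)
    z = zscore_envelope(envelope(bp), cfg.baseline, srate)
    return bp, z


def detect_channel(
    rec: Recording, channel: str, cfg: HilbertConfig | None = None
) -> list[EventRecord]:
    """Run the two-threshold detector over one channel of a recording.

    Clusters are found within each baseline epoch independently (a cluster
    touching an epoch edge is kept as-is). Returned events are sorted by
    start sample and carry the channel label and bandpass band.
    """
    cfg = cfg or HilbertConfig()
    signal = rec.channel(channel)
    bp, z = _prepare(signal, rec.srate, cfg)
    events: list[EventRecord] = []
    for s, e in _epoch_bounds(signal.size, cfg.baseline, rec.srate):
        for cl in find_clusters(z[s:e], cfg.onset_threshold):
            shifted = ClusterInterval(cl.start_sample + s, cl.end_sample + s,
                                      cl.peak_z)
            ev = qualify(shifted, z, bp, rec.srate, cfg, label=channel)
            if ev is not None:
                events.append(ev)
    events.sort(key=lambda ev: ev.start_sample)
    return events


def detect_at_cursor(
    z: np.ndarray,
    bp_signal: np.ndarray,
    srate: float,
    cursor_sample: int,
    cfg: HilbertConfig,
    label: str = "",
) -> EventRecord | None:
    """Qualify the cluster nearest a cursor within the search range.

    Among clusters with any sample within ``cfg.search_range`` seconds of
    the cursor, the nearest (earlier one on a tie) is qualified; returns
    ``None`` when no cluster is in range or qualification fails.
    """
    if not 0 <= cursor_sample < len(z):
        raise ValueError("cursor outside the series")
    range_samples = cfg.search_range * srate
    best: ClusterInterval | None = None
    best_dist = np.inf
    for cl in find_clusters(z, cfg.onset_threshold):
        if cl.start_sample <= cursor_sample < cl.end_sample:
            dist = 0.0
        else:
            dist = min(
                abs(cursor_sample - cl.start_sample),
                abs(cursor_sample - (cl.end_sample - 1)),
            )
        if dist <= range_samples and dist < best_dist:
            best, best_dist = cl, dist
    if best is None:
        return None
    return qualify(best, z, bp_signal, srate, cfg, label=label)


def ripplelab_hilbert(
    signal: np.ndarray,
    srate: float,
    band: tuple[float, float] = (80.0, 250.0),
    sd_threshold: float = 3.5,
    min_duration_ms: float = 10.0,
    epoch_length_s: float | str = 600.0,
    filter_kind: str = "fir_window",
    label: str = "",
) -> list[EventRecord]:
    """Single-threshold comparator detector (RIPPLELAB-style).

    The per-epoch z-scored envelope is thresholded at ``sd_threshold`` SD;
    maximal supra-threshold runs lasting at least ``min_duration_ms`` become
    events, characterized with the same features as the main detector. A
    run whose bandpassed segment shows fewer than two oscillation peaks
    cannot be assigned a frequency and is dropped.
    """
    x = np.asarray(signal, dtype=float)
    spec = FilterSpec(kind=filter_kind, band=band)
    bp = bandpass(x, srate, spec)
    z = zscore_envelope(envelope(bp), epoch_length_s, srate)
    min_samples = min_duration_ms * 1e-3 * srate
    events: list[EventRecord] = []
    for s, e in _epoch_bounds(x.size, epoch_length_s, srate):
        for cl in find_clusters(z[s:e], sd_threshold):
            if (cl.end_sample - cl.start_sample) < min_samples:
                continue
            cs, ce = cl.start_sample + s, cl.end_sample + s
            peaks = features.oscillation_peaks(bp[cs:ce])
            if peaks.size < 2:
                continue
            duration_s = (ce - cs) / srate
            avg_freq = features.average_frequency(peaks, srate)
            events.append(
                EventRecord(
                    label=label,
                    start_sample=cs,
                    end_sample=ce,
                    type=classify_frequency(avg_freq),
                    avg_freq=avg_freq,
                    n_cycles=features.cycle_count(duration_s, peaks, srate),
                    peak_zscore=cl.peak_z,
                    bp_freq=band,
                )
            )
    events.sort(key=lambda ev: ev.start_sample)
    return events
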