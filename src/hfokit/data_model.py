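"""Core domain types and file formats.

A :class:`Recording` holds a multichannel iEEG matrix in microvolts together
with channel labels, sampling rate, and the wall clock of the first sample.
Detected or manually marked events are :class:`EventRecord` objects; lists of
them round-trip through a tab-separated events table, and per-channel counts
and total durations go to a companion summary table. EDF (European Data
Format) recordings are read through MNE; a minimal 16-bit EDF writer is
provided for exporting simulated recordings and building test fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EVENT_TYPES",
    "Recording",
    "EventRecord",
    "HilbertConfig",
    "RecordingFormatError",
    "EventTableParseError",
    "classify_frequency",
    "load_recording",
    "write_recording_edf",
    "write_events_table",
    "read_events_table",
    "write_summary",
]

logger = logging.getLogger(__name__)

#: The five-value event vocabulary.
EVENT_TYPES = ("gamma", "ripple", "fastripple", "ultrafast", "spike")

#: Conventional band edges used to classify an event by its average
#: frequency: gamma < 80 Hz <= ripple < 250 Hz <= fast ripple < 500 Hz <=
#: ultrafast.
_CLASS_EDGES = (80.0, 250.0, 500.0)


class RecordingFormatError(ValueError):
    """A recording file exists but cannot be interpreted."""


class EventTableParseError(ValueError):
    """A row of an events table could not be parsed."""


def classify_frequency(freq_hz: float) -> str:
    """Map an average frequency to an event-type label.

    Uses the conventional sub-band edges: gamma below 80 Hz, ripple
    80-250 Hz, fast ripple 250-500 Hz, ultrafast above 500 Hz.
    """
    if freq_hz < _CLASS_EDGES[0]:
        return "gamma"
    if freq_hz < _CLASS_EDGES[1]:
        return "ripple"
    if freq_hz < _CLASS_EDGES[2]:
        return "fastripple"
    return "ultrafast"


@dataclass
class Recording:
    """A multichannel recording: channels x samples, in microvolts.

    Parameters
    ----------
    mat : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts.
    labels : list of str
        Channel names, one per row of ``mat``; must be unique.
    srate : float
        Sampling rate in samples per second.
    start_clock : datetime, optional
        Wall clock of the first sample.
    file : str, optional
        Source path, if the recording was loaded from disk.
    """

    mat: np.ndarray
    labels: list[str]
    srate: float
    start_clock: datetime | None = None
    file: str | None = None

    def __post_init__(self) -> None:
        self.mat = np.atleast_2d(np.asarray(self.mat, dtype=float))
        if self.mat.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for {self.mat.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.srate > 0:
            raise ValueError("srate must be positive")

    @property
    def n_channels(self) -> int:
        return self.mat.shape[0]

    @property
    def n_samples(self) -> int:
        return self.mat.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal for a channel by name."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.mat[idx]


@dataclass
class EventRecord:
    """One marked or detected event on a single channel.

    Sample indices are 0-based and the interval is half-open
    ``[start_sample, end_sample)``, so the duration is
    ``(end_sample - start_sample) / srate``. ``peak_zscore`` and ``bp_freq``
    are populated by detection and may be ``None`` on ground-truth or
    hand-entered events.
    """

    label: str
    start_sample: int
    end_sample: int
    type: str
    avg_freq: float
    n_cycles: float
    peak_zscore: float | None = None
    bp_freq: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.start_sample = int(self.start_sample)
        self.end_sample = int(self.end_sample)
        if self.start_sample >= self.end_sample:
            raise ValueError("start_sample must precede end_sample")
        if self.type not in EVENT_TYPES:
            raise ValueError(
                f"type {self.type!r} not one of {EVENT_TYPES}"
            )
        if not self.n_cycles > 0:
            raise ValueError("n_cycles must be positive")
        if self.bp_freq is not None:
            low, high = self.bp_freq
            if not 0 < low < high:
                raise ValueError("bp_freq must satisfy 0 < low < high")
            self.bp_freq = (float(low), float(high))

    def duration_s(self, srate: float) -> float:
        return (self.end_sample - self.start_sample) / srate

    def overlaps(self, other: "EventRecord") -> bool:
        """True if the half-open sample intervals share >= 1 sample."""
        return (
            self.start_sample < other.end_sample
            and other.start_sample < self.end_sample
        )


@dataclass
class HilbertConfig:
    """Parameters of the two-threshold Hilbert detector.

    ``onset_threshold`` (in baseline SD units) defines cluster boundaries on
    the z-scored envelope; ``inclusion_threshold`` gates acceptance at the
    cluster peak; ``min_cycles`` is the minimum number of oscillation cycles
    measured within the cluster boundaries. ``baseline`` is either the
    string ``"whole"`` or an epoch length in seconds over which the envelope
    is independently z-scored. ``search_range`` (seconds) applies only to
    cursor-guided detection.
    """

    band: tuple[float, float] = (80.0, 250.0)
    onset_threshold: float = 1.0
    inclusion_threshold: float = 5.0
    min_cycles: float = 2.4
    baseline: float | str = 600.0
    notch: int | None = None
    filter_kind: str = "fir_window"
    search_range: float = 0.2

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.onset_threshold > self.inclusion_threshold:
            raise ValueError("onset_threshold must not exceed inclusion_threshold")
        if not self.min_cycles > 0:
            raise ValueError("min_cycles must be positive")
        if self.notch not in (None, 50, 60):
            raise ValueError("notch must be None, 50, or 60")
        if self.filter_kind not in ("fir_window", "butterworth4"):
            raise ValueError("filter_kind must be 'fir_window' or 'butterworth4'")
        if isinstance(self.baseline, str) and self.baseline != "whole":
            raise ValueError("baseline must be 'whole' or an epoch length in s")


# ---------------------------------------------------------------------------
# EDF input/output
# ---------------------------------------------------------------------------


def _dedupe_labels(labels: Sequence[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            new = f"{lab}-{seen[lab]}"
            logger.warning("duplicate channel label %r renamed to %r", lab, new)
            out.append(new)
        else:
            seen[lab] = 0
            out.append(lab)
    return out


def load_recording(path: str | Path, format: str = "edf") -> Recording:
    """Load a multichannel recording from disk.

    Parameters
    ----------
    path : path-like
        Path to an EDF file.
    format : {"edf"}
        Only EDF is supported.

    Returns
    -------
    Recording
        All channels, in file order, in microvolts. Duplicate channel names
        are de-duplicated with a numeric suffix (a warning is logged).
    """
    if format != "edf":
        raise ValueError(f"unsupported format {format!r}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    import mne

    try:
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt files
        raise RecordingFormatError(f"cannot read EDF file {p}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise RecordingFormatError(f"no channels in {p}")
    data = raw.get_data(units="uV")
    meas = raw.info.get("meas_date")
    start_clock = None
    if meas is not None:
        start_clock = meas.replace(tzinfo=None)
    return Recording(
        mat=np.asarray(data, dtype=float),
        labels=_dedupe_labels(list(raw.ch_names)),
        srate=float(raw.info["sfreq"]),
        start_clock=start_clock,
        file=str(p),
    )


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _format_phys(v: float) -> str:
    # EDF physical min/max must fit 8 ASCII chars
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} in 8 characters")


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as a 16-bit EDF file.

    Each channel is scaled to its own physical min/max, so quantization
    error is at most (max - min) / 2**16 microvolts per channel. One data
    record per second is used when the sample count divides evenly by the
    sampling rate; otherwise the whole signal is stored as a single record.
    """
    p = Path(path)
    n_ch, n_samp = rec.mat.shape
    srate = rec.srate
    if n_samp % int(srate) == 0 and srate == int(srate):
        samples_per_record = int(srate)
        record_dur = 1.0
    else:
        samples_per_record = n_samp
        record_dur = n_samp / srate
    n_records = n_samp // samples_per_record

    clock = rec.start_clock or datetime(2000, 1, 1)
    pmins, pmaxs = [], []
    for ch in rec.mat:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)

    dur_str = ("%g" % record_dur)
    if len(dur_str) > 8:
        dur_str = "%.6f" % record_dur

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate X X X X", 80),
            _ascii_field(clock.strftime("%d.%m.%y"), 8),
            _ascii_field(clock.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (n_ch + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(dur_str, 8),
            _ascii_field(n_ch, 4),
        ]
    )

    def sig_fields(getter, width):
        return b"".join(_ascii_field(getter(i), width) for i in range(n_ch))

    header += sig_fields(lambda i: rec.labels[i], 16)
    header += sig_fields(lambda i: "", 80)
    header += sig_fields(lambda i: "uV", 8)
    header += sig_fields(lambda i: _format_phys(pmins[i]), 8)
    header += sig_fields(lambda i: _format_phys(pmaxs[i]), 8)
    header += sig_fields(lambda i: -32768, 8)
    header += sig_fields(lambda i: 32767, 8)
    header += sig_fields(lambda i: "", 80)
    header += sig_fields(lambda i: samples_per_record, 8)
    header += sig_fields(lambda i: "", 32)

    # digital conversion uses the *formatted* physical range so that the
    # reader's rescaling inverts ours exactly
    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for i, ch in enumerate(rec.mat):
        lo = float(_format_phys(pmins[i]))
        hi = float(_format_phys(pmaxs[i]))
        scaled = (ch - lo) / (hi - lo) * 65535.0 - 32768.0
        digital[i] = np.clip(np.round(scaled), -32768, 32767).astype("<i2")

    with open(p, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * samples_per_record, (r + 1) * samples_per_record)
            for i in range(n_ch):
                fh.write(digital[i, sl].tobytes())
    return p


# ---------------------------------------------------------------------------
# Events table and per-channel summary
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "channel",
    "start_sample",
    "end_sample",
    "start_s",
    "end_s",
    "start_clock",
    "end_clock",
    "type",
    "avg_freq_hz",
    "n_cycles",
    "peak_zscore",
    "bp_low_hz",
    "bp_high_hz",
)

_CLOCK_FMT = "%Y-%m-%d %H:%M:%S.%f"


def _fmt_opt(v: float | None) -> str:
    # repr round-trips floats exactly, preserving write->read identity
    return "" if v is None else repr(float(v))


def write_events_table(
    events: Iterable[EventRecord],
    path: str | Path,
    srate: float,
    start_clock: datetime | None = None,
) -> Path:
    """Write events as a tab-separated table, one row per event.

    Times appear three ways: exact sample indices, seconds from recording
    start (4 decimals), and wall clock derived from ``start_clock`` (blank
    when no clock is known). ``read_events_table`` inverts this exactly via
    the sample columns.
    """
    p = Path(path)
    lines = ["\t".join(_TABLE_COLUMNS)]
    for ev in events:
        s_s = ev.start_sample / srate
        e_s = ev.end_sample / srate
        if start_clock is not None:
            s_clk = (start_clock + timedelta(seconds=s_s)).strftime(_CLOCK_FMT)
            e_clk = (start_clock + timedelta(seconds=e_s)).strftime(_CLOCK_FMT)
        else:
            s_clk = e_clk = ""
        low, high = ev.bp_freq if ev.bp_freq is not None else (None, None)
        lines.append(
            "\t".join(
                [
                    ev.label,
                    str(ev.start_sample),
                    str(ev.end_sample),
                    f"{s_s:.4f}",
                    f"{e_s:.4f}",
                    s_clk,
                    e_clk,
                    ev.type,
                    repr(float(ev.avg_freq)),
                    repr(float(ev.n_cycles)),
                    _fmt_opt(ev.peak_zscore),
                    _fmt_opt(low),
                    _fmt_opt(high),
                ]
            )
        )
    p.write_text("\n".join(lines) + "\n")
    return p


def read_events_table(path: str | Path) -> list[EventRecord]:
    """Read an events table written by :func:`write_events_table`.

    Raises
    ------
    EventTableParseError
        Naming the 1-based line number of the first malformed row.
    """
    p = Path(path)
    lines = p.read_text().splitlines()
    if not lines:
        raise EventTableParseError(f"{p}: empty file")
    header = lines[0].split("\t")
    if tuple(header) != _TABLE_COLUMNS:
        raise EventTableParseError(f"{p}: line 1: unrecognized header")
    events = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_TABLE_COLUMNS):
            raise EventTableParseError(
                f"{p}: line {lineno}: expected {len(_TABLE_COLUMNS)} fields, "
                f"got {len(parts)}"
            )
        row = dict(zip(_TABLE_COLUMNS, parts))
        try:
            low = float(row["bp_low_hz"]) if row["bp_low_hz"] else None
            high = float(row["bp_high_hz"]) if row["bp_high_hz"] else None
            events.append(
                EventRecord(
                    label=row["channel"],
                    start_sample=int(row["start_sample"]),
                    end_sample=int(row["end_sample"]),
                    type=row["type"],
                    avg_freq=float(row["avg_freq_hz"]),
                    n_cycles=float(row["n_cycles"]),
                    peak_zscore=(
                        float(row["peak_zscore"]) if row["peak_zscore"] else None
                    ),
                    bp_freq=(low, high) if low is not None else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise EventTableParseError(f"{p}: line {lineno}: {exc}") from exc
    return events


def write_summary(
    events: Iterable[EventRecord],
    labels: Sequence[str],
    path: str | Path,
    srate: float,
) -> Path:
    """Write the per-channel summary: event counts and total durations.

    One row per channel (including channels with no events), with the count
    and the summed duration in seconds of each of the five event types plus
    totals.
    """
    p = Path(path)
    counts = {lab: {t: 0 for t in EVENT_TYPES} for lab in labels}
    durs = {lab: {t: 0.0 for t in EVENT_TYPES} for lab in labels}
    for ev in events:
        if ev.label not in counts:
            counts[ev.label] = {t: 0 for t in EVENT_TYPES}
            durs[ev.label] = {t: 0.0 for t in EVENT_TYPES}
        counts[ev.label][ev.type] += 1
        durs[ev.label][ev.type] += ev.duration_s(srate)

    cols = ["channel"]
    for t in EVENT_TYPES:
        cols += [f"n_{t}", f"dur_{t}_s"]
    cols += ["n_total", "dur_total_s"]
    lines = ["\t".join(cols)]
    for lab in counts:
        row = [lab]
        for t in EVENT_TYPES:
            row += [str(counts[lab][t]), f"{durs[lab][t]:.4f}"]
        row += [
            str(sum(counts[lab].values())),
            f"{sum(durs[lab].values()):.4f}",
        ]
        lines.append("\t".join(row))
    p.write_text("\n".join(lines) + "\n")
    return p
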