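"""Scoring detected events against ground truth across noise conditions.

Matching is greedy and one-to-one: walking the truth list in start order,
each truth event claims the first unclaimed detected event whose sample
interval overlaps it by at least one sample. From a matching come three
metrics: sensitivity (matched truth over total truth), the false-detection
proportion (unmatched detections over total detections), and the mean
detected-to-true duration ratio over matched pairs. The benchmark sweep
runs one or more detectors over replicate datasets per noise condition and
reports per-condition means with the standard error across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import EventRecord, HilbertConfig
from .detector import detect_channel, ripplelab_hilbert
from .simulator import SimulatedDataset, SimulationConfig, generate_suite

__all__ = [
    "Matching",
    "Scores",
    "RipplelabConfig",
    "match_events",
    "score",
    "run_snr_sweep",
    "write_report",
]


@dataclass
class Matching:
    """Result of matching detected events to truth events.

    ``pairs`` holds (truth_index, detected_index); indices refer to the
    input lists sorted by start sample.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    unmatched_truth: list[int] = field(default_factory=list)
    false_detections: list[int] = field(default_factory=list)


@dataclass
class Scores:
    sensitivity: float
    false_rate: float
    mean_relative_duration: float


def _overlaps(a: EventRecord, b: EventRecord) -> bool:
    return a.start_sample < b.end_sample and b.start_sample < a.end_sample


def match_events(
    detected: Sequence[EventRecord], truth: Sequence[EventRecord]
) -> Matching:
    """Greedy one-to-one matching by >= 1 sample of interval overlap.

    Both lists are processed in start-sample order; each truth event claims
    at most one detected event (the earliest-starting unclaimed one that
    overlaps it). Detected events claimed by no truth event are false
    detections.
    """
    det_order = sorted(range(len(detected)),
                       key=lambda i: detected[i].start_sample)
    truth_order = sorted(range(len(truth)),
                         key=lambda i: truth[i].start_sample)
    used = set()
    m = Matching()
    for ti in truth_order:
        hit = None
        for di in det_order:
            if di in used:
                continue
            if _overlaps(detected[di], truth[ti]):
                hit = di
                break
        if hit is None:
            m.unmatched_truth.append(ti)
        else:
            used.add(hit)
            m.pairs.append((ti, hit))
    m.false_detections = [di for di in det_order if di not in used]
    return m


def score(
    detected: Sequence[EventRecord],
    truth: Sequence[EventRecord],
    matching: Matching | None = None,
) -> Scores:
    """Sensitivity, false-detection proportion, mean relative duration.

    ``false_rate`` is the number of non-truth detections divided by the
    total number of detections (0 when nothing was detected). The relative
    duration averages detected/true duration over matched pairs (NaN when
    nothing matched); durations compare sample counts, so no sampling rate
    is needed.
    """
    if matching is None:
        matching = match_events(detected, truth)
    n_truth = len(truth)
    n_det = len(detected)
    sens = len(matching.pairs) / n_truth if n_truth else 1.0
    false_rate = len(matching.false_detections) / n_det if n_det else 0.0
    if matching.pairs:
        ratios = [
            (detected[di].end_sample - detected[di].start_sample)
            / (truth[ti].end_sample - truth[ti].start_sample)
            for ti, di in matching.pairs
        ]
        rel = float(np.mean(ratios))
    else:
        rel = float("nan")
    return Scores(sens, false_rate, rel)


@dataclass
class RipplelabConfig:
    """Parameters of the single-threshold comparator detector."""

    band: tuple[float, float] = (80.0, 250.0)
    sd_threshold: float = 3.5
    min_duration_ms: float = 10.0
    epoch_length_s: float | str = 600.0
    filter_kind: str = "fir_window"


def _detector_fns(
    hilbert_cfg: HilbertConfig | None,
    ripplelab_cfg: RipplelabConfig | None,
) -> dict[str, Callable[[SimulatedDataset], list[EventRecord]]]:
    fns: dict[str, Callable] = {}
    if hilbert_cfg is not None:
        fns["hilbert"] = lambda ds: detect_channel(
            ds.recording, ds.recording.labels[0], hilbert_cfg
        )
    if ripplelab_cfg is not None:
        c = ripplelab_cfg
        fns["ripplelab"] = lambda ds: ripplelab_hilbert(
            ds.recording.mat[0],
            ds.recording.srate,
            band=c.band,
            sd_threshold=c.sd_threshold,
            min_duration_ms=c.min_duration_ms,
            epoch_length_s=c.epoch_length_s,
            filter_kind=c.filter_kind,
            label=ds.recording.labels[0],
        )
    return fns


def run_snr_sweep(
    sim_cfg: SimulationConfig | None = None,
    hilbert_cfg: HilbertConfig | None = None,
    ripplelab_cfg: RipplelabConfig | None = None,
    replicates: int = 10,
    conditions: list[float | None] | None = None,
) -> pd.DataFrame:
    """Benchmark detectors over the simulated suite.

    Defaults run both the two-threshold detector (onset 1 SD, inclusion
    5 SD, 2.4 cycles, 80-250 Hz, 600 s epochs) and the single-threshold
    comparator (3.5 SD, 10 ms) over 11 conditions x ``replicates``
    datasets. Returns one row per (condition, detector) with the mean and
    standard error of each metric across replicate datasets.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    if hilbert_cfg is None and ripplelab_cfg is None:
        hilbert_cfg = HilbertConfig()
        ripplelab_cfg = RipplelabConfig()
    fns = _detector_fns(hilbert_cfg, ripplelab_cfg)

    rows: dict[tuple[str, str], dict[str, list[float]]] = {}
    for ds in generate_suite(sim_cfg, replicates=replicates,
                             conditions=conditions):
        for name, fn in fns.items():
            sc = score(fn(ds), ds.truth)
            acc = rows.setdefault(
                (ds.condition, name),
                {"sensitivity": [], "false_rate": [], "rel_duration": []},
            )
            acc["sensitivity"].append(sc.sensitivity)
            acc["false_rate"].append(sc.false_rate)
            acc["rel_duration"].append(sc.mean_relative_duration)

    records = []
    for (cond, name), acc in rows.items():
        rec = {"condition": cond, "detector": name,
               "n_datasets": len(acc["sensitivity"])}
        for metric, vals in acc.items():
            arr = np.asarray(vals, dtype=float)
            rec[metric] = float(np.nanmean(arr))
            n = np.sum(np.isfinite(arr))
            rec[f"{metric}_se"] = (
                float(np.nanstd(arr, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_report(table: pd.DataFrame, path) -> None:
    """Write the sweep table as a tab-separated report."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
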