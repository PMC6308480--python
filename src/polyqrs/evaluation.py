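"""Delineation-error evaluation against reference annotations.

The protocol mirrors the standard QT-DB practice: per record, each reference
fiducial is matched to the nearest detection of the same label within a
window; signed errors (detected minus reference, ms, negative = early) are
summarised per record by mean and sample standard deviation, and database
aggregates are *unweighted* means of the per-record values. Stability is
judged against the CSE inter-expert tolerances on the aggregate standard
deviation: 6.5 ms for the QRS onset and 11.6 ms for the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducial import FiducialPoints
from .io import QON, SOFF, AnnotationSet

__all__ = [
    "TOLERANCE_ONSET_MS",
    "TOLERANCE_OFFSET_MS",
    "RecordError",
    "ErrorStats",
    "beat_errors",
    "record_stats",
    "aggregate",
    "best_channel",
    "section_stats",
    "check_tolerance",
    "evaluate_records",
]

#: CSE working-party tolerances on the aggregate error standard deviation.
TOLERANCE_ONSET_MS = 6.5
TOLERANCE_OFFSET_MS = 11.6


def beat_errors(detected: AnnotationSet, reference: AnnotationSet, fs: float,
                label: str, match_window_ms: float = 150.0
                ) -> tuple[np.ndarray, int]:
    """Signed errors (ms) of the detections nearest each reference fiducial.

    Returns ``(errors, n_unmatched)``: references with no same-label
    detection within the window are counted, not scored. Negative errors
    mean the detection is early.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    ref = reference.samples(label)
    det = detected.samples(label)
    errors = []
    unmatched = 0
    win = match_window_ms / 1000.0 * fs
    for r in ref:
        if det.size == 0:
            unmatched += 1
            continue
        j = int(np.argmin(np.abs(det - r)))
        if abs(det[j] - r) <= win:
            errors.append((det[j] - r) * 1000.0 / fs)
        else:
            unmatched += 1
    return np.array(errors, dtype=float), unmatched


def record_stats(errors) -> tuple[float, float]:
    """Intra-record mean and sample standard deviation (n-1 denominator) of
    a list of errors in ms; the sd is NaN when fewer than two errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        return float("nan"), float("nan")
    mean = float(errors.mean())
    sd = float(errors.std(ddof=1)) if errors.size >= 2 else float("nan")
    return mean, sd


def aggregate(per_record) -> tuple[float, float]:
    """Unweighted means of per-record ``(mean, sd)`` pairs — each record
    counts once regardless of how many beats it contains."""
    per_record = list(per_record)
    if not per_record:
        raise ValueError("no records to aggregate")
    mus = [m for m, _ in per_record]
    sds = [s for _, s in per_record]
    return float(np.mean(mus)), float(np.mean(sds))


@dataclass
class RecordError:
    """Per-record error summary for one fiducial label."""

    record_id: str
    n_matched: int
    mean_ms: float
    sd_ms: float


@dataclass
class ErrorStats:
    """Per-record and aggregate delineation errors for onset and offset."""

    onset: list[RecordError] = field(default_factory=list)
    offset: list[RecordError] = field(default_factory=list)
    tolerance_onset_ms: float = TOLERANCE_ONSET_MS
    tolerance_offset_ms: float = TOLERANCE_OFFSET_MS

    def aggregate_onset(self) -> tuple[float, float]:
        return aggregate([(r.mean_ms, r.sd_ms) for r in self.onset])

    def aggregate_offset(self) -> tuple[float, float]:
        return aggregate([(r.mean_ms, r.sd_ms) for r in self.offset])


def evaluate_records(pairs, fs: float, match_window_ms: float = 150.0) -> ErrorStats:
    """Evaluate ``(record_id, detected, reference)`` triples into ErrorStats."""
    stats = ErrorStats()
    for rec_id, det, ref in pairs:
        for label, bucket in ((QON, stats.onset), (SOFF, stats.offset)):
            errs, _ = beat_errors(det, ref, fs, label, match_window_ms)
            mean, sd = record_stats(errs)
            bucket.append(RecordError(str(rec_id), int(errs.size), mean, sd))
    return stats


def best_channel(stats_ch1: dict, stats_ch2: dict) -> dict[str, int]:
    """Per-record channel selection by the smaller ``|mean| + sd`` criterion.

    Inputs map record id to ``(mean_ms, sd_ms)``; ties and records present
    in only one channel resolve to that/first channel (0 or 1).
    """
    choice: dict[str, int] = {}
    for rec in sorted(set(stats_ch1) | set(stats_ch2)):
        if rec not in stats_ch2:
            choice[rec] = 0
            continue
        if rec not in stats_ch1:
            choice[rec] = 1
            continue
        m1, s1 = stats_ch1[rec]
        m2, s2 = stats_ch2[rec]
        choice[rec] = 1 if (abs(m2) + s2) < (abs(m1) + s1) else 0
    return choice


def section_stats(fiducials: list[FiducialPoints], fs: float,
                  beat_labels=None, min_count: int = 1) -> dict:
    """Mean and sd (ms) of the QR (onset to R) and RS (R to offset) section
    lengths, grouped by beat label; labels with fewer than ``min_count``
    complete beats are dropped."""
    if beat_labels is None:
        beat_labels = ["all"] * len(fiducials)
    if len(beat_labels) != len(fiducials):
        raise ValueError("one label per beat required")
    groups: dict[str, dict[str, list[float]]] = {}
    for fp, lab in zip(fiducials, beat_labels):
        g = groups.setdefault(str(lab), {"qr": [], "rs": []})
        if fp.q_on is not None:
            g["qr"].append((fp.r_peak - fp.q_on) * 1000.0 / fs)
        if fp.s_off is not None:
            g["rs"].append((fp.s_off - fp.r_peak) * 1000.0 / fs)
    out = {}
    for lab, g in groups.items():
        if min(len(g["qr"]), len(g["rs"])) < min_count:
            continue
        out[lab] = {
            "qr": record_stats(g["qr"]),
            "rs": record_stats(g["rs"]),
            "n": min(len(g["qr"]), len(g["rs"])),
        }
    return out


def check_tolerance(stats: ErrorStats) -> dict[str, bool]:
    """CSE-tolerance verdicts on the aggregate standard deviations
    (boundary inclusive)."""
    _, sd_on = stats.aggregate_onset()
    _, sd_off = stats.aggregate_offset()
    return {
        "onset": bool(sd_on <= stats.tolerance_onset_ms),
        "offset": bool(sd_off <= stats.tolerance_offset_ms),
    }
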