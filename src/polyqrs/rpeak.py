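"""R-peak detection (Pan-Tompkins) and R-R segmentation.

The delineation pipeline treats R-peak detection as a solved prerequisite:
the classic Pan-Tompkins chain (5-15 Hz band-pass, five-point derivative,
squaring, 150 ms moving-window integration, dual adaptive thresholds with
search-back) finds the beats, and each detection is then refined to the
extremum of the absolute band-passed amplitude within +/-50 ms, which makes
the result robust to QRS polarity. Externally supplied R annotations can be
used instead anywhere a peak list is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EcgRecord
from .preprocessing import bandpass

__all__ = ["BeatSegment", "detect_rpeaks", "segment_rr"]

#: Physiological refractory period between QRS complexes.
REFRACTORY_S = 0.200
#: Half-width of the refinement window around each integrator detection.
REFINE_S = 0.050


@dataclass
class BeatSegment:
    """The signal between two consecutive R-peaks (inclusive at both ends)."""

    start_index: int
    end_index: int
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")
        if len(self.samples) != self.end_index - self.start_index + 1:
            raise ValueError("samples length must equal end_index - start_index + 1")

    def __len__(self) -> int:
        return len(self.samples)


def detect_rpeaks(record: EcgRecord, channel: int = 0) -> np.ndarray:
    """Detect R-peaks on one channel; returns strictly increasing sample indices.

    Raises ``ValueError`` for records shorter than the 2 s threshold-learning
    span; a zero-variance channel yields an empty list.
    """
    x = record.channel(channel)
    fs = record.fs
    if len(x) < 2 * fs:
        raise ValueError("record must be at least 2 s long for adaptive thresholding")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    # detection-stage signal chain
    bp = bandpass(x, fs, 5.0, 15.0, order=2)
    deriv = np.convolve(bp, np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0, mode="same")
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integ, distance=max(1, refractory))
    if cand.size == 0:
        return np.array([], dtype=int)

    learn = integ[: int(2 * fs)]
    spki = 0.25 * float(learn.max())
    npki = 0.5 * float(learn.mean())
    thr = npki + 0.25 * (spki - npki)

    qrs: list[int] = []
    noise_peaks: list[int] = []
    rr_hist: list[float] = []
    i = 0
    while i < cand.size:
        p = int(cand[i])
        v = float(integ[p])
        if v > thr and (not qrs or p - qrs[-1] > refractory):
            # search-back: did we skip a beat in an overlong RR interval?
            if qrs and rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                if p - qrs[-1] > 1.66 * rr_avg:
                    back = [c for c in noise_peaks
                            if qrs[-1] + refractory < c < p - refractory
                            and integ[c] > 0.5 * thr]
                    if back:
                        b = max(back, key=lambda c: integ[c])
                        rr_hist.append(b - qrs[-1])
                        qrs.append(int(b))
            if qrs:
                rr_hist.append(p - qrs[-1])
            qrs.append(p)
            spki = 0.125 * v + 0.875 * spki
        else:
            noise_peaks.append(p)
            npki = 0.125 * v + 0.875 * npki
        thr = npki + 0.25 * (spki - npki)
        i += 1

    # refine each integrator detection to the |band-passed| extremum nearby
    half = int(round(REFINE_S * fs))
    refined: list[int] = []
    for p in qrs:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        r = lo + int(np.argmax(np.abs(bp[lo:hi])))
        refined.append(r)
    refined = sorted(set(refined))

    # enforce the refractory period after refinement, keeping the larger peak
    out: list[int] = []
    for r in refined:
        if out and r - out[-1] < refractory:
            if abs(bp[r]) > abs(bp[out[-1]]):
                out[-1] = r
        else:
            out.append(r)
    return np.array(out, dtype=int)


def segment_rr(record: EcgRecord, rpeaks, channel: int = 0) -> list[BeatSegment]:
    """Split one channel into R-R sections; N peaks give N-1 segments that
    share their boundary R samples. Fewer than two peaks give ``[]``."""
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size < 2:
        return []
    x = record.channel(channel)
    segs = []
    for a, b in zip(rpeaks[:-1], rpeaks[1:]):
        segs.append(BeatSegment(int(a), int(b), x[a : b + 1], record.fs))
    return segs
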