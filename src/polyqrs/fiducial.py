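"""QRS onset/offset selection on the cumulative signal.

Every interior vertex of the cumulative staircase within 0.3 s of the
relevant R-peak is scored with three feature families and the argmax wins:

* **amplitude** — cumulative-amplitude distance to the far end of the
  segment, normalised by the maximum over the search set; near the true
  boundary this is close to 1, at intra-QRS vertices (e.g. PVC notches) it
  is small;
* **time** — distance from a reference point 0.3 s away from the R-peak,
  normalised by 0.3 s; discourages drifting onto the P-wave;
* **angles** — the chords to the left/right neighbours should be flat on
  the baseline side and steep on the waveform side. The baseline-side term
  is cos(theta), the waveform-side term sin^2(theta) (strict: the QRS rise
  is steep and rarely distorted). Both exponents are configurable; a
  lenient sqrt(cos) baseline variant is one parameter away, but the linear
  cosine is the default because it is what separates the true boundary
  vertex from the adjacent Q/S trough, whose baseline-side chord is the
  steep trough wall.

The onset of a beat is found in the segment *ending* at its R-peak, the
offset in the segment *starting* at it, so the first beat of a record has
no onset and the last no offset; those are flagged, not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cumulative import CumulativeVertexSet, cumulative_signal
from .io import QON, RPEAK, SOFF, AnnotationSet, EcgRecord
from .polygonal import ApproxParams, approximate
from .preprocessing import bandpass_filter
from .rpeak import detect_rpeaks, segment_rr

__all__ = [
    "FeatureWeights",
    "VertexFeatures",
    "FiducialPoints",
    "DelineationParams",
    "DetectionError",
    "amplitude_features",
    "time_features",
    "vertex_angles",
    "score_candidates",
    "detect_onset",
    "detect_offset",
    "delineate_record",
]


class DetectionError(RuntimeError):
    """No candidate vertex in the search window for one beat side."""


@dataclass
class FeatureWeights:
    """Scoring parameters: the reference window (s) and the exponents of the
    baseline-direction cosine and waveform-direction sine terms."""

    window_s: float = 0.3
    cos_exponent: float = 1.0
    sin_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.cos_exponent <= 0 or self.sin_exponent <= 0:
            raise ValueError("window and exponents must be positive")


@dataclass(frozen=True)
class VertexFeatures:
    """Raw per-vertex feature values (before weighting)."""

    AL: float
    AR: float
    TL: float
    TR: float
    thetaL: float
    thetaR: float


@dataclass
class FiducialPoints:
    """Per-beat delineation result, all indices in record coordinates."""

    beat_index: int
    r_peak: int
    q_on: Optional[int] = None
    s_off: Optional[int] = None
    complete: bool = True
    scores: dict = field(default_factory=dict)


def amplitude_features(cum: CumulativeVertexSet, i: int) -> tuple[float, float]:
    """Cumulative-amplitude distance from the segment's first vertex (AL)
    and to its last (AR); 0-based vertex index."""
    if not 0 <= i < cum.n:
        raise IndexError(f"vertex index {i} out of range")
    al = float(cum.vydp[i] - cum.vydp[0])
    ar = float(cum.vydp[-1] - cum.vydp[i])
    return al, ar


def time_features(cum: CumulativeVertexSet, i: int, fs: float,
                  window_s: float = 0.3) -> tuple[float, float]:
    """Signed sample distances from the reference points ``window_s`` after
    the previous R-peak (TL) and before the next (TR)."""
    if not 0 <= i < cum.n:
        raise IndexError(f"vertex index {i} out of range")
    w = window_s * fs
    tl = float(cum.vx[0] + w - cum.vx[i])
    tr = float(cum.vx[i] - (cum.vx[-1] - w))
    return tl, tr


def vertex_angles(cum: CumulativeVertexSet, i: int, x_scale: float,
                  y_scale: float) -> tuple[float, float]:
    """Angles of the chords to the left/right neighbour vertices against the
    horizontal, on axes rescaled by ``x_scale`` (samples) and ``y_scale``
    (cumulative amplitude). Interior vertices only; both in [0, pi/2]."""
    if not 0 < i < cum.n - 1:
        raise ValueError("angles are defined for interior vertices only")
    if x_scale <= 0 or y_scale <= 0:
        raise ValueError("scales must be positive")

    def ang(j: int) -> float:
        dx = abs(float(cum.vx[i] - cum.vx[j])) / x_scale
        dy = abs(float(cum.vydp[i] - cum.vydp[j])) / y_scale
        return float(np.arctan2(dy, dx))

    return ang(i - 1), ang(i + 1)


def _features(cum: CumulativeVertexSet, idx: np.ndarray, fs: float,
              w: FeatureWeights) -> list[VertexFeatures]:
    # same unit-square aspect as the polygonal stage: chords are judged on
    # the segment rescaled to [0,1] x [0,1], so "flat" and "steep" mean the
    # same thing to the curvature stage and the angle features
    x_scale = float(cum.vx[-1] - cum.vx[0])
    y_scale = cum.total_range or 1.0
    out = []
    for i in idx:
        al, ar = amplitude_features(cum, int(i))
        tl, tr = time_features(cum, int(i), fs, w.window_s)
        thl, thr = vertex_angles(cum, int(i), x_scale, y_scale)
        out.append(VertexFeatures(al, ar, tl, tr, thl, thr))
    return out


def score_candidates(cum: CumulativeVertexSet, fs: float, w: FeatureWeights,
                     side: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Score every candidate vertex for one side.

    ``side`` is ``"onset"`` (searched within ``window_s`` before the
    segment's last vertex, the next R-peak) or ``"offset"`` (within
    ``window_s`` after the first vertex, the previous R-peak). Returns the
    candidate vertex indices and a dict of the four weight terms plus their
    ``total``.
    """
    if cum.n < 3:
        raise DetectionError("segment has no interior vertices")
    win = w.window_s * fs
    interior = np.arange(1, cum.n - 1)
    vx = cum.vx[interior]
    if side == "onset":
        mask = (vx >= cum.vx[-1] - win) & (vx < cum.vx[-1])
    elif side == "offset":
        mask = (vx > cum.vx[0]) & (vx <= cum.vx[0] + win)
    else:
        raise ValueError(f"side must be 'onset' or 'offset', got {side!r}")
    cand = interior[mask]
    if cand.size == 0:
        raise DetectionError(f"no candidate vertex in the {side} search window")
    feats = _features(cum, cand, fs, w)
    if side == "onset":
        A = np.array([f.AR for f in feats])
        T = np.array([f.TR for f in feats])
        th_base = np.array([f.thetaL for f in feats])
        th_wave = np.array([f.thetaR for f in feats])
    else:
        A = np.array([f.AL for f in feats])
        T = np.array([f.TL for f in feats])
        th_base = np.array([f.thetaR for f in feats])
        th_wave = np.array([f.thetaL for f in feats])
    amax = A.max()
    terms = {
        "amplitude": A / amax if amax > 0 else np.zeros_like(A),
        "time": T / win,
        "angle_baseline": np.cos(th_base) ** w.cos_exponent,
        "angle_waveform": np.sin(th_wave) ** w.sin_exponent,
    }
    terms["total"] = terms["amplitude"] + terms["time"] + terms["angle_baseline"] + terms["angle_waveform"]
    return cand, terms


def _argmax_tiebreak(cand: np.ndarray, total: np.ndarray, side: str) -> int:
    best = total.max()
    tied = cand[np.isclose(total, best, rtol=0.0, atol=0.0)]
    # ties resolve toward the R-peak: latest candidate for the onset (next R
    # is on the right), earliest for the offset
    return int(tied[-1] if side == "onset" else tied[0])


def detect_onset(cum: CumulativeVertexSet, fs: float,
                 w: FeatureWeights | None = None) -> int:
    """Index (into ``cum``) of the QRS-onset vertex of the beat at the
    segment's right R-peak."""
    w = w or FeatureWeights()
    cand, terms = score_candidates(cum, fs, w, "onset")
    return _argmax_tiebreak(cand, terms["total"], "onset")


def detect_offset(cum: CumulativeVertexSet, fs: float,
                  w: FeatureWeights | None = None) -> int:
    """Index (into ``cum``) of the QRS-offset vertex of the beat at the
    segment's left R-peak."""
    w = w or FeatureWeights()
    cand, terms = score_candidates(cum, fs, w, "offset")
    return _argmax_tiebreak(cand, terms["total"], "offset")


@dataclass
class DelineationParams:
    """Everything the full pipeline needs."""

    channel: int = 0
    apply_filter: bool = True
    bp_low_hz: float = 1.0
    bp_high_hz: float = 25.0
    bp_order: int = 2
    approx: ApproxParams = field(default_factory=ApproxParams)
    weights: FeatureWeights = field(default_factory=FeatureWeights)
    rpeaks: Optional[np.ndarray] = None  # bypass detection when given
    diagnostics: bool = False


def delineate_record(record: EcgRecord,
                     params: DelineationParams | None = None
                     ) -> tuple[list[FiducialPoints], AnnotationSet]:
    """Run the full pipeline on one channel of a record.

    Returns one :class:`FiducialPoints` per detected beat plus the combined
    annotation set. Beats whose onset- or offset-side segment is missing or
    fails detection are flagged ``complete=False``.
    """
    params = params or DelineationParams()
    work = record
    if params.apply_filter:
        work = bandpass_filter(record, params.bp_low_hz, params.bp_high_hz,
                               params.bp_order)
    if params.rpeaks is not None:
        rp = np.asarray(params.rpeaks, dtype=int)
    else:
        rp = detect_rpeaks(work, params.channel)
    if rp.size == 0:
        import warnings

        warnings.warn("no R-peaks detected; empty delineation", stacklevel=2)
        return [], AnnotationSet([])

    segments = segment_rr(work, rp, params.channel)
    onsets: dict[int, int] = {}
    offsets: dict[int, int] = {}
    diag: dict[int, dict] = {}
    for si, seg in enumerate(segments):
        try:
            verts = approximate(seg, params.approx)
            cum = cumulative_signal(verts)
        except (ValueError, DetectionError):
            continue
        try:
            cand, terms = score_candidates(cum, seg.fs, params.weights, "offset")
            vi = _argmax_tiebreak(cand, terms["total"], "offset")
            offsets[si] = seg.start_index + int(cum.vx[vi])
            if params.diagnostics:
                diag.setdefault(si, {})["offset"] = (cum.vx[cand] + seg.start_index, terms)  # beat si
        except DetectionError:
            pass
        try:
            cand, terms = score_candidates(cum, seg.fs, params.weights, "onset")
            vi = _argmax_tiebreak(cand, terms["total"], "onset")
            onsets[si + 1] = seg.start_index + int(cum.vx[vi])
            if params.diagnostics:
                diag.setdefault(si + 1, {})["onset"] = (cum.vx[cand] + seg.start_index, terms)
        except DetectionError:
            pass

    beats: list[FiducialPoints] = []
    entries: list[tuple[int, str]] = []
    for bi, r in enumerate(rp):
        q = onsets.get(bi)
        s = offsets.get(bi)
        fp = FiducialPoints(beat_index=bi, r_peak=int(r), q_on=q, s_off=s,
                            complete=(q is not None and s is not None))
        if params.diagnostics:
            fp.scores = {k: v for k, v in diag.get(bi, {}).items()}
        beats.append(fp)
        entries.append((int(r), RPEAK))
        if q is not None:
            entries.append((q, QON))
        if s is not None:
            entries.append((s, SOFF))
    return beats, AnnotationSet(entries)
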