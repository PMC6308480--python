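"""Synthetic ECG records with exact fiducial ground truth.

Beats are sums of compact-support Gaussian deflections, one per wave
(P, Q, R, S, T). Each deflection is truncated at +/-3 sigma with its small
residual pedestal removed, so the wave is continuous and *exactly* zero
outside its support: the boundary between waveform and baseline — the very
thing a delineator estimates — is then an exact sample index, not a
convention about where a tail "effectively" ends. Ground truth is

* ``q_on``  = support start of the earliest included QRS deflection,
* ``r_peak`` = the R centre,
* ``s_off`` = support end of the latest included QRS deflection,

with centres and support radii snapped to the sample grid. Morphology
variants cover the shapes a delineator must survive: missing Q or S,
inverted (downward-QRS) beats, PVC-like widening and intra-QRS notches.

Noise emulates the standard taxonomy: respiratory baseline wander
(0.15-0.3 Hz sinusoid), 50/60 Hz powerline interference and broadband
Gaussian noise. Noise never moves the ground truth. What the generator does
*not* emulate: heart-rate variability, respiration-modulated amplitudes and
electrode-motion spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import QON, RPEAK, SOFF, AnnotationSet, EcgRecord

__all__ = [
    "Wave",
    "BeatSpec",
    "NoiseSpec",
    "generate_beat",
    "generate_record",
    "add_noise",
    "morphology_spec",
    "simulate",
    "NOISE_PRESETS",
]


@dataclass(frozen=True)
class Wave:
    """One deflection: centre offset from the R-peak (s), Gaussian sigma (s)
    and signed amplitude (mV)."""

    center_s: float
    sigma_s: float
    amp_mv: float


@dataclass
class BeatSpec:
    """Morphology of one beat.

    ``widened`` scales the centres and widths of the QRS deflections
    (PVC-like); ``extra`` deflections (e.g. an intra-QRS notch) are given in
    final time and do not enter the ground truth, which is defined by the
    primary QRS deflections only.
    """

    p: Wave = Wave(-0.20, 0.025, 0.15)
    q: Wave = Wave(-0.025, 0.004, -0.15)
    r: Wave = Wave(0.0, 0.010, 1.0)
    s: Wave = Wave(0.030, 0.005, -0.25)
    t: Wave = Wave(0.30, 0.055, 0.35)
    polarity: str = "upright"
    include_p: bool = True
    include_q: bool = True
    include_s: bool = True
    include_t: bool = True
    widened: float = 1.0
    extra: list[Wave] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.widened < 1.0:
            raise ValueError("widened factor must be >= 1")
        if self.polarity not in ("upright", "inverted"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        qrs_amp = [abs(w.amp_mv) for w, inc in
                   ((self.q, self.include_q), (self.s, self.include_s)) if inc]
        if any(a >= abs(self.r.amp_mv) for a in qrs_amp):
            raise ValueError("R amplitude must be strictly largest in the QRS")
        for w in (self.p, self.q, self.r, self.s, self.t, *self.extra):
            if w.sigma_s <= 0:
                raise ValueError("wave widths must be positive")

    def waves(self) -> list[Wave]:
        """All deflections in final (widened) time."""
        out = []
        if self.include_p:
            out.append(self.p)
        for w, inc in ((self.q, self.include_q), (self.r, True),
                       (self.s, self.include_s)):
            if inc:
                out.append(Wave(w.center_s * self.widened,
                                w.sigma_s * self.widened, w.amp_mv))
        if self.include_t:
            out.append(self.t)
        out.extend(self.extra)
        return out

    def qrs_waves(self) -> list[Wave]:
        out = []
        for w, inc in ((self.q, self.include_q), (self.r, True),
                       (self.s, self.include_s)):
            if inc:
                out.append(Wave(w.center_s * self.widened,
                                w.sigma_s * self.widened, w.amp_mv))
        return out


_PEDESTAL = math.exp(-4.5)  # Gaussian value at 3 sigma


def _snapped(w: Wave, fs: float) -> tuple[int, int]:
    """(centre, support radius) of a wave in samples."""
    c = int(round(w.center_s * fs))
    r = max(1, int(round(3.0 * w.sigma_s * fs)))
    return c, r


def _render(w: Wave, fs: float, out: np.ndarray, origin: int) -> None:
    """Add one truncated Gaussian to ``out`` (R-peak at index ``origin``)."""
    c, r = _snapped(w, fs)
    lo = max(0, origin + c - r)
    hi = min(len(out), origin + c + r + 1)
    d = np.arange(lo - origin - c, hi - origin - c, dtype=float)
    sigma = r / 3.0
    g = (np.exp(-0.5 * (d / sigma) ** 2) - _PEDESTAL) / (1.0 - _PEDESTAL)
    out[lo:hi] += w.amp_mv * g


def _truth_offsets(spec: BeatSpec, fs: float) -> tuple[int, int, int]:
    """(q_on, r_peak, s_off) sample offsets relative to the R centre."""
    qrs = spec.qrs_waves()
    starts = [_snapped(w, fs)[0] - _snapped(w, fs)[1] for w in qrs]
    ends = [_snapped(w, fs)[0] + _snapped(w, fs)[1] for w in qrs]
    return min(starts), 0, max(ends)


def generate_beat(spec: BeatSpec, fs: float) -> tuple[np.ndarray, dict[str, int]]:
    """Render one beat; returns samples spanning exactly the beat support and
    the ground-truth offsets (into the returned array)."""
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    waves = spec.waves()
    snaps = [_snapped(w, fs) for w in waves]
    lo = min(c - r for c, r in snaps)
    hi = max(c + r for c, r in snaps)
    out = np.zeros(hi - lo + 1)
    for w in waves:
        _render(w, fs, out, origin=-lo)
    if spec.polarity == "inverted":
        out = -out
    q_on, _, s_off = _truth_offsets(spec, fs)
    truth = {"q_on": q_on - lo, "r_peak": -lo, "s_off": s_off - lo}
    return out, truth


@dataclass
class NoiseSpec:
    """Additive noise: baseline-wander and powerline sinusoids (random
    phase) plus white Gaussian noise. All amplitudes in mV; zero = clean."""

    baseline_freq: float = 0.25
    baseline_amp: float = 0.0
    powerline_freq: float = 60.0
    powerline_amp: float = 0.0
    white_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")


def add_noise(samples: np.ndarray, fs: float, noise: NoiseSpec) -> np.ndarray:
    """Return ``samples`` plus the configured noise; reproducible per seed."""
    x = np.asarray(samples, dtype=float).copy()
    rng = np.random.default_rng(noise.seed)
    t = np.arange(len(x)) / fs
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    if noise.baseline_amp > 0:
        x += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t + ph1)
    if noise.powerline_amp > 0:
        x += noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t + ph2)
    if noise.white_sd > 0:
        x += rng.normal(0.0, noise.white_sd, size=len(x))
    return x


def generate_record(specs: list[BeatSpec], rr_s: list[float], fs: float,
                    noise: NoiseSpec | None = None
                    ) -> tuple[EcgRecord, AnnotationSet]:
    """Place beats at cumulative R-R positions and add noise.

    ``rr_s`` has one interval per consecutive beat pair. Overlapping beat
    supports raise an error. The returned annotations carry the exact
    Qon/Rpeak/Soff ground truth, which noise never moves.
    """
    if len(rr_s) != len(specs) - 1:
        raise ValueError("need exactly len(specs) - 1 R-R intervals")
    snaps = [[_snapped(w, fs) for w in sp.waves()] for sp in specs]
    lo_ext = [min(c - r for c, r in sn) for sn in snaps]
    hi_ext = [max(c + r for c, r in sn) for sn in snaps]

    r_pos = [-lo_ext[0] + int(round(0.05 * fs))]
    for rr in rr_s:
        r_pos.append(r_pos[-1] + int(round(rr * fs)))
    for i in range(len(specs) - 1):
        if r_pos[i] + hi_ext[i] >= r_pos[i + 1] + lo_ext[i + 1]:
            raise ValueError(f"beats {i} and {i + 1} overlap; increase rr_s[{i}]")
    n = r_pos[-1] + hi_ext[-1] + int(round(0.05 * fs)) + 1

    x = np.zeros(n)
    entries: list[tuple[int, str]] = []
    for sp, r0 in zip(specs, r_pos):
        beat = np.zeros(n)
        for w in sp.waves():
            _render(w, fs, beat, origin=r0)
        x += -beat if sp.polarity == "inverted" else beat
        q_on, _, s_off = _truth_offsets(sp, fs)
        entries.append((r0 + q_on, QON))
        entries.append((r0, RPEAK))
        entries.append((r0 + s_off, SOFF))
    if noise is not None:
        x = add_noise(x, fs, noise)
    rec = EcgRecord(x[:, None], fs, ["SYN"], ["mV"])
    return rec, AnnotationSet(entries)


#: Morphology presets used across tests and examples.
def morphology_spec(kind: str) -> BeatSpec:
    """Named morphology classes: ``normal``, ``no-q``, ``no-s``,
    ``inverted``, ``pvc`` (widened) and ``pvc-notch`` (widened with an
    upward intra-QRS notch between R and S)."""
    if kind == "normal":
        return BeatSpec()
    if kind == "no-q":
        return BeatSpec(include_q=False)
    if kind == "no-s":
        return BeatSpec(include_s=False)
    if kind == "inverted":
        return BeatSpec(polarity="inverted")
    if kind == "pvc":
        return BeatSpec(widened=2.0, include_p=False)
    if kind == "pvc-notch":
        return BeatSpec(widened=2.0, include_p=False,
                        extra=[Wave(0.035, 0.007, 0.45)])
    raise ValueError(f"unknown morphology {kind!r}")


NOISE_PRESETS = {
    "clean": NoiseSpec(),
    # baseline wander at 20% of the R amplitude, 60 Hz mains at 10%,
    # broadband noise at 2% (R amplitude is 1 mV in the default beat)
    "ambulatory": NoiseSpec(baseline_freq=0.25, baseline_amp=0.20,
                            powerline_freq=60.0, powerline_amp=0.10,
                            white_sd=0.02),
}


def simulate(n_beats: int, fs: float = 250.0, morphology: str = "normal",
             rr_s: float = 0.8, noise: NoiseSpec | None = None,
             seed: int = 0) -> tuple[EcgRecord, AnnotationSet]:
    """Convenience wrapper: ``n_beats`` identical beats at a fixed R-R
    interval, with the noise seed derived from ``seed``."""
    spec = morphology_spec(morphology)
    specs = [spec] * n_beats
    if noise is not None:
        noise = replace(noise, seed=seed)
    return generate_record(specs, [rr_s] * (n_beats - 1), fs, noise)
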