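"""The cumulative auxiliary signal.

QRS morphology varies widely: the complex may point up or down and the Q and
S deflections may or may not be present. Accumulating the *absolute*
vertex-to-vertex amplitude change turns every morphology into the same
monotone staircase: flat along the baseline, rising steeply across the QRS.
The onset and offset vertices keep their role as the boundary between the
flat and steep parts, and the transform is exactly invariant under polarity
flips. The signal stays at vertex resolution — every downstream feature is
defined on vertices only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polygonal import VertexSet

__all__ = [
    "CumulativeVertexSet",
    "amplitude_difference",
    "accumulate",
    "cumulative_signal",
]


@dataclass
class CumulativeVertexSet:
    """Vertices of the cumulative signal.

    ``vx`` are the (unchanged) sample positions, ``vyd`` the signed
    vertex-to-vertex amplitude differences (first element 0) and ``vydp``
    their running absolute sum — a non-decreasing sequence starting at 0
    whose last value is the total variation of the vertex amplitudes.
    """

    vx: np.ndarray
    vyd: np.ndarray
    vydp: np.ndarray

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=int)
        self.vyd = np.asarray(self.vyd, dtype=float)
        self.vydp = np.asarray(self.vydp, dtype=float)
        if not (len(self.vx) == len(self.vyd) == len(self.vydp)):
            raise ValueError("vx, vyd, vydp must have equal length")
        if len(self.vx) == 0:
            raise ValueError("empty cumulative vertex set")
        if np.any(np.diff(self.vx) <= 0):
            raise ValueError("vx must be strictly increasing")
        if self.vyd[0] != 0 or self.vydp[0] != 0:
            raise ValueError("first amplitude difference and cumulative value must be 0")
        if np.any(np.diff(self.vydp) < 0):
            raise ValueError("cumulative values must be non-decreasing")

    @property
    def n(self) -> int:
        return len(self.vx)

    @property
    def total_range(self) -> float:
        return float(self.vydp[-1] - self.vydp[0])


def amplitude_difference(verts: VertexSet) -> list[tuple[int, float]]:
    """Per-vertex signed amplitude change from its left neighbour; the first
    vertex gets 0. X-positions are carried through unchanged."""
    if verts.n == 0:
        raise ValueError("empty vertex set")
    ys = verts.ys
    d = np.diff(ys, prepend=ys[0])
    return list(zip((int(x) for x in verts.xs), (float(v) for v in d)))


def accumulate(diffs) -> CumulativeVertexSet:
    """Running sum of absolute amplitude differences."""
    diffs = list(diffs)
    vx = np.array([d[0] for d in diffs], dtype=int)
    vyd = np.array([d[1] for d in diffs], dtype=float)
    if len(vyd) and vyd[0] != 0:
        raise ValueError("first amplitude difference must be 0")
    vydp = np.cumsum(np.abs(vyd))
    return CumulativeVertexSet(vx, vyd, vydp)


def cumulative_signal(verts: VertexSet) -> CumulativeVertexSet:
    """Build the cumulative auxiliary signal from a polygonal vertex set."""
    return accumulate(amplitude_difference(verts))
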