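"""Polygonal approximation of an R-R section.

Each R-R section is reduced to a small ordered vertex set in three stages:

1. *initial vertices* — strict local maxima of a k-cosine curvature measure
   that exceed a threshold (sharp poles such as Q/R/S peaks), plus the two
   bounding R-peaks;
2. *additional vertices* — recursive greedy splitting between consecutive
   initial vertices until every sample lies within a perpendicular-deviation
   tolerance of its covering chord (smooth corners such as the QRS onset,
   which curvature alone can miss);
3. *position optimisation* — per interval, a dynamic program relocates the
   additional vertices to the placement (same count) minimising the total
   squared vertical error of the piecewise-linear reconstruction.

Angles and distances are computed on axis-normalised coordinates: within a
segment, time is rescaled to [0, 1] over the R-R interval and amplitude to
[0, 1] over the segment's amplitude range. This makes ``support_k``-angles,
the curvature threshold (radians) and the deviation tolerance dimensionless
and transferable across sampling rates and gains.

Vertices always lie on the signal: ``vy`` is the sample amplitude at ``vx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rpeak import BeatSegment

__all__ = [
    "Vertex",
    "VertexSet",
    "ApproxParams",
    "curvature",
    "initial_vertices",
    "sequential_approximation",
    "dp_optimize",
    "approximate",
    "reconstruct",
]


@dataclass(frozen=True)
class Vertex:
    """A polygon vertex: sample index within the segment and its amplitude."""

    vx: int
    vy: float


@dataclass
class VertexSet:
    """Strictly x-ordered vertices spanning (part of) a segment."""

    vertices: list[Vertex]

    def __post_init__(self) -> None:
        xs = [v.vx for v in self.vertices]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("vertex x-positions must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)

    def __iter__(self):
        return iter(self.vertices)

    def __getitem__(self, i):
        return self.vertices[i]

    @property
    def xs(self) -> np.ndarray:
        return np.array([v.vx for v in self.vertices], dtype=int)

    @property
    def ys(self) -> np.ndarray:
        return np.array([v.vy for v in self.vertices], dtype=float)


@dataclass
class ApproxParams:
    """Tunables of the three approximation stages.

    ``support_ms`` is the half-support of the curvature angle in
    milliseconds (10 ms by default -- sharper than the narrowest QRS
    feature, a brief Q wave; a wider support cannot resolve such a wave's
    corners and fires off-corner); ``curv_threshold`` is in radians on
    normalised axes;
    ``tolerance`` is the perpendicular-deviation bound as a fraction of the
    segment's amplitude range.
    """

    support_ms: float = 10.0
    curv_threshold: float = 0.15
    tolerance: float = 0.02

    def support_k(self, fs: float) -> int:
        return max(1, int(round(self.support_ms / 1000.0 * fs)))


def _normalized(segment: BeatSegment) -> tuple[np.ndarray, np.ndarray]:
    """Segment coordinates rescaled to the unit square."""
    s = segment.samples
    n = len(s)
    xs = np.arange(n, dtype=float) / max(n - 1, 1)
    rng = float(np.ptp(s))
    ys = (s - s.min()) / (rng if rng > 0 else 1.0)
    return xs, ys


def curvature(segment: BeatSegment, support_k: int) -> np.ndarray:
    """k-cosine curvature: pi minus the interior angle at each sample formed
    by the chords to the samples ``support_k`` away on either side, on
    normalised axes. The first and last ``support_k`` samples get 0."""
    if support_k < 1:
        raise ValueError("support_k must be >= 1")
    n = len(segment)
    if n <= 2 * support_k:
        raise ValueError(f"segment of {n} samples too short for support_k={support_k}")
    xs, ys = _normalized(segment)
    k = support_k
    ax = xs[: n - 2 * k] - xs[k : n - k]
    ay = ys[: n - 2 * k] - ys[k : n - k]
    bx = xs[2 * k :] - xs[k : n - k]
    by = ys[2 * k :] - ys[k : n - k]
    dot = ax * bx + ay * by
    na = np.hypot(ax, ay)
    nb = np.hypot(bx, by)
    cosang = np.clip(dot / (na * nb), -1.0, 1.0)
    out = np.zeros(n)
    out[k : n - k] = np.pi - np.arccos(cosang)
    return out


def initial_vertices(segment: BeatSegment, support_k: int,
                     curv_threshold: float) -> VertexSet:
    """Segment endpoints plus strict local curvature maxima above threshold."""
    c = curvature(segment, support_k)
    n = len(segment)
    idx = [0]
    for i in range(1, n - 1):
        if c[i] > curv_threshold and c[i] > c[i - 1] and c[i] > c[i + 1]:
            idx.append(i)
    if idx[-1] != n - 1:
        idx.append(n - 1)
    s = segment.samples
    return VertexSet([Vertex(i, float(s[i])) for i in idx])


def _perp_dist(xs: np.ndarray, ys: np.ndarray, a: int, b: int) -> np.ndarray:
    """Perpendicular distance of samples a+1..b-1 from the line through a, b
    (normalised coordinates)."""
    x0, y0, x1, y1 = xs[a], ys[a], xs[b], ys[b]
    dx, dy = x1 - x0, y1 - y0
    norm = float(np.hypot(dx, dy))
    xi = xs[a + 1 : b]
    yi = ys[a + 1 : b]
    return np.abs(dy * (xi - x0) - dx * (yi - y0)) / norm


def sequential_approximation(segment: BeatSegment, vA: Vertex, vB: Vertex,
                             tolerance: float) -> VertexSet:
    """Greedy recursive vertex insertion between two vertices.

    While any sample deviates from its covering chord by more than
    ``tolerance`` (perpendicular distance, normalised axes), a vertex is
    inserted at the sample of maximum deviation and both halves are
    revisited. The endpoints are always retained, so the result starts at
    ``vA`` and ends at ``vB``.
    """
    if vB.vx <= vA.vx:
        raise ValueError("vB must lie strictly right of vA")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    xs, ys = _normalized(segment)
    keep: list[int] = [vA.vx, vB.vx]
    stack = [(vA.vx, vB.vx)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        d = _perp_dist(xs, ys, a, b)
        k = int(np.argmax(d))
        if d[k] > tolerance:
            m = a + 1 + k
            keep.append(m)
            stack.append((a, m))
            stack.append((m, b))
    keep = sorted(set(keep))
    s = segment.samples
    return VertexSet([Vertex(i, float(s[i])) for i in keep])


# ---------------------------------------------------------------------------
# dynamic-programming position optimisation
# ---------------------------------------------------------------------------

def _chord_cost_fns(s: np.ndarray):
    """Prefix sums enabling O(1) squared-vertical-error cost of any chord.

    For a chord from sample u to v (inclusive ends), the cost is
    sum_{i=u..v} (s_i - (alpha + beta i))^2 with the line through
    (u, s_u), (v, s_v). Expanding the square leaves only range sums of
    s_i, s_i^2, i*s_i, i and i^2, all available from cumulative sums.
    """
    n = len(s)
    i = np.arange(n, dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(s)])
    cs2 = np.concatenate([[0.0], np.cumsum(s * s)])
    cis = np.concatenate([[0.0], np.cumsum(i * s)])
    ci = np.concatenate([[0.0], np.cumsum(i)])
    ci2 = np.concatenate([[0.0], np.cumsum(i * i)])

    def cost(u: np.ndarray, v: int) -> np.ndarray:
        u = np.asarray(u, dtype=int)
        beta = (s[v] - s[u]) / (v - u)
        alpha = s[u] - beta * u
        S = cs[v + 1] - cs[u]
        S2 = cs2[v + 1] - cs2[u]
        IS = cis[v + 1] - cis[u]
        I = ci[v + 1] - ci[u]
        I2 = ci2[v + 1] - ci2[u]
        cnt = (v - u + 1).astype(float) if u.ndim else float(v - u + 1)
        return (S2 - 2 * alpha * S - 2 * beta * IS
                + alpha * alpha * cnt + 2 * alpha * beta * I + beta * beta * I2)

    return cost


def dp_optimize(segment: BeatSegment, verts: VertexSet) -> VertexSet:
    """Relocate interior vertices to the least-squares optimal positions.

    The endpoints are fixed; the ``m = n - 2`` interior vertices are moved
    (keeping their count and strict ordering) to minimise the total squared
    vertical error between the piecewise-linear reconstruction and the
    signal over the spanned range. Exact via dynamic programming; equal-cost
    placements resolve deterministically to the leftmost configuration.
    """
    m = verts.n - 2
    if m < 0:
        raise ValueError("vertex set must contain at least the two endpoints")
    if m == 0:
        return verts
    a, b = int(verts[0].vx), int(verts[-1].vx)
    s = segment.samples[a : b + 1]
    n = len(s)
    if m > n - 2:
        raise ValueError("more interior vertices than interior samples")
    cost = _chord_cost_fns(s)

    big = np.inf
    positions = np.arange(n)
    # D[v] = best cost of covering [0, v] with the current number of chords
    D = np.full(n, big)
    for v in range(1, n):
        D[v] = float(cost(np.array([0]), v)[0])
    parent = np.zeros((m + 1, n), dtype=int)
    for j in range(1, m + 1):
        D_next = np.full(n, big)
        for v in range(j + 1, n):
            us = positions[j:v]
            tot = D[us] + cost(us, v)
            k = int(np.argmin(tot))  # first minimum -> leftmost predecessor
            D_next[v] = float(tot[k])
            parent[j, v] = int(us[k])
        D = D_next
    # backtrack from the fixed right endpoint
    path = []
    v = n - 1
    for j in range(m, 0, -1):
        v = int(parent[j, v])
        path.append(v)
    path.reverse()
    idx = [0] + path + [n - 1]
    return VertexSet([Vertex(a + i, float(segment.samples[a + i])) for i in idx])


def approximate(segment: BeatSegment, params: ApproxParams | None = None) -> VertexSet:
    """Full three-stage polygonal approximation of one R-R section."""
    params = params or ApproxParams()
    k = params.support_k(segment.fs)
    iv = initial_vertices(segment, k, params.curv_threshold)
    merged: list[Vertex] = [iv[0]]
    for va, vb in zip(iv.vertices[:-1], iv.vertices[1:]):
        seq = sequential_approximation(segment, va, vb, params.tolerance)
        opt = dp_optimize(segment, seq)
        merged.extend(opt.vertices[1:])
    return VertexSet(merged)


def reconstruct(verts: VertexSet, length: int) -> np.ndarray:
    """Piecewise-linear reconstruction of a vertex set over ``length`` samples."""
    if verts.n < 2 or verts[0].vx != 0 or verts[-1].vx != length - 1:
        raise ValueError(f"vertex set must span [0, {length - 1}]")
    return np.interp(np.arange(length), verts.xs, verts.ys)
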