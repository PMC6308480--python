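"""Polygonal approximation: curvature, vertex insertion, DP optimisation.

Each stage is checked against an independent brute-force oracle: a direct
per-sample angle computation for the curvature, a per-sample point-to-chord
distance scan for the deviation bound, and exhaustive enumeration of interior
placements for the dynamic program.
"""

import itertools

import numpy as np
import pytest

from polyqrs.polygonal import (
    ApproxParams,
    Vertex,
    VertexSet,
    approximate,
    curvature,
    dp_optimize,
    initial_vertices,
    reconstruct,
    sequential_approximation,
)

from conftest import make_segment


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def norm_coords(samples):
    s = np.asarray(samples, dtype=float)
    xs = np.arange(len(s)) / (len(s) - 1)
    rng = np.ptp(s)
    ys = (s - s.min()) / (rng if rng > 0 else 1.0)
    return xs, ys


def oracle_curvature(samples, k):
    """pi minus the angle at each sample, computed point by point."""
    xs, ys = norm_coords(samples)
    n = len(xs)
    out = np.zeros(n)
    for i in range(k, n - k):
        a = np.array([xs[i - k] - xs[i], ys[i - k] - ys[i]])
        b = np.array([xs[i + k] - xs[i], ys[i + k] - ys[i]])
        c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        out[i] = np.pi - np.arccos(np.clip(c, -1, 1))
    return out


def oracle_max_deviation(samples, vxs):
    """Max perpendicular distance of any sample from its covering chord."""
    xs, ys = norm_coords(samples)
    worst = 0.0
    for a, b in zip(vxs[:-1], vxs[1:]):
        dx, dy = xs[b] - xs[a], ys[b] - ys[a]
        norm = np.hypot(dx, dy)
        for i in range(a + 1, b):
            d = abs(dy * (xs[i] - xs[a]) - dx * (ys[i] - ys[a])) / norm
            worst = max(worst, d)
    return worst


def oracle_sse(samples, vxs):
    """Total squared vertical error of the piecewise-linear reconstruction."""
    s = np.asarray(samples, dtype=float)
    recon = np.interp(np.arange(vxs[0], vxs[-1] + 1), vxs, s[np.asarray(vxs)])
    return float(np.sum((recon - s[vxs[0] : vxs[-1] + 1]) ** 2))


def oracle_best_sse(samples, a, b, m):
    """Exhaustive enumeration over all interior placements."""
    best = np.inf
    for combo in itertools.combinations(range(a + 1, b), m):
        best = min(best, oracle_sse(samples, [a, *combo, b]))
    return best


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("slope", [0.0, 1.0, -2.5])
def test_curvature_straight_line_is_zero(slope):
    seg = make_segment(slope * np.arange(20.0) + 3.0)
    c = curvature(seg, support_k=2)
    assert np.all(c < 1e-9)


def test_curvature_triangle_apex_is_max():
    s = np.concatenate([np.zeros(6), [1, 2, 3, 2, 1], np.zeros(6)])
    seg = make_segment(s)
    c = curvature(seg, support_k=2)
    assert np.argmax(c) == 8  # the apex


def test_curvature_matches_bruteforce_oracle(rng):
    s = rng.normal(size=15)
    seg = make_segment(s)
    for k in (1, 2, 3):
        np.testing.assert_allclose(curvature(seg, k), oracle_curvature(s, k),
                                   atol=1e-12)


def test_curvature_range_and_boundaries(rng):
    s = rng.normal(size=40)
    c = curvature(make_segment(s), 3)
    assert np.all((c >= 0) & (c <= np.pi))
    assert np.all(c[:3] == 0) and np.all(c[-3:] == 0)


def test_curvature_too_short_segment_raises():
    with pytest.raises(ValueError):
        curvature(make_segment(np.zeros(5)), support_k=3)


# ---------------------------------------------------------------------------
# initial vertices
# ---------------------------------------------------------------------------

def test_initial_vertices_straight_line_endpoints_only():
    seg = make_segment(np.linspace(0, 5, 30))
    vs = initial_vertices(seg, 2, 0.15)
    assert list(vs.xs) == [0, 29]


def test_initial_vertices_triangle_pulse():
    # flat baseline, linear rise, linear fall, flat baseline: the apex and
    # the two baseline corners are curvature maxima -> 5 vertices total
    s = np.concatenate([np.zeros(8), np.arange(1, 6), [6.0], np.arange(5, 0, -1),
                        np.zeros(8)])
    seg = make_segment(s)
    vs = initial_vertices(seg, 1, 0.15)
    oracle = oracle_curvature(s, 1)
    expect = [0] + [i for i in range(1, len(s) - 1)
                    if oracle[i] > 0.15 and oracle[i] > oracle[i - 1]
                    and oracle[i] > oracle[i + 1]] + [len(s) - 1]
    assert list(vs.xs) == sorted(set(expect))
    assert 13 in vs.xs          # the apex
    assert len(vs) == 5


def test_initial_vertices_unreachable_threshold():
    s = np.sin(np.linspace(0, 6, 50))
    vs = initial_vertices(make_segment(s), 2, np.pi)
    assert list(vs.xs) == [0, 49]


def test_vertices_lie_on_signal(rng):
    s = rng.normal(size=60)
    seg = make_segment(s)
    for v in approximate(seg, ApproxParams(support_ms=10, tolerance=0.05)):
        assert v.vy == s[v.vx]


# ---------------------------------------------------------------------------
# sequential approximation
# ---------------------------------------------------------------------------

def _endpoints(seg):
    s = seg.samples
    return Vertex(0, float(s[0])), Vertex(len(s) - 1, float(s[-1]))


def test_sequential_linear_signal_no_insertions():
    seg = make_segment(np.linspace(-1, 2, 25))
    va, vb = _endpoints(seg)
    vs = sequential_approximation(seg, va, vb, 0.02)
    assert list(vs.xs) == [0, 24]


def test_sequential_single_spike_one_vertex():
    s = np.linspace(0, 1, 21)
    s[10] += 0.4  # far above any reasonable tolerance
    seg = make_segment(s)
    va, vb = _endpoints(seg)
    vs = sequential_approximation(seg, va, vb, 0.1)
    assert 10 in vs.xs
    assert oracle_max_deviation(s, list(vs.xs)) <= 0.1


@pytest.mark.parametrize("trial", range(10))
def test_sequential_deviation_bound_random(rng, trial):
    s = np.random.default_rng(500 + trial).normal(size=40).cumsum()
    seg = make_segment(s)
    va, vb = _endpoints(seg)
    tol = 0.05
    vs = sequential_approximation(seg, va, vb, tol)
    assert vs[0].vx == 0 and vs[-1].vx == 39
    assert oracle_max_deviation(s, list(vs.xs)) <= tol + 1e-12


def test_sequential_bad_order_raises():
    seg = make_segment(np.arange(10.0))
    with pytest.raises(ValueError):
        sequential_approximation(seg, Vertex(5, 5.0), Vertex(2, 2.0), 0.02)


# ---------------------------------------------------------------------------
# dynamic-programming optimisation
# ---------------------------------------------------------------------------

def test_dp_no_interior_is_identity(rng):
    s = rng.normal(size=20)
    seg = make_segment(s)
    vs = VertexSet([Vertex(0, s[0]), Vertex(19, s[19])])
    assert dp_optimize(seg, vs) is vs


def test_dp_recovers_true_breakpoint():
    # piecewise-linear signal with a single breakpoint at 12
    s = np.concatenate([np.linspace(0, 6, 13), np.linspace(6, 0, 13)[1:]])
    seg = make_segment(s)
    vs = VertexSet([Vertex(0, s[0]), Vertex(5, s[5]), Vertex(24, s[24])])
    opt = dp_optimize(seg, vs)
    assert list(opt.xs) == [0, 12, 24]
    assert oracle_sse(s, list(opt.xs)) < 1e-18


@pytest.mark.parametrize("trial", range(10))
def test_dp_matches_exhaustive_enumeration(trial):
    rng = np.random.default_rng(900 + trial)
    s = rng.normal(size=25).cumsum()
    seg = make_segment(s)
    inner = sorted(rng.choice(np.arange(1, 24), size=2, replace=False))
    vs = VertexSet([Vertex(0, s[0])] + [Vertex(int(i), s[i]) for i in inner]
                   + [Vertex(24, s[24])])
    opt = dp_optimize(seg, vs)
    assert opt[0].vx == 0 and opt[-1].vx == 24
    np.testing.assert_allclose(oracle_sse(s, list(opt.xs)),
                               oracle_best_sse(s, 0, 24, 2), rtol=1e-12)


def test_dp_never_increases_error(rng):
    for _ in range(5):
        s = rng.normal(size=30).cumsum()
        seg = make_segment(s)
        inner = sorted(rng.choice(np.arange(1, 29), size=3, replace=False))
        vs = VertexSet([Vertex(0, s[0])] + [Vertex(int(i), s[i]) for i in inner]
                       + [Vertex(29, s[29])])
        assert oracle_sse(s, list(dp_optimize(seg, vs).xs)) <= oracle_sse(
            s, list(vs.xs)) + 1e-12


# ---------------------------------------------------------------------------
# full approximation and reconstruction
# ---------------------------------------------------------------------------

def test_approximate_straight_line_two_vertices():
    seg = make_segment(np.linspace(0, 3, 40))
    assert approximate(seg).n == 2


def test_approximate_vertex_count_monotone_in_tolerance(rng):
    s = rng.normal(size=120).cumsum()
    seg = make_segment(s)
    counts = [approximate(seg, ApproxParams(tolerance=t)).n
              for t in (0.01, 0.02, 0.05, 0.1)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_approximate_polarity_flip_same_x_positions(rng):
    s = rng.normal(size=100).cumsum()
    up = approximate(make_segment(s))
    dn = approximate(make_segment(-s))
    assert list(up.xs) == list(dn.xs)
    np.testing.assert_allclose(up.ys, -dn.ys)


def test_reconstruct_examples():
    vs = VertexSet([Vertex(0, 0.0), Vertex(4, 4.0)])
    np.testing.assert_allclose(reconstruct(vs, 5), [0, 1, 2, 3, 4])


def test_reconstruct_exact_at_vertices(rng):
    s = rng.normal(size=50)
    seg = make_segment(s)
    vs = approximate(seg, ApproxParams(tolerance=0.05))
    recon = reconstruct(vs, 50)
    for v in vs:
        assert recon[v.vx] == v.vy


def test_reconstruct_span_mismatch_raises():
    vs = VertexSet([Vertex(0, 0.0), Vertex(4, 4.0)])
    with pytest.raises(ValueError):
        reconstruct(vs, 10)


def test_reconstruct_after_approximate_within_tolerance():
    # clean smooth signals: the deviation bound survives the DP stage
    t = np.linspace(0, 2 * np.pi, 150)
    s = np.sin(t) + 0.3 * np.sin(3 * t)
    seg = make_segment(s)
    tol = 0.02
    vs = approximate(seg, ApproxParams(tolerance=tol))
    assert oracle_max_deviation(s, list(vs.xs)) <= tol
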