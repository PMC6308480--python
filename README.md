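# polyqrs

QRS-complex onset/offset delineation for ECG signals by curvature-based
polygonal approximation.

## The problem

Automatic ECG analysis needs the *fiducial points* of each heartbeat — the
onset (Qon), peak (R) and offset (Soff) of the QRS complex. R-peaks are easy
(largest amplitude, fast slope); the onset and offset are hard, because near
the waveform/baseline boundary every sample looks like its neighbours, and
thresholds on slope or amplitude are fragile. `polyqrs` addresses this for
researchers and engineers building delineation, beat-classification or
signal-compression pipelines, and ships a synthetic generator with exact
ground truth so every stage is testable without downloading annotated
databases.

## The method

Each R–R section *S* (split at Pan–Tompkins-detected R-peaks) is reduced to
a small vertex set *V* = {v₁,…,v_NV}, vᵢ = (vxᵢ, vyᵢ), in three stages:

1. **curvature seeds** — strict local maxima of the k-cosine curvature
   (π minus the interior angle over a ±10 ms support, on axes normalised to
   the unit square) above 0.15 rad, plus the bounding R-peaks;
2. **greedy insertion** — between consecutive seeds, vertices are inserted
   at the point of maximum perpendicular deviation until every sample is
   within 2% (of the segment's amplitude range) of its covering chord;
3. **DP optimisation** — interior vertex positions are relocated, exactly,
   to the placement minimising the total squared vertical reconstruction
   error (an O(1)-per-chord prefix-sum cost inside an O(m·n²) dynamic
   program).

Because QRS morphology varies (Q/S present or absent, upright or inverted),
scoring operates on the **cumulative signal**: vyᵢᴰ′ = Σ_{k≤i} |vy_k −
vy_{k−1}|, a monotone staircase that is flat on the baseline, steep across
the QRS, and exactly polarity-invariant. Each interior vertex within 0.3 s
of the relevant R-peak is scored with

    onset : ω_A(Aᵢᴿ) + ω_T(Tᵢᴿ) + ω_θC(θᵢᴸ) + ω_θS(θᵢᴿ)
    offset: ω_A(Aᵢᴸ) + ω_T(Tᵢᴸ) + ω_θS(θᵢᴸ) + ω_θC(θᵢᴿ)

where Aᵢ are cumulative-amplitude distances to the segment ends (normalised
by the search-window maximum), Tᵢ are distances from a reference point 0.3 s
from the R-peak (normalised by 0.3 s), θ are chord angles to the neighbour
vertices, ω_θC(θ) = cos θ rewards a flat baseline-side chord and ω_θS(θ) =
sin²θ a steep waveform-side chord. The argmax is the fiducial point.

## Worked example

```
$ python examples/simulate_and_delineate.py
record: 16.0 s at 250 Hz, 20 beats found
Qon: mean error +0.0 ms, sd 0.0 ms, 1 unmatched
Soff: mean error +0.0 ms, sd 0.0 ms, 1 unmatched
mean QR section length: 36 ms (onset to R-peak)
```

On a clean 20-beat synthetic record every detected onset and offset lands on
the generator's ground-truth boundary (error 0 ms); one onset and one offset
go unmatched because the first beat has no preceding segment and the last no
following one. With ambulatory-grade noise
(`examples/evaluate_noisy_record.py`) the aggregate spread stays inside the
CSE inter-expert stability tolerances (6.5 ms onset / 11.6 ms offset):

```
onset :  +3.96 +/-  1.70 ms  (pass vs 6.5 ms)
offset: +10.46 +/-  4.01 ms  (pass vs 11.6 ms)
```

The same pipeline is available as a CLI:

```
polyqrs simulate --beats 20 --out rec.csv --truth truth.csv
polyqrs delineate rec.csv --out detected.csv
polyqrs evaluate --detected detected.csv --reference truth.csv --fs 250 --report report.json
```

## Scope

QRS onset/offset only. P- and T-wave delineation, beat classification and
compression applications are out of scope; evaluation against local copies
of PhysioNet databases (QT-DB-style two-channel records with reference
annotations) is supported through the WFDB reader and the evaluation
harness, but is not required by the test suite.
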