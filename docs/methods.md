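# Methods

This note records the model, the parameter choices and the open design
decisions behind `polyqrs`, in the spirit of a lab notebook for the package.

## Pipeline

```
record → band-pass (1–25 Hz, zero phase) → R-peak detection (Pan–Tompkins)
       → R–R segmentation → polygonal approximation → cumulative signal
       → per-vertex scoring → Qon / Soff per beat
```

The onset of a beat is found in the segment that *ends* at its R-peak, the
offset in the segment that *starts* there. The first beat of a record
therefore has no onset and the last no offset; both are emitted with
`complete=False` rather than dropped.

## Preprocessing

An order-2 Butterworth band-pass (1–25 Hz) applied forward and backward
(`sosfiltfilt`) suppresses respiratory baseline wander (≈0.15–0.3 Hz) and
powerline/muscle noise. Zero phase matters: any group delay would translate
every onset/offset estimate, which is precisely the measured quantity. The
pass band edges are exposed (`bp_low_hz`, `bp_high_hz`, `bp_order`); the
effective magnitude response is the squared single-pass response.

A deliberate consequence: on *clean* signals the 25 Hz cutoff smears the
narrowest deflections (a 4 ms-sigma Q wave has most of its energy above
25 Hz), displacing boundary corners by 1–5 samples at 250 Hz. The clean
synthetic studies therefore run with `apply_filter=False` — there is nothing
to suppress, and the residual bias would measure the filter, not the
delineator. Noisy studies keep the filter on and absorb the smearing within
their 20 ms criterion.

## R-peak detection

Full Pan–Tompkins chain: 5–15 Hz band-pass (detection only), five-point
derivative, squaring, 150 ms moving-window integration, dual adaptive
thresholds with search-back at 1.66× the running RR average, 200 ms
refractory period. Each integrator detection is refined to the extremum of
the absolute band-passed amplitude within ±50 ms, which makes detection
polarity-robust (inverted QRS included). Delineation always runs on the
1–25 Hz signal, never on the detection-stage signal. Externally supplied
R-peak annotations can replace the detector (`DelineationParams.rpeaks`,
CLI `--rpeaks`).

## Polygonal approximation

All angles and distances are computed on the segment normalised to the unit
square (time over the R–R interval, amplitude over the segment range),
making the three parameters dimensionless and transferable across sampling
rates and gains:

* `support_ms = 10` — half-support of the k-cosine curvature. Must be
  sharper than the narrowest modelled feature: a brief Q wave spans ≈24 ms,
  and a 20 ms arm overshoots it, firing at trough-minus-k and freezing a
  misplaced initial vertex (interval endpoints are fixed for the later
  stages).
* `curv_threshold = 0.15` rad — initial vertices are strict local curvature
  maxima above this; endpoints (R-peaks) are always included. No minimum
  separation between maxima is imposed.
* `tolerance = 0.02` — perpendicular-deviation bound of the greedy
  insertion stage (2% of the segment amplitude range). Vertex counts are
  monotone non-increasing in this tolerance, and the detected fiducials are
  stable across a wide tolerance range — the premise that boundaries
  survive as vertices.

The DP stage minimises total squared *vertical* error: vertical (not
perpendicular) error admits an exact O(1) chord cost from prefix sums of
(s, s², i·s, i, i²), giving an O(m·n²) exact optimisation per interval.
Equal-cost placements resolve deterministically (first-minimum backtrack,
leftmost predecessor). The DP can in principle break the insertion stage's
deviation bound; on clean physiological shapes it does not (checked in the
test suite), and the bound itself is only guaranteed at stage 2.

## Cumulative signal and scoring

The cumulative signal is kept at vertex resolution; every downstream
feature is defined on vertices only. Per candidate vertex (interior, within
`window_s = 0.3` s of the relevant R-peak — inside this window the time
feature is non-negative, and 0.3 s comfortably exceeds half of any QRS,
normal width 0.08–0.12 s):

* amplitude: cumulative distance to the far segment end, normalised by the
  search-window maximum, so it attains 1 in each search;
* time: distance from the reference point 0.3 s from the R-peak,
  normalised by 0.3 s — discourages locking onto the P-wave;
* angles: chords to the immediate neighbours, on the same unit-square
  aspect as the approximation stages. **This aspect choice is load-bearing**:
  with a much wider x-scale (e.g. the 0.3 s window), the boundary vertex's
  waveform-side chord looks flat, and the adjacent Q/S trough — whose
  R-side chord is always near-vertical — outscores the true boundary by a
  small, systematic margin (errors of one Q/S half-width). On the segment
  aspect, baseline chords stay near 0° and all intra-QRS chords near 90°,
  which is the geometry the feature design assumes.

Weight exponents: `cos_exponent = 1` (baseline side), `sin_exponent = 2`
(waveform side). A lenient `sqrt(cos)` baseline variant is one parameter
away; it is not the default because the leniency is exactly what lets the
trough vertex win on clean beats — the linear cosine's penalty on the
trough's steep baseline-side chord is the margin that separates the two.
Ties in the total score resolve toward the R-peak (the conservative,
shorter-QRS reading). An empty search window raises a per-beat detection
failure, which the pipeline reports as an incomplete beat, never as a crash.

Polarity and uniform amplitude scaling provably cancel everywhere (absolute
differences, normalised features), and the test suite asserts bit-identical
delineations for s, −s and 3s.

## Synthetic generator

Beats are sums of per-wave Gaussians truncated at ±3σ with the residual
pedestal removed, so each wave is continuous and exactly zero outside its
support. Ground truth is the support boundary of the earliest/latest QRS
deflection — an exact sample index by construction, not a convention about
invisible tails. Default morphology (centre s, σ s, amplitude mV, R-peak
at 0): P(−0.20, 0.025, 0.15), Q(−0.025, 0.004, −0.15), R(0, 0.010, 1.0),
S(0.030, 0.005, −0.25), T(0.30, 0.055, 0.35) — a ≈82 ms QRS with brief Q/S
deflections, clinically ordinary timings. Morphology classes: `normal`,
`no-q`, `no-s`, `inverted` (exact negation, truth unchanged), `pvc`
(QRS centres and widths ×2, no P) and `pvc-notch` (widened plus an upward
intra-QRS bump that receives vertices but never enters the truth).

Noise: baseline sinusoid (default 0.25 Hz), powerline sinusoid (50/60 Hz),
white Gaussian noise; random phases and samples drawn from a seeded
generator, bit-reproducible, and never moving the ground truth. The
`ambulatory` preset uses 20% / 10% / 2% of the R amplitude respectively.

What the generator does **not** emulate: heart-rate variability,
respiration-modulated amplitudes, electrode-motion spikes, ST-segment
shifts, or biphasic/slurred transitions. Passing the synthetic studies
therefore demonstrates correctness of the algorithmic chain under the
stated morphologies and noise types — not clinical performance on
pathological recordings, which requires evaluation against annotated
databases through the WFDB reader.

## Evaluation protocol

Per record and label, each reference fiducial is matched to the nearest
same-label detection within 150 ms (the window must exceed any plausible
delineation error while staying under half the shortest RR); signed errors
are detected−reference in ms. Records are summarised by mean and sample
standard deviation (n−1); database aggregates are unweighted means of the
per-record values, so short records count as much as long ones. Stability
verdicts compare the aggregate σ with the CSE inter-expert tolerances
(6.5 ms onset, 11.6 ms offset), boundary inclusive. Two-channel records are
resolved per record by the smaller |mean| + sd channel, ties to the first
channel. QR/RS section-length statistics group by beat label with a
configurable minimum count (30 is the conventional cut for PAC/PVC
sub-analyses).

## Problem sizes

The test suite and the acceptance script use 50 beats per morphology class
(200 clean + 200 noisy fiducial pairs), 60-beat records for detector
quality, 200 random segments (length ≤ 30, ≤ 3 interior vertices) for the
exhaustive DP cross-check and 101 beats for the vertex-preservation rate;
these sizes give stable percentages while keeping the whole suite in the
seconds range.

## Known limitations

* WFDB support is minimal: single-segment, single-`.dat`, format-16
  records and MIT annotation files; formats 212/80 etc. are not parsed.
* The DP stage optimises within initial-vertex intervals only (interval
  endpoints are fixed by construction); a misplaced curvature seed is not
  recoverable downstream — the reason the curvature support must stay
  below the narrowest feature width.
* On very short R–R intervals (< 0.6 s) the onset and offset search
  windows of adjacent beats overlap the T/P waves, and the time feature's
  pull toward the R-peak grows relatively stronger.
* Aggregate σ on clean synthetic records is 0 by construction (every error
  identical); σ becomes informative only under noise or morphology mixes.
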