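# Methods notes

## Coordinate and unit conventions

All locus and fixation coordinates are retinal degrees with the origin at
the anatomical fovea; `+x` is the temporal retina in right-eye (OD)
convention and `+y` superior. Left-eye exams are handled only through
`normalize_eye`, which mirrors `x → −x` once (idempotent afterwards), so
hemifield pooling is a sign test on `x`. Degrees meet millimetres in exactly
one constant, `MM_PER_DEG = 0.288` (emmetropic retinal scale), used to
convert simulated island ellipse axes to areas in mm².

Sensitivities are dB of stimulus attenuation on a 0–36 dB range (1 dB =
0.1 log-unit of luminance; the stimulus luminance span 0.00064–2.545 cd/m²
is exactly 36.0 dB). Loci where the brightest stimulus is not seen carry
the export sentinel **−1.0 dB**, stored verbatim; every downstream index
branches on it explicitly rather than treating it as a numeric value.

## Test grid

The default scotopic pattern is 1 central locus plus 3 rings × 12 loci.
The device's exact ring radii are unpublished; the default `[1°, 3°, 7°]`
is a configurable choice whose convex hull (a regular 12-gon, area
`½·n·R²·sin(2π/n) = 147 deg²`) makes healthy volume-to-mean sensitivity
ratios come out on the observed scale. Ring loci start on the temporal
axis and run counter-clockwise; construction is deterministic. A
rectilinear 68-point 10-2 variant is provided for mesopic exams.

## Synthetic observer and staircase

The generator exists so that every pipeline stage is testable without
patient data; its defaults are the study conditions and are not tuned per
analysis.

* **Observer**: probability of reporting a stimulus at level `L` with true
  threshold `T` is `fp + (1 − fp − lapse)·Φ((T − L)/σ)`, a standard
  cumulative-Gaussian psychometric model in dB with false-positive and
  lapse mixture (defaults σ = 1.5 dB, fp = 0.03, lapse = 0.01; σ = 0 gives
  the deterministic step observer). For a truly non-seen locus only false
  positives can produce presses.
* **Staircase** (4-2 bracketing): start 18 dB; 4 dB brighter after each
  not-seen, 4 dB dimmer after each seen; the first not-seen→seen reversal
  switches to 2 dB steps; the second such reversal terminates and the last
  seen level is returned. Not seeing 0 dB yields the −1.0 sentinel; seeing
  36 dB terminates at the ceiling. The device's internals (start level,
  reversal count, estimator) are not public; these are configurable
  stand-ins. For a deterministic observer the estimate is the largest even
  level ≤ T, so |measured − true| ≤ 2 dB and all outputs lie on the even-dB
  lattice.
* **Estimator bias**: the last-seen rule reads ≈1.3 dB below the true
  threshold on average, so the cohort prior peak (23.3 dB) sits that much
  above the target surface; *measured* healthy exams then land at a
  realistic scale (mean sensitivity ≈ 20.6 dB, volume ≈ 2950 dB·deg²).

## Sensitivity fields

Healthy: `peak − slope·r` clamped to [0, 36] (defaults peak 22 dB directly,
slope 0.4 dB/deg), with cyan inside the rod-free radius (0.5°) replaced by
a low foveal residual (default 4.0 dB — bright cyan is still visible to
foveal cones, so the healthy central cyan threshold is above zero).
`peak_cyan = peak_red` encodes the CIE-calibration convention: the ~20 dB
radiance offset between colors is absorbed into the per-color dB scale, so
in healthy retina the off-fovea cyan−red difference is 0.0 dB and any
negative difference means relative rod dysfunction.

Choroideremia: the healthy surface minus a color-specific deficit inside a
residual elliptical island centred 1.5° temporally (emulating the temporal
sparing typical of the disease); non-seen outside the island or wherever
the deficit exhausts sensitivity, producing the −1.0-heavy skewed pointwise
distributions of advanced disease. A per-subject severity draw shrinks the
island while growing the red (cone) deficit; the cyan (rod) deficit is
large throughout. This makes red volume sensitivity track island area
strongly while cyan is floored — the mechanism behind the
structure–function asymmetry — and makes the cyan−red volume difference
more negative in early (large-island) disease.

Retest sessions re-run every staircase with independent observer noise plus
an additive per-locus perturbation of SD `retest_sd_within` (default
1.5 dB), drawn independently per color, applied to the true threshold
rather than the staircase: biological/criterion drift and staircase noise
stay separable, and the cyan and red within-subject variances add in the
combined cyan−red index.

What the generator does **not** emulate: dark-adaptation kinetics (the
adaptation period is metadata), learning and fatigue effects, eye-tracker
latency, spatially correlated threshold noise, and real fixation dynamics
(saccades, drifts). Passing tests therefore show that the analysis recovers
the structure this model encodes, not that the device behaves this way.

## Reliability gate

Fixation losses = 100 × pressed/presented blind-spot catch trials; exams
fail at ≥30% (the inclusive boundary is deliberate and the cutoff is
exposed). The preferred retinal locus for P1/P2 is the coordinate-wise
median of the trace (robust to saccadic outliers; the device's estimator is
unpublished and an explicit center can be supplied). Fujii classes use
strict inequalities (P1 exactly 75% is not stable). BCEA uses
`k = −ln(1−P)` with the exact `1 − 1/e` convention for the "63%" output
(so BCEA95/BCEA63 = 2.996); sample SDs with ddof = 1. The rod-free check
requires a scotopic cyan exam with a central locus and compares the central
threshold to 8.0 dB, applied uniformly to both groups; the sentinel counts
as detected (a full central scotoma is the expected physiology).

## Volume integration

Volume sensitivity integrates the piecewise-linear interpolant over the
Delaunay triangulation of the loci, restricted to the convex hull with no
extrapolation: each triangle contributes `area × mean(vertex values)`,
which is exact for linear pieces, deterministic, and free of smoothing
assumptions. Non-seen loci enter as 0.0 dB. Known limitation: on a
perfectly regular radial grid the inter-ring quads are isosceles
trapezoids, hence cyclic, so the Delaunay diagonal choice is a tie-break;
different tie-breaks change the integral by ~0.1%. The triangulation is
deterministic for fixed coordinates, but exact rotation equivariance holds
only in generic position (verified on jittered grids).

Mean sensitivity maps the sentinel to 0.0 dB (matching device behaviour,
where fully non-seeing exams report 0.0-dB means while pointwise exports
carry −1.0; the mapping is configurable in pointwise pair building). A
regression test documents that on the radial grid the mean is spatially
weighted toward the dense centre, unlike the area-weighted volume index.
The central locus can be excluded from global indices to remove the
rod-free-fovea bias from cyan summaries.

## Cyan–red difference classification

Per-locus `cyan − red` is undefined when either value is the sentinel;
both-non-seen loci default to *equally reduced* (black). Within the limit,
loci are *equal-normal* (gray) unless either threshold falls below a
per-locus normative lower bound (healthy reference mean − 2 SD — the
"reduced" boundary is not quantified in the literature, so this
conventional bound is used and exposed); beyond the limit the sign gives
rod (−) or cone (+) dysfunction. The limits 0 / 4 / 13 dB correspond to
raw, device-default, and test–retest-adjusted displays. Differences are
computed only within a session; cross-session change belongs to the
repeatability models.

## Repeatability models

Differences are fixed as test2 − test1. The repeated-measures model fits a
random-intercept MixedLM (statsmodels, REML) to the differences;
`sd_within = √scale`, `sd_between = √cov_re`. CoR defaults to the classic
formula `2 × 1.96 × SD_within` (a `sqrt2` flag provides the
`1.96·√2·SD_within` alternative); limits of agreement use the *total* SD
`√(σ_b² + σ_w²)` — CoR answers "how much within-subject change is real",
LoA "how far apart two sessions can plausibly be". With all differences
identical the fit degenerates to zero SD components rather than erroring.
Confidence intervals come from a cluster bootstrap: subjects resampled with
replacement, model refit, percentile intervals (default 1000 replicates,
seeded). The naive pooled-SD CoR is provided as a diagnostic only; it
strictly exceeds the mixed-model CoR whenever between-subject variance is
present, which is precisely why the mixed model is required.

For one-pair-per-subject indices (mean, volume), `sd_within =
SD(differences)/√2` and LoA = bias ± 1.96·SD(differences).

The combined cyan−red pointwise analysis forms the per-locus difference
within each session, excludes loci with a non-seen (< 0 dB) value in either
color at either session (the primary rule; a stricter variant additionally
excluding 0.0-dB values is exposed as an option, since both phrasings are
in circulation), then fits the repeated-measures model to the
session-to-session change of the difference index.

## Cohort statistics

Group comparisons use two-sided Mann–Whitney U; paired color comparisons
use the Wilcoxon signed-rank test (scipy chooses exact vs normal
approximation by sample size); all-zero paired differences return p = 1.0
by policy. Structure–function uses Spearman rank correlation of island
area (mm²) against cyan volume, red volume and their difference, requiring
n ≥ 4 and non-constant inputs. No multiple-testing correction is applied
by default. Report tables are plain CSV; the exclusion log lists each
gated-out exam with all of its reasons, and included + excluded always
equals the input count.

## Problem sizes and determinism

Simulated checks use 4–20 subjects per group and 25–1000 bootstrap or
Monte-Carlo replicates, chosen as the smallest sizes at which the
statistical properties under test are stable; all randomness flows from
explicit integer seeds through `numpy.random.default_rng`, so cohorts,
pipelines and bootstrap intervals are bit-reproducible.
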