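# Methods

## Signal model

Every tissue is a mixture of mono-exponentially decaying T2\* pools. The
noiseless magnitude signal of a voxel at echo time TE (ms) is

    S(TE) = Σ_t  w_t · s0_t · c_t · Σ_j f_{t,j} · exp(−TE / T2*_{t,j})

with `w_t` the voxel's volume fraction of tissue *t* (partial volume),
`s0_t` its proton-density amplitude (arbitrary units), `c_t` a suppression
factor (1 everywhere except fat, see below), and `(f_{t,j}, T2*_{t,j})` the
pool fractions and decay constants. Repetition-time/flip-angle steady-state
weighting is folded into `s0`: both echoes follow a single excitation, so
T1 cancels in the two-point ratio and needs no explicit model.

The two-point **apparent T2\*** estimator inverts the ratio of the two
echo intensities:

    aT2* = −ΔTE / ln(iTE2 / iTE1)

The primary, ROI-level estimate applies this to the ROI-*mean* intensity of
each echo (one intensity per ROI per echo); the mean of the valid voxelwise
estimates is reported alongside as a sensitivity analysis. The two coincide
for homogeneous ROIs and differ for heterogeneous ones (Jensen's
inequality); the package treats the ROI-mean form as primary because the
estimator is defined on ROI signal intensities. Voxels where either
intensity is non-positive or where the signal does not decay are flagged
invalid and excluded (not clipped); finite estimates above 200 ms are kept
but flagged unreliable, since a ~4.4 ms echo spacing barely distinguishes
such slow decay. Echo subtraction is floored at zero, matching the
magnitude-image convention of scanner-side subtraction.

## Phantom geometry and defaults

The phantom is a 2-D thigh cross-section extruded along the slice axis
(the nerve runs parallel to the main field, so magic-angle effects are not
modelled): a muscle disc bounded by a thin fascia ring and a subcutaneous
fat ring, containing a circular nerve with a deterministic fascicle layout
(one central + a ring). Defaults, chosen to resemble mid-thigh sciatic
anatomy at the protocol's resolution:

| parameter | default | note |
|---|---|---|
| grid / voxel | 96×96×12 / 0.6×0.6×5.0 mm | 12 slices = 6 cm slab |
| TE1 / TE2 | 0.98 / 5.37 ms | dual-echo vTE protocol |
| muscle radius | 24 mm (13 mm in the demo pipeline's 64-grid) | thigh cropped by FOV is acceptable; air corners must remain for the noise ROI |
| nerve radius | 3.85 mm | CSA ≈ 46.5 mm² |
| nerve tissue | s0 650, 70% @ 50 ms + 30% @ 2 ms | long fascicular water + short connective/myelin pool; whole-nerve T2 literature spans ~45–70 ms, fascicle-scale T2\* ~16–22 ms |
| muscle | s0 1000, 28 ms | single pool |
| fascia/tendon | s0 900, 1.5 ms | bright on subtraction |
| fat | s0 1000, 30 ms, suppression 0.05 | binomial fat suppression emulated as a 5% amplitude factor |
| supersample | 4 | boundary partial volume by block-averaging a supersampled one-hot rasterization; supersample = 1 yields pure voxels (used by exactness tests) |
| noise σ | 12 | Rician per echo, independent; gives nerve SNR ≈ 80–90, the in-vivo regime |

The nerve amplitude sits below muscle so the nerve/muscle
contrast-to-noise ratio lands near in-vivo values (~0.3). Noise is applied
independently per echo (monopolar readout, separate acquisitions of the
two echoes' k-space lines).

## Cohort generator

A simulated cohort has 10 "young" (21–26 y, 6M/4F) and 5 "senior"
(46–62 y, 3M/2F) subjects, two sides each. Height ~ N(1.75, 0.08) m and
BMI ~ N(21.9, 1.2) kg/m² are drawn and weight derived as BMI·height²;
drawing weight independently would give an unrealistically wide BMI
spread. Per subject-side, nerve aT2\* = side mean (17.25 ms right,
18.57 ms left) + subject effect N(0, 3.5) + side residual N(0, 4). The
side residual is deliberately wide: a 1.3 ms side contrast that is *not*
statistically significant at n = 15 requires a paired-difference SD of
roughly 5 ms, and the per-side SDs then land near 4–5 ms. Nerve calibre is
CSA ~ N(46.5, 7) mm² per subject plus N(0, 3) per side. Each subject-side
phantom uses a *single-pool* nerve at the drawn aT2\*, so the configured
value is exactly the two-point ground truth (the recovery oracle is
exact); the two-pool default tissue is used when a fascicular
substructure, rather than an exact oracle, is wanted. All draws derive
from one seed through spawned sub-seeds; cohorts are bit-reproducible.

## Simulated readers

Manual segmentation variability is emulated by adding a smooth unit-SD
Gaussian random field (in-plane smoothing σ = 2 voxels) to the signed
distance transform of the true mask and keeping, per slice, the top-n
voxels of the perturbed level set, where n is the true per-slice count.
Keeping the count fixed preserves ROI area — a free boundary threshold
systematically dilates convex ROIs — so reader CSA is unbiased while the
boundary wanders. The field amplitude is calibrated by bisection (16 probe
draws per iterate, 12 iterations, separate calibration RNG stream) so the
*expected Dice against the true mask* matches the target; target 1 returns
exact copies. Two independent tracings at Dice 0.70 vs truth overlap each
other at ~0.55–0.60 — pairwise inter-reader Dice is geometrically lower
than either reader's Dice against the truth, and the report tables show
the pairwise value. Reader masks admit adjacent muscle, which biases the
reader-measured aT2\* upward by ~2 ms relative to the true-mask value at
Dice 0.70; this is the reproducibility cost the agreement battery
measures, not an estimator defect.

## Validation statistics

- **SNR** = nerve-ROI mean / raw SD of a background-air ROI. For channel
  noise σ the background magnitude SD is σ·√(2−π/2) (Rayleigh); an
  optional flag divides it out, but the raw printed convention is the
  default. **CNR** = (SNR_muscle − SNR_nerve)/SNR_muscle, exactly the
  normalized form; negative values (nerve brighter) are returned with a
  flag.
- **ICC**: single-measure, from the ANOVA mean squares of a
  targets×raters table. Forms: one-way random ICC(1,1); two-way random,
  absolute agreement ICC(A,1) — the default for inter- and intra-reader
  agreement, the usual choice for method validation; two-way mixed
  consistency ICC(C,1). Confidence intervals use the exact F bounds
  (one-way, consistency) and the Satterthwaite approximation (agreement);
  H0: ICC = 0 is tested with F = MSR/MSE (MSR/MSW one-way). Degenerate
  inputs (constant table, <3 targets, <2 raters, missing cells) raise.
  Note two properties of the raw estimators that are kept rather than
  hidden: ICC(A,1) can fall below −1 on pathological noise tables (no
  clamping is applied), and absolute agreement is only guaranteed ≤
  consistency when both MSR and MSC exceed MSE.
- **Paired comparisons**: Shapiro–Wilk at α = 0.05 on the differences
  routes to the paired t test (normal) or the Wilcoxon signed-rank test.
  Wilcoxon drops zero differences, uses the exact null for n ≤ 25 when
  ranks are untied, otherwise the normal approximation with continuity
  correction. Identical paired samples return t = 0, p = 1 rather than an
  undefined statistic.
- **Regression**: OLS of aT2\* on weight, height and BMI with intercept.
  BMI is a function of the other two, so the design is near-collinear by
  construction; the condition number is always reported and a warning is
  emitted above 1e8.
- **Multiplicity**: Bonferroni α/m, family size defaulting to 6,
  reported rounded to 3 decimals alongside full precision.

The subtraction-contrast property has a turning point: the noiseless
echo1−echo2 difference is maximal at T2\* = ΔTE/ln(TE2/TE1) ≈ 2.6 ms for
this protocol, increasing below it and strictly decreasing above it.

## Pipeline and problem sizes

The demonstration pipeline runs 15 subjects × 2 sides on a 64×64×12 grid
(scaled-down in-plane FOV with the same voxel size and slice count, sized
so the whole chain completes in about a minute on one CPU), simulated
readers at target Dice 0.70, extreme-slice discard k = 2, ICC(A,1),
α = 0.05 with family 6. Intra-reader agreement re-segments the first five
subjects (deterministic stand-in for the study design's five random ones).
Muscle and background-noise ROIs are placed automatically from the ground
truth: pure-muscle voxels in a 2–7 mm annulus around the nerve, and
pure-air voxels outside the thigh. Every stochastic stage draws from the
run seed via spawned sub-seeds; the manifest lists each output with its
SHA-256, reruns with the same config+seed are bit-identical, and a rerun
over an up-to-date output directory is a no-op.

Monte-Carlo problem sizes: noisy-recovery bias uses 200 replicates on a
48×48×12 single-pool phantom at nerve SNR 80 (observed bias ≲ 0.1%,
comfortably within the 2% acceptance band); the Rician-floor check uses
500 replicates of a homogeneous block at echo-2 SNR 2.5 and asserts the
*sign* of the bias (upward) — near the noise floor the magnitude bias
props up iTE2 and inflates aT2\*, and individual replicates can even fail
to decay (counted as infinite overshoot, hence median statistics).

## What the phantom does and does not show

Passing tests demonstrate correctness of the estimators, the agreement
statistics and the orchestration on data whose generating model is known.
The phantom deliberately omits: k-space acquisition effects (asymmetric
readout blurring, chemical shift), B0 inhomogeneity and susceptibility
(aT2\* vs T2 is represented only through the configured decay constants),
magic-angle dependence, through-slice anatomy changes, and reader
behaviour correlated with image content (simulated readers perturb
geometry independently of the noise realisation). Consequently the
in-vivo values it reproduces (aT2\* scenario means, SNR/CNR scale, Dice
0.70) are emulated operating points, not predictions, and agreement
statistics on real data may be less favourable than on the phantom.
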