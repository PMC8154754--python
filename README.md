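# vtemri

Quantitative analysis of dual-echo **variable-echo-time (vTE) MR
neurography** of peripheral nerve, with a synthetic phantom generator that
makes every stage of the pipeline verifiable against known ground truth.

Peripheral nerves contain short-T2\* species — collagenous connective
tissue (endo-/peri-/epineurium) and myelin — that are invisible at
conventional echo times. A vTE spoiled gradient-echo acquisition reaches
TE < 1 ms; with a second echo at ~5 ms, subtracting Echo 2 from Echo 1
suppresses the long-T2\* components and highlights the short-T2\* ones, and
the two echoes support a quantitative two-point estimate of the effective
transverse decay, the *apparent* T2\*:

```
aT2* = −ΔTE / ln(iTE2 / iTE1),      ΔTE = TE2 − TE1
```

where `iTE1`, `iTE2` are the signal intensities of the nerve ROI on the two
echo images. The package implements, for researchers validating such
protocols:

- **`vtemri.phantom`** — a multi-compartment digital thigh phantom
  (muscle, fascia, suppressed fat, nerve with fascicles; each tissue a
  mixture of mono-exponential T2\* pools), partial volume by
  supersample-and-average, Rician magnitude noise, simulated bilateral
  cohorts with demographics, and simulated "reader" segmentations
  calibrated to a target Dice overlap;
- **`vtemri.relaxometry`** — echo subtraction, voxelwise and ROI-level
  aT2\* with invalid-voxel accounting, cross-sectional area (CSA), and the
  discard-extreme-slices rule (10 of 12 slices analysed);
- **`vtemri.roi`** — polygonal ROIs (JSON), voxel-centre rasterization,
  cross-echo mask transfer, Dice index;
- **`vtemri.stats` / `vtemri.reports`** — SNR and CNR by the background-ROI
  conventions, single-measure ICC (one-way, absolute agreement,
  consistency) with F-based confidence intervals, paired t and Wilcoxon
  signed-rank tests behind a Shapiro–Wilk gate, multivariable regression,
  Bonferroni thresholds, and the four standard validation tables;
- **`vtemri.pipeline` / CLI** — a deterministic simulate → segment → fit →
  validate → report chain with a checksummed manifest.

## Worked example

`examples/02_fit_apparent_t2star.py` builds a noiseless phantom whose nerve
is a single 17.25 ms pool and fits it:

```
configured nerve T2*      : 17.25 ms
ROI-mean estimate         : 17.2500000000 ms
voxelwise-mean estimate   : 17.2500000000 ms
CSA over 10 slices        : 46.4 mm^2
subtraction, fascia mean  : 443.2  (short T2*, bright)
subtraction, muscle mean  : 140.1  (long T2*, dark)
```

Two points determine a mono-exponential, so both estimators recover the
ground truth to machine precision; the subtraction image is ~3× brighter in
the 1.5 ms fascia than in 28 ms muscle, the visual signature of short-T2\*
imaging. `examples/03_reader_agreement.py` adds simulated readers at an
expected Dice of 0.70 and shows the reproducibility cost of manual
segmentation (reader masks admit adjacent muscle and nudge aT2\* upward),
and `examples/04_cohort_report.py` runs the full 15-subject bilateral
cohort and prints demographics, group-comparison, reader-agreement and
SNR/CNR tables. The same run is available from the shell:

```bash
vtemri demo --out demo_run --seed 0
```

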