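# Methods

## Perfusion model and pipeline

A near-infrared recording of an intravenous ICG bolus is a stack of
non-negative intensity frames with timestamps (`FrameSequence`). The
analysis reduces it to one scalar and three flags per breast:

1. **ROI curve.** The mean intensity over the operator-drawn breast ROI is
   computed per frame. Phase logic is index-based on this sampled curve;
   timestamps are informational.
2. **Phase detection.** The arterial phase ends at the first frame whose ROI
   mean reaches `rise_fraction` (default 0.95) of the curve maximum; the
   venous phase starts at the last frame still at or above `fall_fraction`
   (default 0.90) of the maximum. The plateau window is the inclusive range
   between them; it always contains the argmax frame and is therefore never
   empty, even for a single-peaked curve. The fractions were chosen so that
   a flat-topped bolus curve yields its visually flat segment; both are
   configurable. An identically zero curve is rejected ("no perfusion
   signal").
3. **Plateau map.** Per-pixel median over the plateau window (robust to
   frame-to-frame flicker); `mean` is available, and a one-frame window
   reproduces a frozen-screen workflow. On noise-free input with a sharp
   venous onset both aggregators are exact; with a slow washout the 0.90
   fall fraction admits the first one or two decay frames, which the median
   ignores and the mean does not — one reason median is the default.
4. **RPU normalization.** `RPU = 100 · clip(I / normalizer, 0, 1)` inside
   the breast ROI, where the normalizer is the `percentile` (default 100,
   i.e. the brightest in-ROI point) of in-ROI intensities. Percentile 99 is
   recommended for noisy sensors and is logged whenever ≠ 100. RPU is
   invariant to any positive rescaling of intensities (gain, dose, bit
   depth).
5. **Segmentation.** Hypoperfused = breast pixels with RPU strictly below
   `cutoff` (default 30; a pixel exactly at 30.0 is adequately perfused).
   Connected components (8-connectivity) smaller than `min_component_px`
   (default 25 at the default resolution) are removed as speckle **before**
   the nipple is excluded, then all nipple pixels are dropped. The ordering
   matters: a hypoperfused region that the nipple disc splits in two is
   connected through hypoperfused nipple skin and must not be discarded as
   speckle; filtering the nipple-free mask instead can delete real 2–5-px
   crescents at the nipple margin. `min_component_px = 1` reproduces raw
   per-pixel thresholding. The nipple is never counted hypoperfused
   regardless of its RPU, since the nipple–areolar complex routinely reads
   below the cutoff without necrosis (dye-injection interference).
6. **Ratio and flags.** `area_percent_ratio = 100 · |hypo| / |breast|`; the
   denominator is the full breast ROI including the nipple (the clinical
   definition names the ipsilateral breast area without qualification — an
   open choice documented here). Flags: `is_hypoperfused_flap` (any region
   survives cleanup), the 15% decision threshold (change strategy / close
   follow-up when exceeded), and the one-third eligibility screen
   (`ratio > 100/3` marks a flap outside the intended-use population).

The ratio is monotone non-decreasing in `cutoff` and non-increasing in
`min_component_px`; both properties are tested.

## Synthetic data generator

The generator emulates a 3-minute post-injection recording over a
breast-shaped domain:

- **Geometry.** Centred ellipse with semi-axes 45% of the image dimensions;
  a disc nipple (radius 8 px at the default 160×192 resolution; radius 0 =
  skin-sparing case). Perforator territories are a Voronoi partition from
  uniformly drawn seed pixels; discrete boundary slivers that the ellipse
  clipping disconnects are absorbed into an adjacent territory so every
  territory is 8-connected, as a contiguous patch of perfused skin should
  be (>99% of pixels keep their exact nearest-seed label).
- **Kinetics.** Piecewise curve per pixel: linear rise to `plateau_level`
  (default 180 intensity units, mid gray range) at `time_to_peak` (30 s),
  constant plateau until `washout_start` (120 s), then exponential decay at
  `washout_rate` (0.02 /s); frames every 2 s over 0–180 s. This is the
  minimal form exhibiting the three named phases; the recording duration
  matches the clinical protocol (injection followed by 3 minutes of video),
  while frame rate and bit depth are implementer choices since no device
  values are published.
- **Dropout.** Selected territories have their plateau multiplied by
  `dropout_factor` (default 0.15, i.e. RPU 15 — safely below the 30 cutoff
  but nonzero). Ground truth is the union of dropout territories; the
  recorded `truth_area_fraction` excludes the nipple from the numerator and
  divides by the full breast area, mirroring the analysis convention.
  `simulate_case` picks territories greedily in shuffled order until a
  target fraction is reached and records the *realized* fraction.
- **Noise and background.** Zero-mean Gaussian sensor noise truncated at 0
  (intensities are non-negative counts); constant background of 1% of the
  plateau level outside the breast, so correct normalization genuinely
  requires the ROI. A single RNG seed per case drives seed-point choice,
  dropout order and noise, making cases bit-reproducible.
- **Cohorts.** Necrosis ~ Bernoulli(prevalence); the predictor is positive
  with probability `sens` given necrosis and negative with probability
  `spec` otherwise. Covariates (age, BMI, mastectomy/reconstruction type,
  area ratio) are plausible fillers keyed to outcome status so report code
  has realistic structure; they carry no causal model.

What the simulator does **not** emulate: light transport and fluorophore
pharmacokinetics, patient or camera motion, spatially correlated noise,
methylene-blue interference with nipple perfusion, and gradual (rather than
territory-wise) perfusion gradients. Passing recovery tests therefore show
that the pipeline is exact under its own model assumptions and robust to
independent sensor noise — not that the 30% cutoff is clinically optimal.

## Diagnostics

- `build_confusion` cross-tabulates boolean predictor and outcome columns,
  rejecting uncodable rows by index.
- `diagnostic_metrics`: sens = tp/(tp+fn), spec = tn/(tn+fp),
  ppv = tp/(tp+fp), npv = tn/(tn+fn), each with an exact Clopper–Pearson
  95% CI (chosen because three of the four cell counts in a typical cohort
  of this size are tiny; the interval is conservative, with empirical
  coverage ≈98% at n = 45 in our simulation). Zero-denominator metrics are
  reported missing with a warning, never as 0.
- `fisher_exact_two_sided`: probability-mass convention (sum of
  hypergeometric probabilities of all margin-consistent tables at most as
  probable as the observed one, with 1e-7 relative tie tolerance) — the
  convention of mainstream statistical software, delegated to
  `scipy.stats.fisher_exact` and verified in the test suite against a full
  enumeration oracle built from exact integer binomial coefficients.
- `summary_ttest`: two-sided p from mean/SD/n per group; `pooled` (classical
  Student t, the default since that is the test named in the source
  protocol) or `welch`. Zero-variance degenerate inputs resolve by limits
  (equal means → p = 1, unequal → p = 0 with a warning).
- `cohort_report` renders per-variable group comparisons (t test for
  continuous, Fisher for 2×2 categorical) in deterministic order;
  single-group cohorts get descriptive rows only.
- p-values render to 3 decimals with `<0.001` below threshold.

## Numerical and I/O choices

- TIFF export rounds to uint16; lossless for integer-valued stacks and
  immaterial otherwise because RPU is scale-invariant and plateau medians of
  the synthetic model are integers by construction.
- Masks are strict 0/255 PNG; any nonzero pixel reads as True.
- `RunConfig` (all thresholds, fractions, aggregator, seed) validates its
  ranges, round-trips through YAML, and is logged in every CLI assessment
  report, so a run can be reproduced bit-identically.
- Pixel convention: row-major, 0-based; masks are never resampled.

## Problem sizes

Tests run on 48–128 px domains with 8–24 territories; the acceptance script
uses 128×152 px, 24 territories, 91 frames, a 5000-row simulated cohort and
10 000 binomial replicates for CI coverage — sizes at which every quantity
of interest (exact recovery, coverage, recovered sens/spec) is already
stable to well within its tolerance.

## Known limitations

- Breast and nipple ROIs are inputs (drawn by the operator clinically);
  there is no automatic segmentation from raw images.
- No motion correction between frames; the clinical workflow fixes the
  camera and patient.
- The decision (15%) and eligibility (one-third) thresholds are applied as
  given; the package does not optimize cutoffs (no ROC search), and offers
  no multivariate risk modelling.
- The synthetic cohort's covariates are descriptive fillers; only
  predictor/outcome have calibrated operating characteristics.
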