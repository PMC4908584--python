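# Methods

## The measurement problem

A competitive lateral-flow strip for a small analyte (here vitamin B12,
~1.4 kDa, too small to be sandwiched by two antibodies) reports analyte
concentration inversely: labelled antibody that escapes capture by sample
analyte binds the immobilised analyte–carrier conjugate at the **test
line**, while a secondary antibody at the **control line** captures label
regardless. High sample concentration → faint test line, strong control
line → low T/C ratio. Silver enhancement darkens both lines to push the
limit of detection into the sub-nmol/L range the B12 assay needs. The
quantitative readout is therefore a densitometry problem: measure the
darkness of two transverse lines in a photograph and form their ratio.

## Image-quantification pipeline

`analyze` composes five steps, each exposed individually:

1. **smooth** — 3×3 Gaussian filter, implemented as the binomial kernel
   (outer product of `[1, 2, 1]`, normalised by 16). Borders are handled by
   edge replication. The kernel preserves constants exactly, so a uniform
   brightness change commutes with smoothing.
2. **to_gray** — luma conversion with BT.601 weights (0.299, 0.587, 0.114)
   by default; single-channel input passes through. The lines are
   reddish-brown on a light membrane, so grayscale intensity separates line
   from background in one channel.
3. **collapse_profile** — each pixel row (perpendicular to flow) is
   replaced by its median, reducing the image to a 1D profile indexed along
   the flow axis. The median rejects speckle, dust, and edge artifacts that
   would bias a row mean; even-width rows use the mean-of-middle-two
   convention.
4. **find_minima** — lines are local minima of the profile. A candidate
   minimum is accepted only if it lies at least `min_depth` grayscale units
   (default **10**) below the nearest enclosing turning point on *both*
   sides — i.e. a bilateral prominence criterion. The turning point on each
   side is found by walking outward while the profile is non-rising; the
   array edge counts as a turning point, a boundary extremum never counts
   as a minimum, and a plateau minimum reports its centre index. Each
   detection carries its left/right baselines; its depth is
   `min(left, right baseline) − minimum`.
5. **assign_lines / tc_ratio** — with more detections than expected the two
   deepest are kept (ties broken toward the upstream line); the detection
   nearer the sample-inlet end (row 0) is the test line. The default T/C is
   the ratio of baseline-subtracted **depths**. Ratioing the raw minimum
   intensities instead (available as `tc_mode="raw_min_ratio"` for
   ablation) would *rise* with concentration and be sensitive to exposure;
   depth ratios fall from ~1 toward ~0.3 across the calibrated range,
   matching the direction of the 4PL, and are exactly invariant to a
   constant illumination offset. Fewer than two detections raises
   `InvalidTestError` — the image analogue of "control line absent, test
   invalid".

The coordinate convention (row 0 = sample inlet) is carried by
`StripImage`; an optional ROI crop (fractions of height) handles
photographs that include cassette edges. Automatic strip localisation,
perspective correction, and colour constancy are out of scope.

## 4PL calibration

Batches of strips vary, so each batch is calibrated with the immunoassay
standard four-parameter logistic,

    T/C = d + (a − d) / (1 + (x / c)^b),    x = concentration (pmol/L)

with `a > d` (decreasing curve), `b > 0`, `c > 0`. Fitting is unweighted
nonlinear least squares over all replicates (`scipy.optimize.curve_fit`),
initialised at `a₀ = max` and `d₀ = min` of the per-level mean T/C,
`c₀ =` the nonzero calibrator whose mean T/C is nearest `(a₀+d₀)/2`, and
`b₀ = 1`, with bounds `a, d ∈ [0, 2]`, `b ∈ (0, 20]`, `c ∈ (0, 10⁵]`. At
least four distinct calibrator concentrations are required. `r_squared` is
computed against the per-level replicate means — the summary a
three-replicate design reports — not against individual replicates.

Prediction uses the analytic inverse
`x = c·((a−d)/(T/C − d) − 1)^(1/b)`. Out-of-range readings are clamped and
flagged rather than raised, so cohort evaluation can proceed:

- `T/C ≥ a`: no detectable analyte → concentration 0, flag `below_range`;
- `T/C ≤ d`, or an inversion beyond the batch's highest calibrator
  (`max_concentration`, recorded by the fit): the value is extrapolation
  and is reported only as "greater than the highest calibrator" → flag
  `above_range`.

The highest-calibrator cap matters statistically as well as for honest
reporting: near the bottom asymptote the inverse has unbounded sensitivity
(`dx/d(T/C) → ∞` as `T/C → d`), so modest T/C noise explodes into extreme
concentration values there. Such readings carry no usable magnitude and
would dominate moment-based statistics; flagging them keeps bias and
correlation estimates meaningful, exactly as a ">highest calibrator"
laboratory report does.

Calibrations round-trip through JSON with full float precision, keyed by
`batch_id`.

## Diagnostic evaluation

Given paired reference and predicted concentrations per subject:

- **median bias** = median of `100·(pred − ref)/ref` (%); robust to the
  skewed errors 4PL inversion produces.
- **correlation** — Pearson r with its two-sided t-test p-value (the
  conventional signed-r-with-p report); Spearman available as an option.
- **classification** — deficient iff concentration **strictly below** the
  cut-off; default cut-off panel 150, 221, 258, 332 pmol/L. Range flags
  override magnitudes: `below_range` → deficient, `above_range` → not.
- **sens_spec** — sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)` with
  "positive" = deficient by the reference assay; a cohort with no
  positives (or negatives) reports the undefined metric as missing with a
  reason rather than 0/0.
- **roc** — the decision threshold sweeps all distinct predicted values
  plus ±∞, giving a staircase from (0, 0) to (1, 1); AUC by trapezoid. The
  tests verify equivalence with the Mann–Whitney normalisation
  (scikit-learn's `roc_auc_score` as an independent oracle) and invariance
  under monotone transforms of the predictions.

Range-flagged rows are excluded from bias and correlation (no magnitude)
but enter classification and the ROC through their flag, pinned to the
appropriate extreme.

## Synthetic data generator

`render_strip` emulates a silver-enhanced strip photographed at macro
range: a light background (default grayscale 200) crossed by two dark
lines rendered as Gaussian dips along the flow axis. Defaults mirror the
physical strip: 20 px/mm (a ~25 mm membrane → 500 rows; 4 mm width →
80 columns), line width 1 mm, line separation 3 mm. The Gaussian
cross-section (FWHM = line width) reflects reagent diffusion during
dispensing — a dispensed line has soft shoulders, not rectangular edges —
and guarantees a single local minimum per line. At each line centre the
noiseless profile equals `background − depth` exactly. Pixel noise is
additive zero-mean Gaussian; uneven lighting is modelled as a linear ramp
along the flow axis only. An RGB mode tints the lines reddish-brown
(weighted so the luma-converted depth equals the nominal depth) to
exercise the grayscale path. Output is 8-bit, clipped and rounded; a given
spec + seed is bit-reproducible.

`generate_calibration_set` ties line darkness to chemistry through the
calibration curve: at concentration x the test depth is
`control_depth · curve(x)`, so ground-truth T/C equals the curve value
exactly. The built-in reference batch curve is
`a=0.99, b=3, c=303.7 pmol/L, d=0.3` with highest calibrator 1107 pmol/L;
the simulated dilution series uses 0, 46, 92, 184, 369, 738, 1107 pmol/L
(a doubling series inside the calibrated 0–1107 range), three replicates
per level. `generate_cohort` draws reference concentrations log-uniformly
over 100–1100 pmol/L — spanning the deficient and sufficient physiological
range with roughly balanced classes at the 332 pmol/L cut-off — and
applies multiplicative Gaussian noise of a stated analytic CV (default
10%, of the order of the replicate CVs such assays show) to the true T/C
before inversion.

What the generator does **not** emulate: lens point-spread and vignetting,
perspective and strip misalignment, membrane texture and flow streaks,
colour temperature shifts, silver-development kinetics, or competitive-
binding chemistry (which enters only implicitly through the calibration
curve). Passing tests therefore demonstrate the correctness of the
*algorithmic* chain — rendering → densitometry → calibration → diagnosis —
under controlled noise, not robustness to real-world photography.

## Numerical choices and degenerate inputs

- 3×3 Gaussian realised as the binomial (1,2,1)²/16 — the standard
  discrete 3×3 approximation; σ is not separately tunable.
- Profile arithmetic in float64; 8-bit quantisation only at image
  boundaries (render output, smooth/to_gray of integer images).
- Prominence threshold fixed at 10 grayscale units by default, the
  smallest line depth the assay treats as real signal.
- Depth ties in line assignment keep the more upstream detection;
  >2 detections log a warning rather than fail.
- Blank or single-line strips raise `InvalidTestError` with the pipeline
  stage attached; the CLI maps this to `status=invalid_test` per image
  without aborting a batch.
- Zero-variance or <3-pair cohorts make correlation an error, not a NaN;
  single-class cohorts make the undefined ROC an error and the undefined
  sensitivity/specificity a reported absence.

## Problem sizes

The shipped test and reproduction runs use sizes chosen to characterise
the estimators well while keeping a full run interactive: 200 refits for
the calibration-recovery medians, 1000 random profiles for the
peak-detector oracle check, 100 noisy renders for the round-trip error,
and 200-subject cohorts for the diagnostic metrics. All complete in well
under a minute combined.

## Known limitations

- Single-analyte, two-line strips only; no multiplex panels.
- The 4PL is the only calibration family (no 5PL/spline), and batches are
  calibrated independently — no inter-batch harmonisation model.
- Real-photograph preprocessing (localisation, perspective, colour
  constancy) is out of scope; images are assumed cropped and flow-aligned.
- Absolute line optical densities are free parameters of the simulation,
  anchored only through the T/C ratio; the generator cannot validate
  absolute-darkness claims.
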