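# stripquant

Quantitative readout for competitive lateral-flow immunoassay strips, built
around the point-of-care vitamin B12 test format: a silver-enhanced strip
photographed with flow along the vertical axis, showing a test line (T) and
a control line (C) as dark transverse bands on a light membrane.

`stripquant` is for assay developers and diagnostics researchers who need
to turn strip photographs into concentrations and to validate that pipeline
quantitatively. It provides:

- **Image quantification** — a 3×3 Gaussian smooth, grayscale conversion,
  collapse of the 2D image to a 1D flow-axis profile via per-row medians,
  detection of the lines as local minima with a bilateral prominence of at
  least 10 grayscale units, and the baseline-subtracted **T/C ratio**.
- **Calibration** — the four-parameter logistic (4PL) standard for
  immunoassays, fitted per strip batch:

  `T/C = d + (a − d) / (1 + ([B12]/c)^b)`

  with top asymptote `a` (T/C at zero analyte), bottom asymptote `d`,
  inflection concentration `c` (pmol/L), and slope exponent `b`. Because
  the assay is competitive, T/C *falls* as concentration rises; the curve
  is inverted analytically to predict concentrations, with out-of-range
  readings clamped and flagged instead of reported as magnitudes.
- **Diagnostics** — median relative bias, Pearson correlation,
  sensitivity/specificity at clinical deficiency cut-offs
  (150/221/258/332 pmol/L; deficient = strictly below), and the ROC curve
  with trapezoidal AUC.
- **Synthetic data** — a seeded generator of strip images (Gaussian-profile
  lines 1 mm wide and 3 mm apart, additive pixel noise, optional
  illumination ramps) and measurement cohorts with known ground truth, so
  every stage is testable without photographs.

## Worked example

One command runs the whole chain on synthetic data — render a 7-level × 3-replicate
dilution series, quantify every strip image, fit the batch 4PL, simulate a
200-subject cohort at 10% analytic CV, and evaluate it:

```bash
stripquant demo --seed 1 --out-dir demo_run
```

```
stripquant demo (seed=1)

Calibration fit on 7-level x 3-replicate synthetic dilution series:
  a=0.9885  b=2.9866  c=305.21  d=0.3004  R^2=1.0000
  (generating curve: a=0.99 b=3.0 c=303.7 d=0.3)

Cohort evaluation (n=200, 10% analytic CV):
  median bias      -0.26 %
  Pearson r        0.9356 (p=1.34e-80)
  ROC AUC          0.9960 (deficiency < 332 pmol/L)
  cutoff    150 pmol/L: sensitivity 0.647  specificity 0.946  (tp=22 fp=9 tn=157 fn=12)
  cutoff    221 pmol/L: sensitivity 0.882  specificity 0.977  (tp=60 fp=3 tn=129 fn=8)
  cutoff    258 pmol/L: sensitivity 0.948  specificity 0.992  (tp=73 fp=1 tn=122 fn=4)
  cutoff    332 pmol/L: sensitivity 0.965  specificity 0.956  (tp=83 fp=5 tn=109 fn=3)

Shift invariance: |dT/C| after +20 offset = 0.00e+00
```

Reading this: the 4PL fitted to T/C ratios *measured from the rendered
images* recovers the generating batch curve to well under 1% per parameter;
on the cohort, the strip-predicted concentrations sit a median 0.26% below
the reference values and separate deficient from sufficient subjects almost
perfectly at the 332 pmol/L cut-off; and adding a constant illumination
offset changes no depth-mode T/C ratio at all, because both line depths are
measured relative to their local baselines.

Individual steps are available as subcommands:

```bash
stripquant simulate strip --seed 4 --out-dir sim      # one synthetic strip
stripquant analyze sim/strip.png                      # -> T/C ratio JSON
stripquant calibrate data.csv --batch B1 -o calib.json
stripquant predict --calib calib.json --tc 0.645
stripquant evaluate cohort.csv --roc-out roc.csv
```

`analyze` on the strip above prints `"tc": 0.5063` against a ground truth
of 0.5000 — the render/measure round trip is accurate to well within the
2% the test suite enforces.

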