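# ctcontrast

Quantitative contrast assessment for contrast-enhanced micro-CT.

Iodine staining makes soft tissue visible in X-ray micro-computed
tomography, but how long to stain, and with which fixation/staining
protocol, is an empirical question: contrast rises with staining duration,
peaks, and then collapses again as every tissue approaches iodine
saturation (overstaining). `ctcontrast` implements the measurement chain
used to answer that question for small specimens such as marine
crustaceans, whose scans combine a bright calcified shell with faint
central-nervous-system (CNS) organs:

* **ROI patch statistics** — circular patches (stated by circumference,
  0.20 mm for organs and background, 6.00 mm as a fallback region on poorly
  contrasted scans) sampled in single slices of 16-bit TIFF stacks, with
  bilateral left/right averaging and a two-patch background mean.
* **Contrast ratios** — per organ,
  `R = (μ_organ − μ_background) / μ_background`, and across organs,
  `R_inter = (max μ_organ − min μ_organ) / min μ_organ`; both are invariant
  to rescaling of the gray values, so scans with different exposure
  settings are comparable. Peak staining time is the argmax of the
  organ-averaged `R` over the sampled durations.
* **Hounsfield-unit standardization** — a two-point affine map anchored on
  water and air reference means (air → 0 HU, water → 1000 HU by default; the
  clinical air → −1000 / water → 0 convention is a switch).
* **Nonparametric protocol comparison** — Kruskal–Wallis, Dunn's pairwise
  post-hoc z tests and Benjamini–Hochberg adjustment, implemented from the
  rank formulas (midranks for ties).
* **Morphometry of segmented labels** — per-organ volume, mesh or
  face-count surface area, percent of total brain volume and brain-region
  sums, in the standard one-row-per-organ report layout.
* **A synthetic phantom** — a seeded generator of stained-specimen volumes
  (ellipsoidal CNS organs inside a calcified shell, protocol- and
  time-dependent staining, Gaussian reconstruction noise) plus homogeneous
  water/air calibration phantoms, so the whole chain can be validated
  against known ground truth.

The package is used from Python (see `examples/`, one short script per
capability); a thin `ctcontrast` command-line wrapper exposes the pipeline
stages (`run`, `simulate`, `sample`, `contrast`, `calibrate`, `stats`,
`volumes`) for shell use.

## Worked example

```bash
python examples/02_staining_time_course.py
```

simulates the six staining durations for the three fixation/staining
protocols, runs the sample → contrast chain on every scan, and prints:

```
mean contrast ratio R by staining duration (h):
protocol               0      12      24      48      72      96   peak
FORMALIN_BLUGOL     8.90   13.79   16.32   18.34   17.17   15.62     48
ETOH_BLUGOL         8.91   13.11   15.52   17.00   15.68   14.79     48
ETOH_I2E            8.96   10.25   10.70   11.23   11.06   10.66     48
```

Each number is the organ-averaged contrast ratio `R` of one simulated scan;
both buffered-Lugol (B-Lugol) protocols climb to a maximum at 48 h and
decline afterwards — the overstaining signature — while alcoholic iodine
(I₂E) stays far below them throughout. `examples/05_morphometry.py` prints
the percent-of-total table for the bundled reference CNS segmentation
(total 0.6142 mm³; hemiellipsoid body neuropil 47.61%, protocerebrum
66.13%), and `examples/04_protocol_comparison_stats.py` runs the
Kruskal–Wallis/Dunn/BH chain on per-organ ratios at peak time.

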