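# Methods

## The measurement problem

Contrast-enhanced micro-CT of small specimens (here modelled on
iodine-stained crustaceans) must balance staining duration against
overstaining: too short and soft tissue is indistinguishable from
background, too long and all tissues approach iodine saturation so the
contrast *between* them collapses. `ctcontrast` quantifies this with two
ROI statistics computed from patch mean gray values μ on 16-bit
reconstructions (0–65535):

* per-organ contrast ratio `R = (μ_organ − μ_background) / μ_background`;
* inter-organ contrast ratio
  `R_inter = (max μ_organ − min μ_organ) / min μ_organ`, which ignores the
  background entirely.

Both are dimensionless and exactly invariant under multiplication of all
gray values by a positive constant, which is what makes scans acquired with
different exposure settings comparable. Peak staining time is the discrete
argmax of the organ-averaged `R` over the sampled durations — no
interpolation, because only the scanned durations are ever compared; ties
resolve to the earlier (cheaper) duration, and a maximum at the last time
point is flagged as "no decline observed".

## ROI patches

Patches are 2D discs in a single z-slice, matching the interactive
workflow in which an annotator picks a homogeneous section per organ. Patch
size is stated as the circle *circumference*: 0.20 mm for organ and
background patches and 6.00 mm for the fallback region used where organs
are indistinguishable. The default conversion takes that literally,
r = C/2π (≈ 31.8 μm, ~15 voxel radius at 2.1 μm pixels — a plausible patch);
because stating a circle by circumference is unusual, a `diameter`
interpretation (r = C/2) is available as a switch. A voxel belongs to the
disc when its center satisfies (y−cy)² + (x−cx)² ≤ r²; patches clipped by
the slice boundary are rejected rather than silently truncated (a partial
disc biases μ). Patch SD is the population SD (ddof = 0), matching the
histogram readout of imaging software; nothing downstream depends on this
choice. Left/right organ patches are averaged unweighted; midline organs
pass through; exactly two background patches are averaged.

## Hounsfield standardization

A two-point affine map `HU(g) = slope·g + intercept` is anchored at the
mean gray of an air and a water reference (water scanned immediately after
the specimen without switching off the beam). The default convention
ascribes 0 HU to air and 1000 HU to water; the clinical convention
(−1000/0) is a labelled switch. Anchors hold to 1e−9 by construction and
outputs are never rounded. Note two caveats, both surfaced by explicit
guards rather than silent behaviour: a contrast ratio computed on HU
differs from the raw-gray one whenever the intercept is nonzero, and with
the air-anchored convention a background patch in air maps to ≈ 0 HU, where
the ratio's denominator is ill-conditioned (ε_HU = 10 HU guard; the
pipeline records NaN for such ratios and keeps the HU means themselves).

## Synthetic phantom

The generator emulates the features of a stained-shrimp reconstruction that
the measurement chain actually touches: an ellipsoidal calcified shell
(annulus, mean 30000), 14 CNS organs as disjoint ellipsoids — 11 bilateral
pairs mirrored exactly about the sagittal midplane, 3 midline — and an air
background with a positive scatter floor (mean 800, so the Eq.-1
denominator is finite, as in real reconstructions). Organ mean intensity
follows

    mean(organ, protocol, t) = baseline + scale[protocol] · A[organ] · f(t),
    f(t) = (t/t_peak) · exp(1 − t/t_peak),

the simplest smooth rise-then-decline with a single interpretable
parameter. f(0) = 0, f(t_peak) = 1 is the unique maximum, and f is strictly
monotone on either side. Defaults: baseline 8000, t_peak = 48 h, organ
amplitudes 4000–12000 (spanning weakly to strongly staining neuropils),
protocol scales FORMALIN_BLUGOL 1.0 > ETOH_BLUGOL 0.85 > ETOH_I2E 0.25
(encoding the qualitative protocol ranking), water reference 10000. Voxels
are drawn from a normal law per tissue class, clipped to [0, 65535] and
rounded; identical seed and inputs give bit-identical volumes.

Noise defaults are set by a power analysis of the desk-scale geometry:
soft tissue SD 400, shell 800, air and water 50. The default layout is a
160³ grid at 10 μm (a 1.6 mm field of view) — far coarser than real scans
at 2.1–3.0 μm, chosen so a full protocol × duration × replicate sweep runs
in minutes on one CPU. At 10 μm a 0.20 mm patch covers only ~35 voxels
(vs ~720 at 2.1 μm), so air SD 50 gives the background mean the same
relative precision (<1%) the real-scale measurement would have; tissue-SD
noise then dominates, and the 48 h peak is separated from its neighbouring
durations by several standard errors.

What the phantom does **not** model: projection/reconstruction physics
(beam hardening, ring artifacts, streaks), diffusion-limited staining
gradients within an organ, anatomy beyond disjoint ellipsoids, and any
calibrated post-peak decline rate (the decline exists but its slope is not
fitted to data). Passing tests therefore demonstrate that the measurement
chain is correct and well-conditioned under realistic noise — not that any
particular biological staining series will behave this way.

## Nonparametric protocol comparison

Per-organ contrast ratios within a protocol are treated as replicates.
The chain is implemented directly from the rank formulas with midranks for
ties: tie-corrected Kruskal–Wallis H with a χ²(k−1) p-value (used
regardless of sample size, as conventional software does; a warning is
logged for groups under five observations — for N ≤ 8 an exact permutation
p can differ noticeably, and one test logs that comparison), Dunn's pairwise
z on pooled mean ranks with two-sided normal p-values (signed, so the
direction of the difference is visible), and Benjamini–Hochberg step-up
adjustment returning values in input order. Independent cross-checks in the
test suite (`scipy.stats.kruskal`, statsmodels `multipletests`, brute-force
rank oracles, an exhaustive N = 6 permutation) never stand in for the
implementation.

## Morphometry

Volume is exact: voxel count × (edge length)³. Two surface estimators are
exposed because interactive segmentation tools rarely document theirs:
`mesh` (default) triangulates the 0.5-isosurface after smoothing the
binary mask with a sub-voxel Gaussian (σ = 0.8 voxels) — the smoothing
removes the ~8% staircase bias a raw binary isosurface carries, giving
< 1% error on digital balls of radius ≥ 12 voxels at the cost of
underestimating structures only a few voxels across — and `voxel_faces`
counts exposed faces × edge², an upper bound that overestimates curved
surfaces by up to ~50%. Percentages are computed unrounded
(100·v/Σv, region sums over member percentages) and rounded only at
presentation. The bundled reference segmentation of a snapping-shrimp CNS
(14 organs, total 0.6142 mm³) serves as a worked input; note its printed
percentage column is internally inconsistent with its own printed volumes
in three cells (rhabdom, median antennular neuropil, and the "visual
neuropils" region sum) — the package reports the arithmetic from the
volumes and flags the difference rather than reproducing inconsistent
cells.

## Numerical and design choices

* Denominator guards everywhere a ratio can degenerate (ε = 1 gray unit,
  ε_HU = 10 HU) — errors, never silent infinities.
* Bilateral organs carry a single label (left + right combined), matching
  one-row-per-organ morphometry reports.
* Coordinates are 0-based (z, y, x) voxel indices; patch centers may be
  fractional; per-slice TIFF directories are ordered lexicographically.
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; per-scan substreams are derived from (base seed, scan index), so
  adding a scan never perturbs another scan's noise.
* Simulation sizes in tests and the reproduction script: 160³ phantoms,
  20 replicates for peak-time recovery; chosen as the smallest sweep at
  which the recovery statistics are stable.

## Known limitations

* Peak detection reports a sampled duration only; if the true optimum lies
  between scanned times it cannot be found, by design.
* The χ² approximation for Kruskal–Wallis is poor at very small N; the
  package warns but does not switch to exact permutation.
* The HU-space contrast ratio is undefined for air-anchored backgrounds
  (≈ 0 HU); the pipeline reports HU means and NaN ratios there.
* Treating per-organ ratios as independent replicates within a protocol
  ignores within-scan correlation; with one specimen per protocol the
  comparison is of scans, not of animals.
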