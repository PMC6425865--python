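# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## IHC scoring

**Optical density and stain separation.** Pixel values of 8-bit RGB images
are converted to per-channel absorbance `OD = −log10((v+1)/256)` and
unmixed by least squares onto two configurable reference stain vectors
(haematoxylin `[0.650, 0.704, 0.286]` and DAB `[0.268, 0.570, 0.776]`,
normalized — the standard Ruifrok–Johnston pair). Negative concentrations
are clamped to zero. The `(v+1)/256` convention makes the transform an
exact inverse of the synthetic renderer's forward map, so round-trip tests
are limited only by 8-bit quantization (≈0.02 OD at mid-range).

**Positivity and scores.** Positivity is the percentage of tissue pixels
with DAB OD above a threshold (default **0.15**, configurable; the value is
comfortably between the rendered "no stain" level of 0 and the weakest
rendered stain level of 0.3, so synthetic-core recovery is robust to the
exact choice). The digital score maps positivity through intervals with
upper edges {12.5, 25, 37.5, 50, 62.5, 75, 87.5}. The published anchor
table uses integer-percent labels with gaps (25 → 26, 50 → 51, 75 → 76);
intervals are implemented half-open on the left — [0, 12.5], (12.5, 25] …
(87.5, 100] — which preserves every printed anchor and leaves no
real-valued input unmapped. The manual proportion bins do the same with
edges {25, 50, 75} and bin 0 reserved for exactly 0%.

**Dichotomization.** The low/high expression cut-point is not a property
of a single core; the default is the cohort median with ties assigned
high, exposed as a knob (`--cutpoint`). A fixed cut (e.g. 50% for
proliferation-marker proportions) can be passed directly.

**Localization.** Calls are made from mean DAB OD in a membrane ring
(cell pixels within 4 px of the boundary, by binary erosion) versus the
interior: both compartments below 0.1 OD → negative; else membranous iff
ring/interior ratio ≥ 1.5 (a stained ring over an empty interior is
membranous by convention), else cytoplasmic. The thresholds are parameters;
the defaults separate the rendered synthetic patterns cleanly.

**Exclusions.** Cores with an empty tissue mask raise
`InsufficientTissueError` and are excluded and logged by the CLI rather
than scored 0, mirroring standard TMA practice for insufficient tissue.

## Association statistics

* **Pearson chi-squared** is computed **without** Yates continuity
  correction (delegated to `scipy.stats.chi2_contingency(correction=False)`
  and unit-tested against a hand-computed `Σ(O−E)²/E` oracle). The
  no-correction convention is what reproduces the bundled published
  tables: the location test on [[33, 50], [13, 0]] gives p ≈ 5.3×10⁻⁵
  uncorrected (consistent with the published "< 0.0001") but ≈ 1.8×10⁻⁴
  corrected.
* **"Unknown" strata** are excluded from tumor-type and grade tests; the
  published grade p-value reproduces only on grades 1–4, and the
  tumor-type p only on the benign/malignant 2×2.
* **Freeman–Halton Fisher exact** (r×c) enumerates every margin-fixed
  table depth-first with infeasible branches pruned, computes table
  probabilities as `(Πrᵢ! Πcⱼ!)/(N! Πnᵢⱼ!)` via log-gamma, and sums those
  ≤ the observed probability with relative tie tolerance 1e-7 (stabilizes
  floating-point ties, same convention as R's `fisher.test`). An `N ≤ 500`
  guard bounds enumeration cost; larger tables should use chi-squared.
* **Reproduction report.** `reproduce_tables()` replays all packaged
  published tables. A computed p "agrees" with a printed one if rounding
  half-up at the printed precision reproduces it **or** truncation at that
  precision does: the packaged 3×3 localization-vs-grade table has exact
  p = 0.0109458 (confirmed against an exact rational-arithmetic
  enumerator), printed as 0.010, which is truncation. One packaged value
  (astrocytoma manual age, printed 0.77) is not reproducible from its
  printed counts under any rounding (the counts give 0.70); the report
  shows the divergence side by side rather than hiding it.
* **t-tests** are pooled-variance by default (Welch via a flag). Exact
  zero-variance inputs are resolved by their limits (identical samples
  p = 1, separated samples p = 0). No multiple-testing correction is
  applied anywhere (matching the source analyses); reports say so.

## Track analytics

Velocity is curvilinear: total path length over duration. Net displacement
over the observation window is reported separately as the
persistence-bearing "distance traveled" quantity; both are always emitted
to avoid the ambiguity between the two in informal usage. Directionality
is displacement/path length (0 for a zero-length path). Missing frames are
allowed; steps use actual Δt with no interpolation. Rose summaries bin the
final displacement angle into 12 sectors by default; zero-displacement
tracks have no angle and are counted separately.

CTCF is the exact affine formula `IntDen − area × background`; negative
values are legitimate (cell dimmer than background) and left to the
caller.

## Spheroid migration

Radii are measured about the centroid of the largest connected component,
treating the spheroid as approximately radially symmetric: core =
equivalent-circle radius √(area/π); front = outermost 1-px annulus with
occupancy ≥ 0.2 (default); edge = farthest cell pixel. A single distant
pixel therefore moves the edge but not the front. Images with two
comparably large components are rejected (crop first).

The migration index formula — `(r_zone(t) − r_core(0)) / r_core(0)` — is a
design choice made here: it is dimensionless, exactly 0 at t = 0, invariant
to pixel size, and produces the 0–0.6 magnitudes reported for glioma
spheroids over 72 h. It lives in one replaceable function
(`migration_index`). At t = 0 both zones coincide with the core by
definition, so MI(0) is set to exactly 0 rather than left to measurement
discretization. Treatment effects compare MI at a timepoint across
conditions (nearest frame with a warning if the timepoint is missing),
require ≥ 3 spheroids per arm, and flag the sign of the effect
(anti- vs pro-migratory relative to the control arm).

## Synthetic generators

All generators take explicit seeds (default constant 20190313) and are
bitwise reproducible.

* **Cohorts.** Replay mode emits a cohort whose per-covariate
  cross-tabulation equals the given counts exactly (the inverse of
  `pd.crosstab`); categories are assigned independently across covariates
  within each class, which is all the information marginal tables carry —
  joint covariate structure is *not* emulated. Sample mode draws class
  labels and conditional categories multinomially with the counts as
  expected proportions.
* **Cores.** A circular core on white background; tissue pixels carry
  haematoxylin OD 0.55, a uniformly random stained fraction additionally
  carries DAB at OD {0, 0.3, 0.6, 1.0} for intensity grades 0–3; Gaussian
  OD noise is added per stain channel. Stained pixels are spatially
  unclustered — real DAB staining is spatially correlated, so passing
  recovery tests shows the measurement chain is correct, not that it is
  robust to tissue architecture.
* **Tracks.** Persistent random walk: fixed step length `speed·dt`, heading
  turns Gaussian with variance `2·dt/persistence_time` (step-to-step
  directional correlation `exp(−dt/persistence_time)`); the ensemble MSD is
  ballistic below the persistence time and diffusive above it. Defaults
  (1-min frames, 72 h, speeds in the 0.06–0.24 μm/min range, ensembles of
  tens to hundreds of cells) match typical glioma time-lapse settings.
  Constant speed means velocity recovery is exact by construction; the
  stochastic content is in headings, hence directionality.
* **Spheroids.** Front/edge radii grow linearly (μm/h); masks are a filled
  disc to the front radius plus sparse scatter (occupancy 0.05, below the
  front threshold 0.2) out to the edge, with pixels guaranteed at the edge
  radius. `spheroid_rates_for_mi` converts target 72-h migration indexes to
  rates, used to calibrate simulations to reported MI magnitudes
  (0.09–0.56).

Because generator and measurement share stain vectors and geometry
conventions by design (so that noise-free recovery is exact), closed-loop
tests validate internal consistency and numerical correctness; they do not
validate against scanner-specific color calibration, uneven illumination,
or section artifacts in real slides.

## Problem sizes and numerical choices

Validation runs use ensembles of 200 tracks (72 h at 1-min frames),
spheroid rasters at 2 μm/px (~700² px), cores of 200 px diameter, 1000-rep
t-test calibration at n = 10 per arm, and exhaustive Fisher oracle sweeps
over all 2×2 tables with N ≤ 40 plus 200 random 3×3 tables with N ≤ 30 —
sizes at which exact enumeration and closed-form oracles are practical
while keeping the whole suite in the order of a minute. p-values are
reported in full precision in CSV output and rounded half-up only when
matched against printed values.

## Known limitations

* No nucleus-level segmentation or tracking: tracks and masks are consumed,
  not created, except by the simulator.
* The front/edge operationalization (annulus occupancy / farthest pixel) is
  a declared stand-in for protocol-specific zone definitions in prior
  spheroid-assay literature; absolute front radii depend on the occupancy
  threshold, though MI comparisons across conditions are insensitive to it.
* The manual-score path on images grades intensity from median positive
  OD against the renderer's reference levels; on real slides a human
  grade is the intended input.
* Replay cohorts carry no joint covariate structure (see above), so they
  support marginal association tests only.
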