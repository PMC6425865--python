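# gliomaquant

A tested, reusable implementation of the quantification chain used in
tissue-microarray (TMA) and migration studies of glioma: DAB
immunohistochemistry scoring, contingency-table association testing, 2D
cell-migration track analytics, and 3D spheroid migration indexing — plus a
seeded synthetic-data generator so that every stage can be validated
closed-loop against known ground truth.

It is aimed at researchers who score stained tissue cores, track migrating
cells, or measure spheroid invasion assays, and who want the downstream
numbers (scores, p-values, velocities, migration indexes) to come from
auditable, reproducible code rather than ad-hoc spreadsheets.

## What it computes

**IHC scores.** For each stained core two 0–7 scores are derived:

* manual composite = intensity grade (0–3) + stained-proportion bin
  (0: 0%, 1: 1–25%, 2: 26–50%, 3: 51–75%, 4: 76–100%);
* digital score from pixel *positivity* — the percentage of tissue pixels
  whose DAB optical density `OD = −log10((v+1)/256)`, unmixed on
  Ruifrok–Johnston stain vectors, exceeds a threshold — mapped through the
  fixed interval table 0–12.5 → 0, 12.6–25 → 1, …, 87.6–100 → 7.

Scores are dichotomized into low/high expression at a configurable
cut-point (cohort median by default, ties high). Subcellular localization
(negative / cytoplasmic / membranous) is called from membrane-ring vs
cytoplasm OD.

**Association tests.** Labeled r×c tables built from cohorts are tested
with Pearson's chi-squared (`Σ(O−E)²/E`, no continuity correction) or the
Freeman–Halton r×c Fisher exact test (exhaustive enumeration of
margin-fixed tables, summing probabilities ≤ that of the observed table).
Condition comparisons use unpaired two-sample t-tests.

**Track metrics.** For each trajectory: path length `Σ‖Δx‖`, net
displacement, velocity = path length / duration, directionality =
displacement / path length ∈ [0, 1], final migration angle (rose plots),
and corrected total cell fluorescence
`CTCF = IntDen − area × mean background`.

**Spheroid migration.** From time-lapse masks: core radius (equivalent
circle of the dense mass), migration-front radius (outermost annulus with
cell occupancy ≥ threshold) and migration-edge radius (farthest cell), and
the migration index `MI_zone(t) = (r_zone(t) − r_core(0)) / r_core(0)`.

**Synthetic data.** Cohort replay/sampling from count tables, rendered
DAB/haematoxylin cores with known stained fraction, persistent random walks
with set speed and persistence time, and linearly growing spheroid masks —
all seeded and bitwise reproducible.

## Worked example

```python
import numpy as np
from gliomaquant import (
    ContingencyTable, fisher_exact_rxc, pearson_chi2,
    PRWParams, gen_tracks, track_stats,
)

# localization vs malignancy counts from a scored TMA cohort
table = ContingencyTable(
    row_labels=("membranous", "cytoplasmic", "negative"),
    col_labels=("malignant", "benign"),
    counts=np.array([[23, 2], [12, 5], [25, 15]]),
)
print(f"Fisher exact p = {fisher_exact_rxc(table).p_value:.4f}")

age = ContingencyTable(
    row_labels=("<=25", "26-60", ">60"), col_labels=("low", "high"),
    counts=np.array([[12, 4], [29, 42], [5, 4]]),
)
chi = pearson_chi2(age)
print(f"chi2 = {chi.statistic:.2f}, df = {chi.df}, p = {chi.p_value:.3f}")

tracks = gen_tracks(PRWParams(speed=0.12, persistence_time=30.0, n_cells=200, seed=7))
stats = [track_stats(t) for t in tracks]
print(f"mean velocity = {np.mean([s.velocity for s in stats]):.3f} um/min")
```

prints

```
Fisher exact p = 0.0241
chi2 = 6.34, df = 2, p = 0.042
mean velocity = 0.120 um/min
```

The Fisher p of 0.024 says the distribution of membranous / cytoplasmic /
negative staining differs between malignant and benign cores; the
chi-squared p of 0.042 says low/high expression is associated with age
group; the recovered mean velocity equals the 0.12 μm/min the simulator
was given.

## Command line

```bash
gliomaquant demo --out demo_run --seed 1       # end-to-end synthetic run
gliomaquant reproduce-tables                   # replay packaged cohort tables
gliomaquant score-tma --manifest cores.csv --out scores.csv
gliomaquant tracks --in tracks.csv --out stats.csv
gliomaquant spheroid --manifest frames.csv --out mi.csv
gliomaquant associate --cohort cohort.csv --row age_group \
    --col expression_class --method chi2
```

Every command writes a JSON run manifest (seed, parameters, config hash)
beside its outputs.

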