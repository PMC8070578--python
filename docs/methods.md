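# Methods

This note records the models, conventions and parameter choices behind
`parscore`, and what the synthetic-data results do and do not demonstrate.

## Occlusal reference frame

All PAR traits are defined relative to the occlusal plane: displacement,
overjet and centerline *parallel* to it, overbite *perpendicular* to it.
Published index definitions never construct that plane explicitly, so the
package must.

* The plane is the total-least-squares fit (smallest singular vector of the
  centred anchor scatter) through a configurable anchor set.  The default
  anchors are the buccal cusps of the first premolars and first molars of all
  four quadrants — posterior landmarks only.  Including incisal edges (a
  common prosthodontic convention) would make the reference plane itself a
  function of overbite and overjet severity, so severe anterior traits would
  leak into every other measurement; with posterior anchors the frame is
  independent of the traits being scored.  The anchor set is a
  `GeometryConfig` field, so the incisor-inclusive convention is one
  configuration away.
* The normal is oriented toward the upper arch using the upper-minus-lower
  landmark-centroid difference, which is robust even when severe traits move
  individual landmarks across the plane.
* The sagittal (anterior) axis is the in-plane projection of the vector from
  the lower inter-molar midpoint to the lower inter-incisal midpoint.  Using
  lower-arch anchors only keeps the axis from rotating with upper-midline
  deviation.  The transverse axis completes a right-handed orthonormal triad.
* Sign conventions: overbite is the normal component of (lower incisal edge −
  upper incisal edge) — positive = overlap, negative = open bite; overjet is
  clamped at 0 from below (reverse overjet is captured by the
  anterior-crossbite count instead).
* Fewer than three non-collinear anchors raises a degenerate-frame error.

All trait measurements are invariant under rigid rotation + translation of
the dentition (verified to 1e-9 over random rigid transforms).

## Scoring thresholds and weights

The index table publishes score *ranges* per trait, not the mm breakpoints.
The defaults follow Richmond's UK conventions and ship as an editable,
YAML-serialisable `ThresholdTable`:

| trait | score 0 | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|
| displacement (mm) | ≤1 | 1.1–2 | 2.1–4 | 4.1–8 | >8 (impacted: 5) |
| overjet (mm) | ≤3 | 3.1–5 | 5.1–7 | 7.1–9 | >9 |
| overbite (coverage of lower incisor) | ≤1/3 | 1/3–2/3 | 2/3–full | full | — |
| open bite (mm) | 0 | ≤1 | 1.1–2 | 2.1–3 | >3 |
| centerline (fraction of lower incisor width) | ≤1/4 | 1/4–1/2 | >1/2 | — | — |
| anterior crossbite (teeth) | 0 | (edge-to-edge, rater-recorded) | 1 | 2 | >2 |

Measurements are rounded to 0.1 mm *half away from zero* before lookup and
interval upper bounds are inclusive — the granularity the breakpoint notation
implies.  Overbite coverage divides the overlap by a configurable lower
central incisor crown height (default 9.0 mm; crown height is not part of the
index table, so it is a config parameter).  Overbite and open bite are
treated as mutually exclusive: the signed overlap selects which table
applies.  Posterior categories per side are sagittal {good 0, <half-unit
discrepancy 1, cusp-to-cusp 2}, vertical {none 0, lateral open bite 1},
transverse {none 0, tendency 1, one tooth in crossbite 2, >1 tooth 3, scissor
bite 4}.  The UK weight scheme (anterior ×1, posterior ×1, overjet ×6,
overbite ×2, centerline ×4) is the default; alternative schemes load from
YAML.  The weighted total is an exact integer sum-product, monotone in every
component.

Component values in rating tables and reports are *weighted* (score ×
weight).  The arithmetic of published component tables identifies this
convention: a mean overjet entry of 12 with weight 6 corresponds to a raw
score of 2, and the weighted component means sum to the reported totals.
`PARScore` retains both the raw components and both totals.

Missing/extracted teeth: a contact pair bridging an unreplaced space is
excluded from displacement scoring; if the space is flagged for prosthetic
replacement, the flanking teeth's facing contacts form a scoreable bridging
pair.  A segment with fewer than two scoreable teeth is skipped and recorded.

## Agreement statistics

* **Dahlberg error**: `sqrt(Σ dᵢ² / 2n)` over n duplicate pairs.  The MSD
  criterion compares it with the *minimum standard deviation*, implemented as
  the smaller of the two compared series' sample SDs (n−1 denominator
  throughout); "minimum SD" has no standard algebraic definition, so this
  reading is recorded in the report metadata.
* **ICC**: two-way random effects, absolute agreement, single measures —
  ICC(2,1)/ICC(A,1) — from the ANOVA mean squares, with the F-based 95% CI
  (Satterthwaite degrees of freedom).  This is the conservative choice for a
  design that crosses raters and methods with subjects.  An all-constant
  stratum (every post-treatment overjet score is 0, say) has no
  between-subject variance: the estimate is reported as an explicit
  *undefined* marker, never NaN and never a spurious 1.0.  The estimate and
  CI agree with an independent mean-squares oracle and with
  `pingouin.intraclass_corr` in the tests.
* **Paired t**: standard two-sided paired test; an all-zero difference vector
  returns t = 0, p = 1 flagged degenerate rather than NaN.
* **Bland–Altman**: bias = mean difference, limits of agreement = bias ±
  1.96·SD of differences; the per-pair (mean, difference) points are kept for
  plotting.  The bias equals the paired-t mean difference by construction.
* **Walter sample size**: `n = 1 + 2k(z_{α/2}+z_β)² / [(k−1)(ln C₀)²]` with
  `C₀ = (1+kθ₁)/(1+kθ₀)`, `θ = ρ/(1−ρ)`, rounded up.  The two-sided critical
  value is used; at (ρ₀ = 0.80, ρ₁ = 0.96, α = 0.05, power 0.80, k = 2) the
  raw value is 11.93 → 12 subjects.
* **Report layout**: intra-rater strata compare session 1 vs session 2 within
  (trait, timepoint, method, rater); inter-rater and method-comparison strata
  use each arm's *second* session, the convention of inter-rater reliability
  tables.  One row per stratum carries mean (SD) per arm, Dahlberg error,
  MSD, ICC with CI, p-value and Bland–Altman quantities.  No multiplicity
  correction is applied (mirroring common practice in this literature); the
  number of tests is recorded in the table metadata.

## Synthetic data

`simulate_ratings` emulates the crossed design of a digital-vs-manual PAR
validation study: 15 subjects × 2 timepoints × 2 methods × 2 raters × 2
sessions.  Each subject-stage has true traits drawn from a severity profile;
each measurement is `truth + method offset + rater offset + session error`,
applied in millimetres at trait level and then pushed through thresholds and
weights.  Defaults (frozen at design time):

* **T0 profile**: per-pair displacements = subject severity factor
  (log-normal, σ = 0.35) × Gamma(1.5, 1.5 mm); overjet ~ N(6, 2) mm clipped
  at 0; overbite overlap ~ N(5, 2.5) mm with a 10% open-bite branch;
  centerline deviation ~ Exp(1.2 mm); per-side probabilities: sagittal
  discrepancy 0.25, lateral open bite 0.05, transverse crossbite 0.20.  This
  yields weighted totals ≈ 31 ± 10 — a severely maloccluded cohort.
* **T1 profile**: residuals an order of magnitude smaller (e.g. displacements
  ~ Exp(0.35 mm), overjet ~ N(2.0, 0.3) mm), giving totals ≈ 1 ± 1.3 and
  essentially always-zero overjet/centerline scores, which exercises the
  undefined-ICC reporting path.
* **Noise**: method and rater offsets ~ N(0, 0.05 mm) drawn once per study;
  session error SD 0.10 mm per measurement; posterior categories mis-recorded
  one step off with probability 0.02.  Digital and manual are equally noisy
  by default (`manual_extra_mm` adds caliper noise if wanted).  These
  magnitudes produce total-PAR Dahlberg errors around 1 score point against
  between-subject SDs around 10.
* **Reproducibility**: one integer seed feeds a `SeedSequence`; the study
  stream and each subject get spawned substreams, so enlarging the design
  does not reshuffle existing subjects.

`generate_dentition` places landmarks on semi-elliptical arch templates with
standard crown widths and *encodes* the sampled traits exactly: contact
displacements as in-plane radial offsets of the facing contact, overjet and
overbite via the upper incisal-edge position relative to the lower labial
surface, centerline as a transverse upper-midline offset, transverse
posterior categories as buccal-cusp offsets on non-anchor teeth.  The
round-trip invariant — `extract_traits` recovers the sampled truth to 1e-6 mm
on noiseless landmarks — is what licenses using the generator as ground truth
for the geometry layer.

What the generator does **not** emulate: mesh/scan artefacts, landmark
identification ambiguity on rotated or worn teeth, sagittal and vertical
posterior relations in geometry (they need occlusal-surface information
beyond the landmark vocabulary and are passed through as categorical rater
input), the edge-to-edge anterior crossbite grade, rater drift over time, or
any systematic digital-vs-manual difference.  Passing tests therefore show
the pipeline is internally correct and statistically calibrated, not that a
particular clinical scanner workflow is valid.

## Problem sizes and tolerances in the test suite

ICC parameter recovery uses 500 subjects × 2 ratings × 10 seeds per target
ICC ∈ {0.5, 0.8, 0.95} with a ±0.02 band on the mean estimate: score
discretisation is absent there by design (continuous scale), so the band
reflects pure Monte-Carlo error.  The error-below-MSD property uses 100
seeded replicates of the full 15-subject crossed study and requires ≥95% of
replicates to satisfy it for the total PAR in every stratum.  Geometric
invariance uses 100 random rigid transforms at tolerance 1e-9.  Statistical
oracles (mean-squares ICC, textbook t, direct Dahlberg/Bland–Altman) are
matched to 1e-9 on ≤10-subject fixtures.

## Known limitations

* Strata whose two arms are *both* constant have Dahlberg error 0 and MSD 0;
  the strict `error < MSD` flag is false there even though the agreement is
  perfect.  The report keeps the raw numbers so the reader can see why.
* At 15 subjects with near-zero treated-stage severity, simulated T1 ICCs for
  individual components fluctuate widely across seeds (discretised scores,
  tiny between-subject variance); point values below 0.95 on some seeds are
  expected behaviour of the estimator at that sample size, not a pipeline
  defect.
* The threshold breakpoints, crown height, and crossbite classification
  margins are conventions, shipped as config rather than constants baked into
  code, because the index table itself does not fix them.
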