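# Methods

## Problem and scope

Preoperative CT is the planning backbone of abdominal wall reconstruction
(AWR), yet radiology reports frequently omit the hernia-specific features
surgeons need.  This package implements a two-part analysis around a fixed
catalog of 16 CT-based planning parameters:

1. a **documentation-completeness audit** that scores each parameter as
   documented / not documented per report and compares documentation
   against intraoperative ground truth, and
2. an **AHP-weighted multi-criteria decision analysis (MCDA)** that fuses
   three evidence sources — literature citation frequency, an expert-panel
   consensus rank, and a surgeon importance survey — into a prioritization
   with three tiers, whose top tier is the STAMP-C essential panel
   (Size/defect width, Tanaka index, Anatomical EHS location, Mesh
   presence, Plane of old mesh, Concurrent inguinal + parastomal/stomal
   hernias).

The underlying registry, report, and survey data are not public; a seeded
synthetic-cohort generator reproduces their published statistical structure
and serves as the test bed.  Published summary tables (prevalences,
documentation counts, survey moments, final MCDA scores, AHP weights) are
treated as *reference inputs* (`stampc.reference`), not as recomputable
outputs.

## Audit model

Each parameter is *generalizable* (readable from the image alone; 8
parameters) or *patient-specific* (meaningful only against surgical
history; 8 parameters).  The documentation rate is

- generalizable: `100 * documented / cohort_n`,
- patient-specific: `100 * documented / occurrence_n`, where occurrence is
  the intraoperative ground-truth count.  These rates may exceed 100%:
  radiologists call sub-threshold findings (e.g. small inguinal hernias)
  that surgery does not confirm.

The old-mesh-plane denominator is the prior-mesh-present count (a plane
exists exactly where mesh does).  A patient-specific rate with zero
occurrences is an error (undefined), never reported as 0.

Summaries are medians with ranges, midpoint convention (mean of the two
central order statistics for even counts), computed per category and over
the pooled 16 rates.  Percent display rounds half-up to one decimal; all
numeric comparisons in tests carry a ±0.1 point tolerance, absorbing the
inconsistent last-digit rounding of the source tables.  Of note, the
pooled midpoint median of the 16 published rates is 32.0; the published
overall headline of 34.4 equals the midpoint of the 9th/10th order
statistics rather than the 8th/9th, an arithmetic that no standard median
convention produces.  The package reports the midpoint median and
documents the discrepancy rather than reproducing it.

## Synthetic cohort

`GeneratorConfig` defaults encode the study conditions: 834 patients,
prevalences (prior mesh 0.711, fracture 0.101, migration 0.092, inguinal
and parastomal 0.041 each, wall abnormality 0.300, ongoing SSO 0.277),
mesh-plane mix (onlay 0.30 / sublay 0.56 / underlay 0.14 among
mesh-present patients), defect width ~ N(17.0, 6.8²) cm and length ~
N(24.0, 6.2²) cm truncated at 0, and prior-repair counts drawn from the
published 1–5+ distribution.  Mesh fracture and migration are sampled only
among mesh carriers at conditional rates `prevalence / mesh_prevalence`,
so the configured *marginal* prevalences hold.

Documentation is sampled per parameter:

- generalizable: Bernoulli with the published report rate (e.g. defect
  width 0.326);
- patient-specific: two channels, `P(doc | present)` and `P(doc | absent)`.
  The absent channel is the over-calling mechanism; for the four over-called
  parameters (fracture, migration, inguinal, parastomal) the present-channel
  probability is fixed at 0.5 and the absent channel solved in closed form
  so the expected documented/occurrence ratio equals the published one
  (1.036, 1.117, 2.412, 2.353).  The split between the channels is not
  identifiable from the published marginals; 0.5 is a neutral choice, and
  `solve_doc_given_absent` makes any other split easy to explore.
  Under-documented parameters use `P(doc | absent) = 0` and
  `P(doc | present)` equal to the published %-of-occurrence.
- old mesh plane: sampled only among patients whose mesh presence is
  itself documented, at the conditional rate `0.017 / 0.362`, which
  enforces plane-documentation ⊆ mesh-documentation while preserving the
  published 1.7% marginal.

One global seed expands into fixed substreams (registry / reports /
survey) via `SeedSequence([seed, stream])`, so each stage regenerates
independently and byte-identically.

### Likert survey model

Ratings are modeled as `round(clip(N(mu, sigma), 1, 10))`.  For each
parameter, (mu, sigma) is calibrated by least squares on (mu, log sigma)
so the *exact* moments of the induced 10-point pmf match the published
mean/SD within 1e-3.  Truncation bias is substantial: the published defect
width rating (9.16 ± 2.02) requires a latent N(14.8, 6.56²) — most of the
mass clamps to 10 and a long left tail supplies the spread.  Infeasible
moment pairs (e.g. mean 9.99 with SD 2) raise a calibration error carrying
the numerically probed feasible SD range.  A target SD of 0 bypasses the
solver: all ratings equal the rounded mean.

What the generator does *not* emulate: correlated ratings within raters,
geographic or specialty clustering, non-response, per-radiologist
documentation styles, and any linkage between a patient's findings and the
probability their report is thorough.  Passing tests therefore demonstrate
that the pipeline arithmetic is correct under the published marginal
structure, not that real reports behave this way.

## AHP engine

Weights come from a positive reciprocal pairwise-comparison matrix
(Saaty 1–9 scale).  Default extraction is the principal right eigenvector
by power iteration (convergence 1e-12 in max norm, 10,000-iteration cap);
row geometric means are the cross-check method.  `lambda_max` is the mean
of the component-wise Rayleigh ratios `(Mw)_i / w_i` (exact at the true
eigenvector), `CI = (lambda_max − n)/(n − 1)`, `CR = CI / RI(n)` with
Saaty's classic random-index table (n ≤ 10; CR ≡ 0 for n ≤ 2); CR < 0.10
flags acceptable coherence.

The two extraction methods coincide exactly for perfectly consistent
matrices and — a useful special case — for *any* reciprocal 3×3 matrix,
which is the order used here (three evidence sources).  For n ≥ 4 their
disagreement grows roughly linearly with CR (about 1e-5 at CR ≈ 0.01 for
n = 5), so near-identity claims should be read at small CR.

The study's own 3×3 judgment matrix is supplementary-only; its published
weights (0.406 / 0.323 / 0.271) and CR (0.082) are reference inputs.  The
engine validates matrices (diagonal, reciprocity to 1e-9, scale bounds —
violations in strict mode, warnings otherwise) and is exercised against a
dense eigen-decomposition oracle in tests.

## MCDA prioritization

Source columns are normalized (default `sum_to_100`; `min_max` and
`z_score` available, both rejecting constant columns), combined as
`final = scale · Σ w_s · normalized_s`, sorted descending and cut into
tiers at (9.0, 6.0): Tier 1 "Essential" (score ≥ 9.0, boundary closed),
Tier 2 "Highly Recommended", Tier 3 "Recommended".  Ties break by catalog
order with consecutive ranks.  STAMP-C membership is Tier-1 membership;
if the Tier-1 set differs from the canonical 7, a warning is attached and
the panel is still emitted from the tiers as computed.

The published final scores (14.51 down to 3.58, summing to ≈ 134) cannot
be reproduced from the published marginals because the per-source raw
scores and their normalization are supplementary-only; the scores are
therefore loadable reference inputs, and the 9.0/6.0 thresholds belong to
that published scale.  On the package's own sum-to-100 scale the scores
sum to 100 (mean 6.25), so the same thresholds partition differently —
the reference-route/simulated-route split in `analysis/03` makes this
explicit.  Tier thresholds are taken as given numbers; no natural-breaks
clustering is re-derived.

Sensitivity analysis draws weight vectors from
`Dirichlet(concentration · baseline)`, re-ranks per draw, and reports the
fraction of draws whose top-k identity set (k = baseline Tier-1 size)
matches the baseline, plus the mean Kendall tau against the baseline
ranking.  Dirichlet centering is the package's choice of simplex
perturbation; concentration 100 keeps draws within a few percent of the
baseline weights.

## Supporting statistics

Cohen's kappa is implemented from `(po − pe)/(1 − pe)` for binary rater
pairs (the three-reviewer design yields three pairwise kappas; po = pe = 1
is reported as kappa 1).  The 2×2 chi-square uses the closed form
`n(ad − bc)²/((a+b)(c+d)(a+c)(b+d))`, df = 1, optional Yates correction,
p-value from the chi-square survival function.  Likert summaries report
sample mean and SD (n − 1 denominator; undefined, not 0, at n = 1).  Both
statistics are cross-checked in tests against scikit-learn and scipy
implementations, which are never used as the computation path.

## Problem sizes and numerics

Default analyses run at the study scale (834 patients, 61 raters, 500
sensitivity draws).  Law-of-large-numbers recovery checks run once at
n = 50,000, where direct documentation rates recover configured values
within 2 percentage points and over-call ratios within 5% (the ratio's
denominator is itself random, so its relative noise at this n is ~2.5%).
Power iteration tolerance 1e-12; Likert calibration tolerance 1e-3 on both
moments; weight-sum and reciprocity tolerances 1e-9.

## Known limitations

- Single-valued mesh plane per patient, although real cohorts carry
  co-existing planes; the dominant plane is recorded.
- The expert-audit rank column and the literature-frequency column are
  reference reconstructions scaled from the published ordering (the
  underlying per-source tables are supplementary-only) — synthetic stand-ins,
  labelled as such where written.
- No free-text report parsing, imaging I/O, per-radiologist effects, or
  accuracy (as opposed to completeness) assessment.
- The chi-square interface is generic: the intention-vs-practice counts it
  was used for in the source analysis are not published.
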