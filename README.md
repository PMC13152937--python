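# stampc

Documentation-completeness auditing and multi-criteria prioritization of
CT parameters for abdominal wall reconstruction (AWR) planning.

Surgeons planning complex ventral hernia repair rely on preoperative CT,
but radiology reports routinely omit the features that drive operative
decisions — defect dimensions, prior mesh and its anatomical plane,
loss-of-domain indices.  This package provides, for health-services
researchers and hernia-surgery groups auditing their own reporting
practice:

- a fixed **catalog of 16 CT-based planning parameters**, split into 8
  *generalizable* (readable from the image alone) and 8 *patient-specific*
  (meaningful only against surgical history);
- a **completeness audit**: per-parameter documentation rates with
  category-appropriate denominators — generalizable rates against the
  cohort, patient-specific rates against intraoperative occurrence counts,
  so rates above 100% expose radiologist over-calling — plus median/range
  summaries;
- an **AHP engine** (Saaty reciprocal matrices → principal-eigenvector
  weights, λmax, CI, CR with the classic random-index table);
- an **MCDA prioritizer**: normalize three evidence sources (literature
  frequency, expert-audit rank, surgeon-survey mean), aggregate with AHP
  weights, rank, cut into tiers at scores (9.0, 6.0), and extract the
  Tier-1 **STAMP-C panel** — **S**ize (defect width), **T**anaka index,
  **A**natomical location (EHS), **M**esh presence, **P**lane of old
  mesh, **C**oncurrent inguinal/parastomal hernia — with a Dirichlet
  weight-perturbation sensitivity analysis;
- a seeded **synthetic-cohort generator** (registry ground truth, report
  flags with an explicit over-call channel, truncated-rounded-normal
  Likert surveys calibrated to published moments) standing in for the
  non-public study data;
- supporting statistics: pairwise Cohen's kappa, 2×2 chi-square, Likert
  summaries.

The core quantities: a parameter's documentation rate is
`100 · documented / denominator`; AHP weights solve `M w = λmax w` for the
reciprocal judgment matrix `M`, with `CR = (λmax − n)/((n − 1) · RI(n))`;
final MCDA scores are `Σ_s w_s · norm_s(p)`, tiered at ≥ 9.0 / ≥ 6.0.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1     # registry, reports, survey
python analysis/02_audit_completeness.py           # rates + medians
python analysis/03_prioritize_parameters.py        # AHP + MCDA + STAMP-C
python analysis/04_weight_sensitivity.py --seed 1  # Dirichlet stability
python analysis/05_agreement_stats.py --seed 1     # kappa / chi2 / Likert
```

The audit step prints simulated vs published rates side by side and ends
with

```
medians (simulated): generalizable 23.9% (published 24.2%),
patient-specific 91.6% (published 87.8%), overall pooled 30.3%
```

— the simulated cohort recovers the published category medians within
sampling noise at n = 834: under-documentation of generalizable features
(median ≈ 24%), and patient-specific rates whose median sits near 90%
only because over-called findings (inguinal hernias documented at ≈ 230%
of their occurrence) offset near-absent ones (old mesh plane ≈ 1.5%).
The prioritization step prints

```
reference route: tier sizes (7, 3, 6) (published 7/3/6); STAMP-C panel:
  S: defect_width
  T: tanaka_index
  ...
simulated route (sum-to-100 scale): top-7 overlaps the published panel
on 7/7 parameters
```

— feeding the published final scores through the tiering logic reproduces
the published ranking and the 7-parameter panel exactly, and the
simulated sources put the same 7 parameters on top.  The sensitivity step
reports top-tier identity stable in 100% of 500 weight draws with mean
Kendall tau 0.99.

The same stages are available as subcommands of the `stampc` CLI
(`simulate`, `audit`, `ahp`, `prioritize`, `sensitivity`, `stats`,
`run-all`), and `stampc run-all` writes the full artifact set — including
a STAMP-C-structured `report.md` and a checksum manifest that is
byte-identical across reruns with the same seed.

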