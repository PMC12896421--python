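# Methods

## Model

The ALBI score is linear in albumin and in log10 bilirubin:

```
score = c_b · log10(bilirubin [µmol/L]) + c_a · albumin [g/L]
```

with published coefficients `c_b = 0.66`, `c_a = −0.085` and grade
thresholds −2.60 (grade 1/2) and −1.39 (grade 2/3), both inclusive from
below. Inputs are conventional laboratory units (albumin g/dL,
bilirubin mg/dL), converted internally by the factors 10 and 17.1. All
constants are exposed on `AlbiParameters`.

**Score precision.** Grades are assigned from the score rounded to two
decimals (`score_decimals=2`), the precision at which ALBI scores are
conventionally reported. This is not a cosmetic choice: on the 0.1
reporting lattice one cell, (albumin 4.1, bilirubin 1.3), scores
−2.59600 — grade 2 under raw double-precision thresholding but grade 1
at reporting precision — and the two-decimal convention is the one that
yields the canonical 399/246 grade partition of the 645 eligible cells.
No lattice score is a round-half tie, so the rounding mode is
immaterial there. Set `score_decimals=None` for raw thresholding.

## Grid derivation

Lattice coordinates are integers in tenths end to end; values are
converted to physical units only when scoring. This avoids the
endpoint drift of floating-point ranges (0.1 is not representable in
binary). The default grid is albumin 3.1–5.5 g/dL × bilirubin
0.3–3.0 mg/dL (25 × 28 = 700 points); the CP-B combination box
(albumin ≤ 3.5 with bilirubin ≥ 2.0, inclusive on both edges, 55
points) is removed, leaving 645 eligible cells.

Steps must be multiples of 0.1; anything else is rejected rather than
silently rounded. For a coarser step the lattice consists of the
integer multiples of the step inside the bounds, so the 0.2-step
sensitivity grid is albumin 3.2–5.4 × bilirubin 0.4–3.0 (156 eligible
cells) — the unique even-tenths convention consistent with the
published sensitivity counts.

## Zone rules

Seven axis-aligned rectangles defined by albumin cutoffs 3.5/4.0/4.4
and bilirubin cutoffs 1.0/2.4. Boundary conventions, chosen to match
the printed zone sizes: albumin exactly 3.5 belongs to `Al-Low-2` (the
low-albumin rule takes precedence over the intermediate band), albumin
exactly 4.4 to `Al-High-1`, and bilirubin thresholds are inclusive from
above. The cohort analytic box admits albumin 3.0 g/dL (mapping to
`Al-Low-2`) although the derivation grid starts at 3.1, because
measured cohorts contain 3.0 readings. `classify_zone` is total on the
positive quadrant: values outside the box return an `out-of-range`
sentinel and the CP-B combination a `CP-B` sentinel, neither of which
carries a grade claim.

On the 0.1 lattice the five decided zones are pure (one formula grade
each) and the three-step classifier therefore agrees with the formula
on 100% of the 645 cells. In continuous albumin/bilirubin space the
straight cutoffs approximate a curved grade boundary, so two thin
discordant slivers exist: the corner of `Int-Better-1` adjacent to
(4.0, 1.0), and the albumin ≈ 4.31–4.4 strip of `Bi-High-2`.
Area-weighted agreement across the decided zones remains above 99%
under uniform sampling; `concordance_analysis` quantifies this per
zone, in continuous or lattice (`deci`) precision.

## Cohort pipeline

Stages, in order: same-day pairing (patient-dates with both analytes;
long analyte/value schemas are pivoted, duplicated analytes keep the
last row in file order with a warning); per-patient deduplication to
the most recent record (date ties: last in file order, logged);
stage-1 CP-A range restriction (albumin < 3.0, bilirubin > 3.0, CP-B
combination — the combination exclusion is a config toggle,
`apply_cpb_combo_exclusion`, enabled by default so that the analytic
cohort matches the derivation region); stage-2 extreme-value exclusion
(albumin > 5.5, bilirubin < 0.3). Removals are attributed to the first
failing rule, so the per-rule log decomposes the funnel exactly.

Subgroups are defined by ICD-10 codes (CLD: any of B18, B19, K70, K73,
K74, C22; HCC: C22) and overlap the total cohort. The goodness-of-fit
test is a Pearson chi-square of subgroup zone counts against the
overall cohort's zone proportions (`scipy.stats.chisquare`, df = k−1).
Using the total cohort as reference despite the subgroup being part of
it is the convention this pipeline validates; the non-independence is a
known caveat and is deliberately not corrected. Zones empty in the
total cohort are dropped from the test (they are necessarily empty in
any subgroup), reducing df accordingly.

## Synthetic cohort generator

Emulates a multi-hospital laboratory extract for one calendar year:

- **Zone mixture** — each clean patient's final record is drawn from a
  configurable zone mixture, uniformly over the zone's 0.1-lattice
  cells (zone totals are all the real cohort constrains; uniform-
  within-zone reproduces every statistic the pipeline tabulates). The
  default weights are the zone frequencies of a 7,583-patient
  real-world CP-A cohort and its CLD (n = 2,325) and HCC (n = 1,130)
  subgroups. Overlapping subgroup mixtures are realised by differencing
  into three disjoint strata (non-CLD, CLD-only, HCC); negative
  differences are rejected at setup.
- **Contamination** — applied sequentially per patient: 19.6% receive
  out-of-CP-A values (low albumin, high bilirubin, or the CP-B
  combination), then 5.7% of the in-range remainder receive near-zero
  bilirubin (0.1–0.2 mg/dL) and 0.01% supra-physiologic albumin
  (> 5.5 g/dL), so a 10,000-patient draw filters to ≈ 8,040 in-range
  and ≈ 7,580 analysable patients in expectation. These are soft
  (generative) rates, not assertions.
- **Visits** — each patient gets 1 + Poisson(`visit_rate`, default 1)
  distinct lab dates; the chronologically last carries the intended
  values, earlier dates are decoys drawn from the overall clean
  mixture. The real visit-count distribution is unknown; Poisson is a
  stand-in. A ground-truth table records each patient's intended zone,
  stratum and retained record, so deduplication can be asserted exactly
  (100% recovery), not just statistically.
- **Codes** — HCC patients always carry C22 (60% with an additional
  CLD code); CLD-only patients carry one or two CLD codes; 30% of
  unaffected patients carry an unrelated comorbidity code (I10) to
  exercise the matcher.

What the generator does *not* emulate: within-zone clinical clustering
(real cohorts concentrate near normal values, e.g. the real `Bi-High-2`
fraction is far below the lattice-uniform one), analyte measurement
error and inter-laboratory calibration differences, longitudinal
trajectories, and non-hepatic confounders (Gilbert syndrome,
malnutrition). Passing recovery tests therefore demonstrates that the
pipeline measures what the generator planted — not that real cohorts
follow the generated distribution.

## Problem sizes and numerical choices

Grid work is exact and sub-second (645 and 156 cells). Statistical
checks use: 10,000 synthetic patients for mixture recovery (each zone
proportion within 3 binomial SE of its weight); 1,000 replicates of
n = 2,000 multinomial draws for chi-square type-I calibration at
α = 0.05 (±3 SE); 2–3·10⁵ uniform samples for continuous concordance;
and a 0.002-resolution dense scan as the oracle locating the two
discordant slivers. All randomness flows through
`numpy.random.default_rng` with explicit seeds; cohorts are
byte-identical across runs at a fixed seed.

## Limitations

- The package audits the published cutoff set; it does not search for
  optimal alternative cutoffs.
- No prognostic/survival analysis: the zones classify hepatic reserve,
  they are not validated here against outcomes.
- Grade 3 cannot occur inside the CP-A box; the grade tables carry a
  grade-3 row only for completeness on out-of-scope inputs.
- The chi-square subgroup test inherits the overlapping-reference
  caveat described above.
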