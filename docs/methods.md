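# Methods

## Scales and classification rules

The **Zulfiqar Frailty Scale (ZFS)** is a six-item binary screening
questionnaire for frailty in ambulatory patients aged 65+: weight loss ≥ 5%
in six months, monopodal stance < 5 s, living alone, presence of aid at
home, memory complaint, and polypharmacy (≥ 5 therapeutic classes).  The
score is the count of "yes" answers; 0 is *robust*, 1–2 *pre-frail*, and ≥ 3
(the published cut-off, exposed as a parameter so threshold sweeps reuse the
same classifier) *frail*.

The criterion instrument is the **modified SEGA grid A** (Short Emergency
Geriatric Assessment, part A): thirteen items each coded 0/1/2 by the
clinician, total out of 26; totals ≤ 8 are *not frail*, 9–11 *frail*, > 11
*very frail*.  The binary criterion used throughout validation is total > 8.
This package consumes already-coded item values; the clinical rubric mapping
a patient to 0/1/2 per item is published separately and is out of scope.

Missing answers are rejected, never imputed or prorated: the scales were
validated under complete administration only.  In lenient batch mode an
incomplete record is dropped with its identifier logged, not silently mended.

## Diagnostic accuracy machinery

Item-level validation crosses each binary item against the frailty criterion
in a 2×2 table (tp, fp, fn, tn) and reports sensitivity, specificity, PPV,
NPV, the Youden index, and the risk ratio
RR = (tp/(tp+fp)) / (fn/(fn+tn)) — the risk of being criterion-frail among
item-positives over the risk among item-negatives.  All six published risk
multipliers match this formula exactly, so it is canonical here (none are
odds ratios).  Metrics are stored as proportions and rendered as whole
percentages only in reports, matching the source display precision.  A
metric with a zero denominator is an explicit `None`/flag, never a silent 0,
so batch reports cannot fabricate values.

Association p-values follow the standard small-count rule: Fisher's exact
test (two-sided, point-probability rule) when any expected cell count is
below 5, otherwise the chi-square test with Yates continuity correction.
The rule is inferred from reproducing the printed p-values (0.013 on the
weight-loss table, whose smallest expected count is 1.18; 0.007 on the
memory comparison, smallest expected count 12.35); the original analysis
does not name its tests.  Degenerate margins return p = 1 with a flag.

Confidence intervals are an extension beyond the original report (which
prints none for these metrics): Wilson score intervals for proportions and
the Katz log-method interval for risk ratios, both at 95% by default, with
no continuity adjustment for zero cells (the interval is flagged undefined
instead).

## ROC analysis and the reconstruction of the score distribution

The operating-characteristics table evaluates "positive iff score ≥ c" for
every integer c.  The AUC is computed as the tie-corrected rank statistic
P(score_pos > score_neg) + ½·P(equal) and, on every call, cross-checked
against the trapezoidal area under the empirical ROC polygon to 1e-12; the
two are mathematically identical on empirical data, and the dual computation
guards against off-by-one threshold bugs.  The Youden-optimal cut-point
breaks ties toward the lowest threshold, favouring sensitivity, consistent
with the scale's screening purpose.

The published cut-point table gives *cumulative* sensitivity and 1 −
specificity per threshold.  `reconstruct_distribution` recovers per-score
patient counts by scaling those fractions by the group sizes (20 frail, 82
not frail), requiring each scaled value to land within 0.02 of an integer
(the printed fractions are exact counts over group size, e.g.
0.1951 × 82 = 15.998), then differencing adjacent thresholds.  Two reading
decisions are recorded prominently:

* The published threshold labels ">k" are interpreted as **"score ≥ k"**:
  under that reading the first row yields 87 screen-positives and the third
  row 36 frail patients, both matching the printed classification counts;
  the literal ">" reading matches neither.
* Scores ≥ 5 are collapsed onto 5 (the table stops there).  The collapse is
  validated by recovering the printed cohort mean 2.1 and SD 1.35 of the
  ZFS total from the pooled reconstructed scores.

The printed summaries are not perfectly mutually consistent: the item-level
counts imply a total of 212 item-positives while the reconstructed score
distribution sums to 214 points.  Consequently no single item-level cohort
can reproduce both at once, and `reference.reconstructed_cohort` carries
*synthetic* item patterns valid only for total-score analyses; item-level
results always come from the embedded contingency tables.

A related print inconsistency: the scale is elsewhere listed with "5" items
and a 63.7% prevalence; the item table defining six elements is followed
here.  The printed "frailty according to ZFS: yes 87" is the score ≥ 1
screen-positive count (pre-frail + frail), not the ≥ 3 frail count of 36;
reports expose it under that name.  The printed IADL annotation "/4" with
mean 7.04 is kept verbatim and flagged (IADL is conventionally /8).

## Correlations

Binary items enter Pearson correlations as 0/1 numerics (so item-item
correlations are phi coefficients) and ordinal items as 0/1/2 numerics —
the only reading under which the near-1 published twin-pair entries are
attainable.  The cross-scale total-score correlation carries a Fisher
z-transform interval tanh(atanh r ± z/√(n−3)).  Undefined correlations
(constant inputs) are NaN sentinels, never 0.  The published 6×13 item
matrix was computed on raw data that were never deposited, so its individual
entries are treated qualitatively only: the structural claim the package
reproduces is that near-duplicate ("twin") pairs dominate their rows.

## Synthetic cohorts

`simulate.generate_cohort` draws, per patient, a standard-normal latent
frailty f; each item observes y = λ·f + ρ·g + √(1−λ²−ρ²)·ε (unit variance),
where g is a residual shared by the two members of a twin pair, and is
thresholded at Φ⁻¹(1−p) so its marginal hits the target prevalence exactly
in expectation (two thresholds for ordinal items).  One seeded stream per
column (factor, pair residuals, items, demographics, in a fixed documented
order) makes cohorts byte-reproducible and stable under appending items.

Default study conditions: the six ZFS marginals are the published item
prevalences (e.g. weight loss 6/102); demographic moments (age 76 ± 8,
weight 74 ± 15, …) and the 55/47 sex split are the published cohort
description; age gets a small positive loading (0.35) on the latent factor
since frailty rises with age.  The thirteen ordinal marginals are not
published per item and were chosen as plausible for an autonomous ambulatory
65+ population (heavier scoring on age, comorbidity and medications; lighter
on nutrition and meals).  Loadings and twin couplings were calibrated once
with `scripts/calibrate_simulator.py` so that, simultaneously, the
cross-scale total correlation lands near 0.81 and the criterion-frailty
prevalence near 19.6%; the frozen defaults give r ≈ 0.81 and prevalence
≈ 21% at large n.  A single factor plus per-pair residual coupling is the
simplest structure able to reproduce the published marginals, the twin-pair
dominance, and a high totals correlation at once; a full 19×19 correlation
target is unidentifiable from the printed summaries and is not attempted.

What the generator does *not* emulate: the mSEGA total's printed SD (3.11 —
the single-factor structure that achieves the high totals correlation
inflates it to ≈ 4.3), item-level missingness, longitudinal change, and
outcome events (falls, hospitalisation).  Passing simulator-based tests
therefore demonstrates correct machinery under the stated copula, not
distributional fidelity of every published moment.

## Problem sizes and numerical choices

Headline results are desk-scale: they derive from 102 patients' summary
tables and run in milliseconds.  Simulator checks use n = 10⁴ (marginal
recovery within 3 binomial SEs, coupling monotonicity) and n = 5000
(cohort-level calibration bands ±0.08 on r, ±5 pp on prevalence); structural
ROC/AUC equivalences use 10³ random small distributions.  Reconstruction
tolerance is 0.02 patients per scaled cumulative count; AUC dual-computation
tolerance is 1e-12; correlation/CI closed forms are evaluated in double
precision without iteration.

## Known limitations

* Item-level and score-level published tables disagree by 2 points; the
  package reproduces each table from its own source rather than forcing a
  joint cohort.
* The exact published item correlation matrix and the exact r = 0.81 are
  irreproducible without the raw data; they are covered by structural and
  calibration checks only.
* Confidence intervals are the package's addition and are labelled as such
  in reports.
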