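# Methods

## The scale and its arithmetic

The mVDS is a 9-item ordinal checklist; each item's levels are ordered
best→worst and carry non-decreasing point weights starting at 0, with the
per-item worst weights summing to exactly 100. Weights are half-point
granular (11.5, 8.5, …), so they are stored internally as integers in
half-point units: totals and per-item breakdowns are computed in integer
arithmetic and divided by two on output, making additivity exact (no
floating-point drift) and equality tests safe. Level indices are 0-based
with 0 = best, so "best level carries weight 0" is a uniform invariant.
Profiles must be complete — every item rated exactly once; partial
profiles are rejected rather than imputed, since the scale defines no
partial-administration rule.

The aspiration item is derived from the Penetration–Aspiration Scale by
`pas_to_aspiration_level`: PAS 1 → intact, 2–5 → penetration, 6–8 →
aspiration. Only the ">5 means aspiration" boundary is externally fixed;
mapping 2–5 to penetration is the standard PAS reading and the only
monotone mapping consistent with a 3-level item.

The scale ships both compiled-in and as a YAML config
(`src/mvds/data/mvds_scale.yaml`); loading a config re-validates the
weight-sum invariant, and export→import round-trips bit-exactly.

## Synthetic cohorts

The generator emulates the structure of a retrospective single-centre
stroke cohort (n = 56) whose patient-level data are unavailable. Per
patient:

1. **Latent severity** `s ~ N(severity_mean, 1)`. Each item's latent value
   is `s + e`, `e ~ N(0, item_noise_sd)`; the true ordinal level is
   obtained by thresholding. The shared factor induces the positive
   inter-item correlation a severity scale presumes; the item noise
   controls how much of the total-score variance is idiosyncratic.
2. **Thresholds** are fixed from the published per-item score marginals
   (converted to level-exceedance probabilities under a unit-normal
   severity). The published table is internally inconsistent — its item
   means sum to ≈32 while the printed total is 36.277 ± 18.64 — so the
   item marginals are treated as soft anchors and `severity_mean` is then
   root-found (deterministically, on the closed-form expected total) so
   that E[total] = 36.277.
3. **PAS** is drawn uniformly inside the band implied by the true
   aspiration level (level 0 → PAS 1, level 1 → PAS 2–5, level 2 → PAS
   6–8), so PAS and the true aspiration item never disagree.
4. **Raters.** Each of two raters observes every true level through
   independent misclassification: with probability `rater_noise` the level
   slips ±1 (clamped to the valid range).
5. **Outcomes.** Oral feeding: `Bernoulli(logit⁻¹(a_f − 0.114·score))`;
   aspiration pneumonia: `Bernoulli(logit⁻¹(a_p + 0.051·score))`, with
   `score` the noise-free total. The slopes are the published per-point
   log-odds. Intercepts are root-found on a fixed 20 000-draw score sample
   so the marginal oral rate is 42/56 (the value implied by the published
   sensitivity/specificity counts) and pneumonia prevalence 0.25 — the
   study reports no pneumonia count, and 0.25 is a typical figure for
   dysphagic stroke inpatients.
6. **Demographics** (age 71 ± 14.5, male fraction 33/56, MMSE 15.3 ± 10,
   MBI 29.6 ± 21.6, log-normal days-since-onset with median 255 and mean
   ≈ 423) are passengers: they are carried in the cohort table but enter
   no model, matching the univariate design of the analyses.

### Calibrated defaults

`item_noise_sd = 1.0` and `rater_noise = 0.11` were fixed once by a
design-time Monte-Carlo sweep (200–400 seeds at n = 56): they give a
cohort-mean total ≈ 36.5, SD ≈ 19.3 (published 36.3 / 18.6), and an
expected ICC(2,1) of the two raters' totals ≈ 0.885 — "very good but
imperfect" agreement, matching the reliability regime the scale was
designed for. All randomness flows from a single `numpy` Generator seeded
from the config, so identical config+seed gives byte-identical CSVs.

### What the simulation does not capture

Real VFSS ratings have structured disagreement (raters differ more on
residue quantification than on binary items), item-specific severity
loadings, and outcome decisions influenced by covariates beyond the score
(lesion site, cognition). The generator uses a single severity factor,
uniform slip noise, and score-only outcome models. Passing tests therefore
demonstrate that the statistical machinery is correct and that parameters
put in can be recovered — not that the scale itself is valid in new
clinical data.

## Statistical engines

**ICC(2,1)** is computed from the two-way ANOVA mean squares
(rows = subjects, columns = raters):
`(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))` — two-way
random effects, absolute agreement, single rater. Cronbach's α is computed
on the same matrix, `k/(k−1)·(1 − Σ var(col)/var(row sums))`. The study
text conflates the two (it specifies the ICC model but labels the result
an α), so both are always reported, clearly labelled, and neither is used
as a numeric target. Optional 95% limits use the McGraw–Wong
F/Satterthwaite construction. An all-equal matrix is defined as perfect
agreement (ICC = α = 1) with a `degenerate` flag; matrices below 2×2 are
rejected.

**Logistic regression** is IRLS with step-halving, which guarantees a
non-increasing deviance (a violation raises rather than returning a bad
fit); convergence when the max parameter change < 1e-8, cap 100
iterations. SE from the inverse observed information; the 95% OR interval
is Wald on the log-odds scale with z = 1.96, matching the reporting style
of clinical tables; profile-likelihood intervals are out of scope.
Complete separation (detectable exactly for a scalar predictor as a
class-splitting threshold) is flagged with a warning and
`converged=False` instead of silently penalising, since the reference
analysis used plain ML. The published infratentorial feeding row prints a
CI spanning 1 alongside p = 0.011 — internally inconsistent; this package
reports the Wald p consistent with the SE.

**ROC.** Candidate cutoffs are midpoints between consecutive distinct
scores plus sentinels beyond the observed range — this is why cutoffs
come out as half-points, matching the "≤36.5" reporting convention — and
the cutoff inequality is inclusive. AUC is the Mann–Whitney estimate
(ties ½), identical to the trapezoidal area; variance, 95% CI and the
AUC = 0.5 test use DeLong placement values (the reference software's CI
method is unnamed; DeLong is the standard choice and is documented as
such). Youden ties are broken toward the larger cutoff — the rule
admitting more patients to oral feeding — for a single deterministic
answer. Each run also reports both 100%-specificity rules (highest `≤ c`
capturing no non-oral patient; lowest `≥ c` capturing no oral patient).
Which class counts as "negative" for the oral direction is fixed as the
non-oral class. Subgroups with one outcome class are skipped with a log
entry, not fatal.

**Analysis score.** Which rater's total enters the regressions/ROC is not
externally specified; the default is the mean of the two raters' totals
(uses all information), switchable to a single rater via `--rater r1|r2`.

## Problem sizes

Module and acceptance tests use the study-scale cohort (n = 56) for
structural checks, n = 2000–5000 for parameter recovery and Wald/AUC
calibration (200 null replicates), and 100–150 random small instances
(n ≤ 30) for oracle-equivalence checks against brute-force pair counting,
exhaustive cutoff search (exact rational arithmetic), explicit ANOVA
sum-of-squares enumeration, and a naive O(n²) DeLong oracle. These sizes
make the full suite run in seconds while leaving Monte-Carlo margins
(2–3 SE) wide enough to be stable across seeds.

## Known limitations

- The generator's outcome models are marginal; no covariate adjustment or
  confounding structure exists to be recovered.
- ICC confidence limits assume the two-way normal ANOVA model; with n = 56
  and integer-ish scores they are approximate.
- The headline clinical values of the motivating study (ICC 0.886,
  AUC 0.904, cutoff ≤36.5, ORs 0.892/1.053) depend on its unavailable 56
  patients: they anchor the generator but are not reproduction targets,
  and seed-to-seed variation around them is expected and correct.
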