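# Methods

## Scoring model

ILD-GAP assigns integer points to five baseline components: ILD subtype
(IPF/unclassifiable 0; CVD-IP, iNSIP, CHP −2), sex (female 0, male 1), age
in years (≤60: 0; (60, 65]: 1; >65: 2), percent-predicted FVC (>75: 0;
[50, 75]: 1; <50: 2) and percent-predicted DLco (>55: 0; (35, 55]: 1;
≤35: 2; unable to perform: 3). Totals span [−2, 8] and map to stages
I (≤1), II (2–3), III (4–5), IV (≥6), or to risk groups low (≤1),
moderate (2–3), high (≥4). ILD-GAPC adds the categorized Charlson score
(0–1 → 0, 2–3 → 1, ≥4 → 2), extending the total to [−2, 10]; risk-group
cutpoints are identical for both models.

Band boundaries are read on the real line: published integer bands like
"61–65" and "36–55" become (60, 65] and (35, 55], so that real-valued ages
and physiology values are classified without gaps. The DLco "≤35 → 2"
reading follows the original ILD-GAP convention; the CCIS upper band is
"≥4 → 2" (the only reading under which the three bands partition the
non-negative integers).

The Charlson index uses the original 1987 weights (ten conditions at 1,
six at 2, severe liver disease at 3, metastatic tumor and AIDS at 6).
Graded pairs — diabetes with/without end-organ damage, mild vs.
moderate/severe liver disease, any tumor vs. metastatic tumor — are
mutually exclusive; the maximum valid score is 33. The age-adjusted
Charlson variant (one extra point per decade from age 50) is available but
off by default: the scoring model already carries age through its own
bands, and the unadjusted 19-condition index is the standard reading.
In an ILD cohort the `chronic_pulmonary_disease` flag arguably
double-counts the index disease; the flag is taken at face value by
default, with an `exclude_index_disease` switch for sensitivity analyses.

## Endpoints

Two 3-year endpoints are derived from per-patient follow-up fields, with
the horizon fixed at 1095 days (follow-up is recorded in days):

- **ILD-related events**: first acute exacerbation or respiratory death
  within the horizon. Patients who died of a non-respiratory cause without
  a prior exacerbation are excluded from this endpoint (the composite
  cannot occur for them and treating them as censored would claim they
  remained at risk); a `nonresp_death_handling="censor"` switch keeps them
  censored at death for sensitivity analyses.
- **All-cause mortality**: death from any cause within the horizon; every
  patient contributes.

Event/censoring ties at the same day are resolved events-first throughout.

## Survival statistics

All estimators are implemented from their defining formulas (lifelines and
scikit-survival serve only as cross-check oracles in the test suite):

- **Kaplan–Meier**: product-limit estimate with Greenwood variance.
- **Log-rank**: k-sample observed-minus-expected statistic with the
  multivariate hypergeometric variance at each distinct event time,
  referred to χ²(k−1). A label-permutation p-value (default 10,000 draws,
  add-one estimator) is available for small samples, where the asymptotic
  reference distribution is unreliable.
- **Cox regression**: univariate Newton–Raphson maximization of the
  partial likelihood with step-halving; Efron tie correction by default,
  Breslow as an option for cross-package comparison. Wald 95% CIs and
  two-sided p. A monotone likelihood (perfect separation) is detected,
  bounded at |β| = 15, and reported with a warning. AIC is
  −2·log PL + 2·(number of coefficients), with the score entered as a
  single linear covariate (a categorical option exists since the choice is
  conventional).
- **Harrell's C**: over pairs where the earlier time is an observed event
  (or the tied subject is censored), the fraction in which the failing
  subject has the higher risk score, ties counting ½. Harrell's original
  estimator, not Uno's IPCW variant.
- **Time-dependent AUC**: cumulative-case/dynamic-control AUC at the
  horizon. Cases (event by t) are weighted 1/G(T−), controls (event-free
  through t) 1/G(t−), with G the reverse Kaplan–Meier censoring-survival
  estimate. With no censoring before the horizon the estimator reduces
  exactly to the Mann–Whitney AUC of score versus event-by-horizon status,
  which the tests assert. The incident/dynamic variant is out of scope.
- **Group comparisons**: Pearson chi-square (no continuity correction) for
  categorical variables; Wilcoxon rank-sum for two groups (normal
  approximation without continuity correction, so identical samples give
  p = 1 exactly) and Kruskal–Wallis for more than two. Two-sided tests,
  0.05 significance, throughout.

## Synthetic cohort generator

The generator emulates the 185-patient hospital cohort the scoring model
was evaluated on, since the patient-level data are not deposited.
Covariates: subtype mix 57:117:6:5 (IPF : CVD-IP/iNSIP : CHP : UC-ILD,
the middle column split evenly between CVD-IP and iNSIP, which carry
identical points); per-subtype male probability (e.g. 49/57 for IPF); age
∼ Normal(71.9, 9.1); %FVC ∼ Normal(94.2, 18.8); per-subtype %DLco (e.g.
Normal(81.9, 26.2) for IPF), linked to %FVC through a Gaussian copula with
ρ = 0.5 because the joint distribution is not published; all three
truncated below at 20 by rejection. CCIS ∼ NegBin(mean 2.5, size 3.27,
giving sd ≈ 2.1), capped at 15, sampled marginally because the published
per-subtype comparison shows no difference. "Cannot perform DLco" has
probability 0 by default (all study patients completed DLco testing) and
is exposed for stress tests.

Events: T ∼ h(t) = h0·exp(β_score·ILD-GAPC + β_ccis·CCIS), exponential by
default with a Weibull shape knob for robustness tests; administrative
censoring ∼ Exp(mean 792 days); an independent non-respiratory death
process at 5.6 × 10⁻⁵/day, chosen so the *observed* non-respiratory death
fraction by 3 years is ≈3.2% (6/185) after censoring pre-empts. An
ILD-related event is a first AE with probability p_ae = 0.5, else a
respiratory death — the published event count is not broken down by type,
so an even split is assumed. After a first AE, follow-up continues until
censoring or non-respiratory death; a second respiratory death process is
not modelled (a deliberate simplification: it cannot affect the
ILD-related endpoint, whose composite event already occurred, and touches
the all-cause endpoint only through the small post-AE population).

Effect sizes: β_score = 0.4 per ILD-GAPC point, matching the published
univariate ILD-GAP hazard ratio of ≈1.49/point; β_ccis = 0.2 models the
comorbidity hazard beyond what the score encodes (the published CCIS
hazard ratio of 1.53 includes the part flowing through the score term, so
the independent component is set smaller). The default baseline hazard
3.917 × 10⁻⁵/day is frozen from `calibrate_baseline_hazard` at the
study's marginal 3-year event fraction 21/185 ≈ 0.114; calibration solves
for h0 by bisection over a common-random-numbers Monte Carlo surface
(50,000 synthetic patients, fixed internal seed) to within 10⁻³.

What the generator does *not* emulate: within-patient correlation between
comorbidity burden and physiology, subtype-specific event rates beyond
what the score induces, non-proportional hazards, and recurrent
exacerbations. Passing tests therefore demonstrate the correctness and
calibration of the machinery under a proportional-hazards world, not the
clinical validity of the scores on real patients.

## Pipeline and determinism

`run_analysis` is deterministic given the cohort and settings: it scores
every patient, derives both endpoints, and emits the characteristics
table, the seven-variable univariate Cox screen (age, male sex, CCIS, IPF
vs. non-IPF, ILD-GAP score, %FVC, %DLco — the DLco row drops
cannot-perform patients), per-model AUC/C-index/AIC rows per endpoint, and
six Kaplan–Meier/log-rank stratifications (ILD-GAP stages, and each
model's risk groups, for each endpoint). Empty strata are reported as
empty rather than dropped; an endpoint with zero events yields metrics
marked unavailable rather than an error; every exclusion is logged with
counts. Reports render to JSON (sorted keys) or TSV with stable float
formatting, so identical inputs give byte-identical files.

## Problem sizes used in the checks

The test suite exercises parameter recovery on 2,000-patient cohorts
(mean of 20 seeds for the point estimate; Wald-CI coverage over 100 seeds,
where the 5-percentage-point granularity of 20 replicates would make a
nominal-coverage band untestable), null calibration over 2,000 simulated
400-patient cohorts plus ten 5,000-patient cohorts for the null AUC, and
10,000-patient simulations for calibration self-consistency. These sizes
put Monte Carlo error well inside each asserted band while keeping the
default suite fast.
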