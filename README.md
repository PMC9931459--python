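# ildgapc

Prognostic scoring and survival-model comparison for interstitial lung
disease (ILD), built around the **ILD-GAP** index and its
comorbidity-extended variant **ILD-GAPC**.

The ILD-GAP index assigns points for **G**ender, **A**ge, **P**hysiology
(percent-predicted FVC and DLco) and ILD subtype (IPF, iNSIP, CVD-IP, CHP,
unclassifiable ILD) and stages patients I–IV (or low/moderate/high risk)
for mortality prediction. It ignores comorbid disease, although
comorbidities are known to drive long-term ILD prognosis. ILD-GAPC adds a
third term: the Charlson Comorbidity Index Score (CCIS), a severity-weighted
sum over 19 comorbid conditions, collapsed to 0/1/2 points
(CCIS 0–1 → 0, 2–3 → 1, ≥4 → 2) and added to the ILD-GAP total.

The package is aimed at clinical biostatisticians evaluating point-based
risk scores on right-censored follow-up data. It provides:

- **`ildgapc.comorbidity`** — Charlson scoring with the original 1987
  weights, mutual-exclusion validation of graded condition pairs, and the
  3-level point categorization.
- **`ildgapc.scoring`** — the ILD-GAP/ILD-GAPC point tables, stage and
  risk-group maps, and derivation of the two 3-year endpoints
  (ILD-related events = first acute exacerbation or respiratory death;
  all-cause mortality) from per-patient follow-up fields.
- **`ildgapc.stats`** — from-formula survival statistics: Kaplan–Meier with
  Greenwood variance, k-sample log-rank (asymptotic or permutation p),
  univariate Cox regression (Newton–Raphson, Efron/Breslow ties) with AIC,
  Harrell's C-index, and IPCW cumulative/dynamic time-dependent ROC AUC.
- **`ildgapc.simulate`** — a synthetic cohort generator whose covariate
  marginals match the published 185-patient hospital cohort and whose
  events follow an explicit proportional-hazards process
  `h(t) = h0 · exp(β_score·ILD-GAPC + β_ccis·CCIS)`, with the baseline
  hazard calibrated to the cohort's 11.4% 3-year event fraction. The
  patient-level study data are not deposited; the simulator makes every
  downstream analysis testable end to end.
- **`ildgapc.pipeline`** — the full analysis: characteristics table,
  univariate Cox screen of seven candidate predictors, per-model
  AUC/C-index/AIC comparison, and Kaplan–Meier/log-rank stratifications,
  rendered to deterministic JSON or TSV.

## Worked example

```bash
ildgapc simulate --n 185 --seed 7 --out cohort.csv
ildgapc score    --cohort cohort.csv --out scored.csv
ildgapc evaluate --cohort cohort.csv --out metrics.json
```

The scored CSV appends `ild_gap`, `ild_gapc`, `gap_stage`, `gap_group` and
`gapc_group` columns. `metrics.json` compares the two models on the
ILD-related-event endpoint at the 3-year horizon (1095 days); for the
cohort above it contains:

```
ild_gap   AUC=0.683 C-index=0.679 AIC=125.5 (n=180, events=14)
ild_gapc  AUC=0.796 C-index=0.794 AIC=115.1 (n=180, events=14)
ild_gap/risk_group/ild_events   log-rank p = 0.0344
ild_gapc/risk_group/ild_events  log-rank p = 0.0008
```

Five of the 185 simulated patients died of non-respiratory causes without
a prior exacerbation and are excluded from this endpoint (n=180). Because
the simulated comorbidity burden carries hazard beyond what the ILD-GAP
components encode (`beta_extra_ccis > 0` by default), the combined model
separates the risk groups more sharply: higher time-dependent AUC and
C-index, lower AIC, and a smaller log-rank p across its low/moderate/high
groups — the qualitative pattern the ILD-GAPC model was proposed to
deliver. `ildgapc report --cohort cohort.csv --out-dir report/` writes the
full table set, including plot-ready Kaplan–Meier step functions.

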