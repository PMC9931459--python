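"""End-to-end study replica: scoring, cohort tables, model comparison, KM sets.

:func:`run_analysis` takes a scored-able cohort and produces, in one
deterministic pass:

* a characteristics table (per-subtype covariate summaries with
  chi-square / Kruskal–Wallis comparison p-values),
* the univariate Cox screen of the seven candidate predictors of 3-year
  ILD-related events (age, male sex, CCIS, IPF vs. non-IPF diagnosis,
  ILD-GAP score, %FVC, %DLco),
* model-comparison metrics (time-dependent AUC at the horizon, Harrell's
  C-index, Cox partial-likelihood AIC) for the ILD-GAP and ILD-GAPC
  totals, per endpoint,
* Kaplan–Meier curve sets with log-rank tests for the ILD-GAP 4-stage
  split and for the low/moderate/high risk-group split of both models,
  for both endpoints.

Every filtering step (non-respiratory-death exclusions, degenerate
stratifications) is logged with counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .scoring import (
    CANNOT_PERFORM,
    DEFAULT_HORIZON_DAYS,
    Diagnosis,
    Endpoint,
    PatientRecord,
    component_points,
    gap_stage,
    outcome_3yr,
    risk_group,
)
from .stats import (
    auc_time_dependent,
    compare_groups,
    cox_aic,
    cox_univariate,
    harrell_c,
    km_estimate,
    logrank_test,
)

__all__ = ["AnalysisSettings", "AnalysisReport", "run_analysis", "render_report"]

logger = logging.getLogger(__name__)

_MODELS = ("ild_gap", "ild_gapc")
_SUBTYPE_GROUPS = {
    "IPF": (Diagnosis.IPF,),
    "CVD_IP_iNSIP": (Diagnosis.CVD_IP, Diagnosis.iNSIP),
    "CHP": (Diagnosis.CHP,),
    "UC_ILD": (Diagnosis.UC_ILD,),
}
_STAGE_LABELS = ("I", "II", "III", "IV")
_GROUP_LABELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class AnalysisSettings:
    horizon_days: float = DEFAULT_HORIZON_DAYS
    nonresp_death_handling: str = "exclude"
    seed: int | None = None
    config_hash: str | None = None


@dataclass
class AnalysisReport:
    characteristics: dict[str, Any]
    univariate: list[dict[str, Any]]
    metrics: dict[str, list[dict[str, Any]]]   # endpoint -> rows per model
    km: dict[str, dict[str, Any]]              # "model/grouping/endpoint" keys
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "characteristics": self.characteristics,
            "univariate": self.univariate,
            "metrics": self.metrics,
            "km": self.km,
            "metadata": self.metadata,
        }


def _summ(values) -> dict[str, float | None]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return {"mean": None, "sd": None}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


def _characteristics(records, breakdowns) -> dict[str, Any]:
    bygroup: dict[str, Any] = {}
    masks = {}
    for name, dxs in _SUBTYPE_GROUPS.items():
        masks[name] = [r.diagnosis in dxs for r in records]
    masks = {"Overall": [True] * len(records), **masks}
    for name, mask in masks.items():
        rs = [r for r, m in zip(records, mask) if m]
        bs = [b for b, m in zip(breakdowns, mask) if m]
        dl = [r.dlco_pct for r in rs if r.dlco_pct != CANNOT_PERFORM]
        bygroup[name] = {
            "n": len(rs),
            "male_n": sum(r.sex.value == "male" for r in rs),
            "age": _summ(r.age for r in rs),
            "ccis": _summ(r.ccis for r in rs),
            "fvc_pct": _summ(r.fvc_pct for r in rs),
            "dlco_pct": _summ(dl),
            "ild_gap": _summ(b.ild_gap_total for b in bs),
            "ild_gapc": _summ(b.ild_gapc_total for b in bs),
            "followup_days": _summ(r.followup_days for r in rs),
        }
    # comparison p-values across the non-empty subtype groups
    pvals: dict[str, float | None] = {}
    nonempty = [
        n for n in _SUBTYPE_GROUPS if bygroup[n]["n"] > 0
    ]
    if len(nonempty) >= 2:
        def groups_of(fn, continuous=True):
            out = []
            for name in nonempty:
                dxs = _SUBTYPE_GROUPS[name]
                vals = [fn(r, b) for r, b in zip(records, breakdowns)
                        if r.diagnosis in dxs]
                vals = [v for v in vals if v is not None]
                out.append(vals)
            return [g for g in out if len(g) > 0]

        def safe_p(groups, kind):
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                return None
            try:
                return compare_groups(groups, kind)
            except ValueError:
                return None

        pvals["age"] = safe_p(groups_of(lambda r, b: r.age), "continuous")
        pvals["male_sex"] = safe_p(
            groups_of(lambda r, b: r.sex.value, False), "categorical"
        )
        pvals["ccis"] = safe_p(groups_of(lambda r, b: r.ccis), "continuous")
        pvals["fvc_pct"] = safe_p(groups_of(lambda r, b: r.fvc_pct), "continuous")
        pvals["dlco_pct"] = safe_p(
            groups_of(
                lambda r, b: r.dlco_pct if r.dlco_pct != CANNOT_PERFORM else None
            ),
            "continuous",
        )
        pvals["ild_gap"] = safe_p(
            groups_of(lambda r, b: b.ild_gap_total), "continuous"
        )
    return {"groups": bygroup, "p_values": pvals}


_UNIVARIATE_VARS = (
    ("age", lambda r, b: r.age),
    ("sex_male", lambda r, b: 1.0 if r.sex.value == "male" else 0.0),
    ("ccis", lambda r, b: float(r.ccis)),
    ("ipf_diagnosis", lambda r, b: 1.0 if r.diagnosis is Diagnosis.IPF else 0.0),
    ("ild_gap_score", lambda r, b: float(b.ild_gap_total)),
    ("fvc_pct", lambda r, b: r.fvc_pct),
    (
        "dlco_pct",
        lambda r, b: r.dlco_pct if r.dlco_pct != CANNOT_PERFORM else None,
    ),
)


def _univariate(records, breakdowns, outcomes) -> list[dict[str, Any]]:
    rows = []
    for name, fn in _UNIVARIATE_VARS:
        xs, ts, es = [], [], []
        for r, b, oc in zip(records, breakdowns, outcomes):
            o = oc[Endpoint.ild_events]
            v = fn(r, b)
            if o.analysis_eligible and v is not None and o.event_time > 0:
                xs.append(v)
                ts.append(o.event_time)
                es.append(o.event_flag)
        row: dict[str, Any] = {"variable": name}
        try:
            fit = cox_univariate(ts, es, xs)
            row.update(
                hr=fit.hr, ci_low=fit.ci_low, ci_high=fit.ci_high, p=fit.p,
                n=fit.n, n_events=fit.n_events,
            )
        except ValueError as exc:
            logger.warning("univariate screen: %s skipped (%s)", name, exc)
            row.update(hr=None, ci_low=None, ci_high=None, p=None,
                       n=len(xs), n_events=int(sum(es)), note=str(exc))
        rows.append(row)
    return rows


def _metrics_rows(totals, outcomes, endpoint, horizon) -> list[dict[str, Any]]:
    rows = []
    for model in _MODELS:
        ts, es, xs = [], [], []
        for oc, tot in zip(outcomes, totals[model]):
            o = oc[endpoint]
            if o.analysis_eligible and o.event_time > 0:
                ts.append(o.event_time)
                es.append(o.event_flag)
                xs.append(float(tot))
        row: dict[str, Any] = {"model": model, "n": len(ts),
                               "n_events": int(sum(es))}
        if sum(es) == 0:
            row.update(auc_3yr=None, c_index=None, aic=None,
                       note="no events for this endpoint")
            logger.warning("metrics unavailable for %s/%s: no events",
                           model, endpoint.value)
        else:
            fit = cox_univariate(ts, es, xs)
            try:
                auc = auc_time_dependent(ts, es, xs, horizon)
            except ValueError as exc:
                auc = None
                logger.warning("AUC unavailable for %s/%s: %s",
                               model, endpoint.value, exc)
            row.update(
                auc_3yr=auc,
                c_index=harrell_c(ts, es, xs),
                aic=cox_aic(fit),
                cox_beta=fit.beta,
                cox_hr=fit.hr,
            )
        rows.append(row)
    return rows


def _km_set(labels, groups_order, outcomes, endpoint) -> dict[str, Any]:
    """KM curves plus log-rank for one stratification; empty strata kept."""
    ts, es, gs = [], [], []
    for oc, lab in zip(outcomes, labels):
        o = oc[endpoint]
        if o.analysis_eligible and o.event_time > 0:
            ts.append(o.event_time)
            es.append(o.event_flag)
            gs.append(lab)
    curves = {}
    for lab in groups_order:
        idx = [i for i, g in enumerate(gs) if g == lab]
        if not idx:
            curves[lab] = {"n": 0, "times": [], "survival": [],
                           "n_at_risk": [], "n_events": []}
            continue
        km = km_estimate([ts[i] for i in idx], [es[i] for i in idx])
        curves[lab] = {
            "n": len(idx),
            "times": [float(t) for t in km.times],
            "survival": [float(s) for s in km.survival],
            "n_at_risk": [int(v) for v in km.n_at_risk],
            "n_events": [int(v) for v in km.n_events],
        }
    present = [lab for lab in groups_order if curves[lab]["n"] > 0]
    out: dict[str, Any] = {"groups": curves, "n_used": len(ts)}
    if len(present) < 2 or sum(es) == 0:
        out["logrank"] = {"chi_square": None, "df": None, "p": None,
                          "note": "not applicable: fewer than two non-empty "
                                  "groups or no events"}
        logger.info("log-rank not applicable (%d non-empty groups, %d events)",
                    len(present), int(sum(es)))
    else:
        lr = logrank_test(ts, es, gs)
        out["logrank"] = {"chi_square": lr.chi_square, "df": lr.df, "p": lr.p}
    return out


def run_analysis(
    cohort: list[PatientRecord],
    settings: AnalysisSettings = AnalysisSettings(),
) -> AnalysisReport:
    """Full analysis of a scored cohort; deterministic given its inputs."""
    if not cohort:
        raise ValueError("cohort is empty")
    breakdowns = [component_points(r) for r in cohort]
    outcomes = [
        outcome_3yr(
            r,
            settings.horizon_days,
            nonresp_death_handling=settings.nonresp_death_handling,
        )
        for r in cohort
    ]
    n_excluded = sum(
        not oc[Endpoint.ild_events].analysis_eligible for oc in outcomes
    )
    logger.info(
        "cohort n=%d; %d patient(s) excluded from the ILD-related endpoint "
        "(non-respiratory death without prior AE)", len(cohort), n_excluded,
    )

    totals = {
        "ild_gap": [b.ild_gap_total for b in breakdowns],
        "ild_gapc": [b.ild_gapc_total for b in breakdowns],
    }
    stage_labels = [gap_stage(t).value for t in totals["ild_gap"]]
    group_labels = {
        m: [risk_group(t).value for t in totals[m]] for m in _MODELS
    }
    stage_counts = {s: stage_labels.count(s) for s in _STAGE_LABELS}

    metrics = {}
    km = {}
    for endpoint in Endpoint:
        metrics[endpoint.value] = _metrics_rows(
            totals, outcomes, endpoint, settings.horizon_days
        )
        km[f"ild_gap/stage/{endpoint.value}"] = _km_set(
            stage_labels, _STAGE_LABELS, outcomes, endpoint
        )
        for m in _MODELS:
            km[f"{m}/risk_group/{endpoint.value}"] = _km_set(
                group_labels[m], _GROUP_LABELS, outcomes, endpoint
            )

    return AnalysisReport(
        characteristics=_characteristics(cohort, breakdowns),
        univariate=_univariate(cohort, breakdowns, outcomes),
        metrics=metrics,
        km=km,
        metadata={
            "n_patients": len(cohort),
            "n_excluded_ild_endpoint": n_excluded,
            "stage_counts": stage_counts,
            "risk_group_counts": {
                m: {g: group_labels[m].count(g) for g in _GROUP_LABELS}
                for m in _MODELS
            },
            "horizon_days": settings.horizon_days,
            "nonresp_death_handling": settings.nonresp_death_handling,
            "seed": settings.seed,
            "config_hash": settings.config_hash,
            "package_version": __version__,
        },
    )


def render_report(report: AnalysisReport, out_dir, fmt: str = "json") -> list[Path]:
    """Serialize a report; bit-stable given an identical report.

    ``fmt="json"`` writes a single ``report.json``; ``fmt="tsv"`` writes
    ``characteristics.tsv``, ``univariate.tsv``, ``metrics.tsv``,
    ``logrank.tsv`` and one step-function table per KM curve set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(
            json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n"
        )
        written.append(path)
    elif fmt == "tsv":
        def dump(df: pd.DataFrame, name: str) -> None:
            p = out_dir / name
            df.to_csv(p, sep="\t", index=False, lineterminator="\n")
            written.append(p)

        rows = []
        for gname, g in report.characteristics["groups"].items():
            row = {"group": gname, "n": g["n"], "male_n": g["male_n"]}
            for var in ("age", "ccis", "fvc_pct", "dlco_pct", "ild_gap",
                        "ild_gapc", "followup_days"):
                row[f"{var}_mean"] = g[var]["mean"]
                row[f"{var}_sd"] = g[var]["sd"]
            rows.append(row)
        dump(pd.DataFrame(rows), "characteristics.tsv")
        dump(pd.DataFrame(report.univariate), "univariate.tsv")
        mrows = []
        for endpoint, rws in report.metrics.items():
            for r in rws:
                mrows.append({"endpoint": endpoint, **r})
        dump(pd.DataFrame(mrows), "metrics.tsv")
        lrows = []
        for key, kmset in report.km.items():
            lrows.append({"stratification": key, **kmset["logrank"]})
        dump(pd.DataFrame(lrows), "logrank.tsv")
        for key, kmset in report.km.items():
            krows = []
            for lab, c in kmset["groups"].items():
                for t, s, nr, ne in zip(c["times"], c["survival"],
                                        c["n_at_risk"], c["n_events"]):
                    krows.append({"group": lab, "time": t, "survival": s,
                                  "n_at_risk": nr, "n_events": ne})
            dump(
                pd.DataFrame(
                    krows,
                    columns=["group", "time", "survival", "n_at_risk",
                             "n_events"],
                ),
                "km_" + key.replace("/", "_") + ".tsv",
            )
    else:
        raise ValueError("fmt must be 'json' or 'tsv'")
    return written
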