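"""Cohort CSV reading/writing and scored-cohort export.

The cohort CSV has one row per patient with columns
``patient_id, diagnosis, sex, age, fvc_pct, dlco_pct, ccis (or the 19
comorbidity flag columns), followup_days, ae_day, death_day, death_cause``.
An empty ``dlco_pct`` cell means the patient could not perform the
measurement.  When both the 19 comorbidity flags and a precomputed ``ccis``
column are present, the flags win; a mismatch is logged as a warning.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .comorbidity import CHARLSON_WEIGHTS, ComorbidityProfile, charlson_score
from .scoring import (
    CANNOT_PERFORM,
    DeathCause,
    PatientRecord,
    component_points,
    gap_stage,
    risk_group,
)

__all__ = ["read_cohort_csv", "write_cohort_csv", "records_to_frame", "write_scored_csv"]

logger = logging.getLogger(__name__)

_FLAG_COLUMNS = tuple(CHARLSON_WEIGHTS)


def _opt_day(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Parse a cohort CSV into validated patient records."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"patient_id", "diagnosis", "sex", "age", "fvc_pct", "dlco_pct",
                "followup_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    has_flags = all(c in df.columns for c in _FLAG_COLUMNS)
    if not has_flags and "ccis" not in df.columns:
        raise ValueError(
            "cohort CSV needs either a 'ccis' column or all 19 comorbidity "
            "flag columns"
        )
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        if has_flags:
            profile = ComorbidityProfile(
                **{c: bool(row[c]) for c in _FLAG_COLUMNS}
            )
            ccis = charlson_score(profile)
            stated = row.get("ccis")
            if stated is not None and not (
                isinstance(stated, float) and math.isnan(stated)
            ) and int(stated) != ccis:
                logger.warning(
                    "patient %s: ccis column (%s) disagrees with the "
                    "comorbidity flags (%d); using the flags",
                    row["patient_id"], stated, ccis,
                )
        else:
            ccis = int(row["ccis"])
        dlco = _opt_day(row["dlco_pct"])
        cause = row.get("death_cause")
        if cause is None or (isinstance(cause, float) and math.isnan(cause)) or cause == "":
            cause = DeathCause.none
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                diagnosis=row["diagnosis"],
                sex=row["sex"],
                age=float(row["age"]),
                fvc_pct=float(row["fvc_pct"]),
                dlco_pct=CANNOT_PERFORM if dlco is None else dlco,
                ccis=ccis,
                followup_days=float(row["followup_days"]),
                ae_day=_opt_day(row.get("ae_day")),
                death_day=_opt_day(row.get("death_day")),
                death_cause=cause,
            )
        )
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Patient records as a DataFrame in the cohort CSV schema."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "diagnosis": [r.diagnosis.value for r in records],
            "sex": [r.sex.value for r in records],
            "age": [r.age for r in records],
            "fvc_pct": [r.fvc_pct for r in records],
            "dlco_pct": [
                None if r.dlco_pct == CANNOT_PERFORM else r.dlco_pct
                for r in records
            ],
            "ccis": [r.ccis for r in records],
            "followup_days": [r.followup_days for r in records],
            "ae_day": [r.ae_day for r in records],
            "death_day": [r.death_day for r in records],
            "death_cause": [
                "" if r.death_cause is DeathCause.none else r.death_cause.value
                for r in records
            ],
        }
    )


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_scored_csv(records: list[PatientRecord], path) -> None:
    """Cohort CSV plus per-model totals, stage and risk groups."""
    df = records_to_frame(records)
    breakdowns = [component_points(r) for r in records]
    df["ild_gap"] = [b.ild_gap_total for b in breakdowns]
    df["ild_gapc"] = [b.ild_gapc_total for b in breakdowns]
    df["gap_stage"] = [gap_stage(b.ild_gap_total).value for b in breakdowns]
    df["gap_group"] = [risk_group(b.ild_gap_total).value for b in breakdowns]
    df["gapc_group"] = [risk_group(b.ild_gapc_total).value for b in breakdowns]
    df.to_csv(path, index=False)
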