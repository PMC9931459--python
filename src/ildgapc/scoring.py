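"""ILD-GAP / ILD-GAPC point assignment, staging, and 3-year outcomes.

The ILD-GAP index assigns points for ILD subtype, sex (Gender), Age and
Physiology (%FVC, %DLco) and predicts mortality in chronic fibrosing
interstitial lung disease.  The ILD-GAPC model adds a third comorbidity
term: the Charlson index score collapsed to 0/1/2 points
(:func:`ildgapc.comorbidity.ccis_points`).

Point table
-----------
===========  =============================  ======
component    band                           points
===========  =============================  ======
diagnosis    IPF / UC-ILD                       0
             CVD-IP / iNSIP / CHP              -2
sex          female                             0
             male                               1
age (y)      <=60                               0
             (60, 65]                           1
             >65                                2
%FVC         >75                                0
             [50, 75]                           1
             <50                                2
%DLco        >55                                0
             (35, 55]                           1
             <=35                               2
             cannot perform                     3
CCIS         0-1 / 2-3 / >=4              0 / 1 / 2  (ILD-GAPC only)
===========  =============================  ======

Totals range over [-2, 8] (ILD-GAP) and [-2, 10] (ILD-GAPC).  The ILD-GAP
total maps to stages I (<=1), II (2-3), III (4-5), IV (>=6); either total
maps to risk groups low (<=1), moderate (2-3), high (>=4).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple

from .comorbidity import ccis_points

__all__ = [
    "Diagnosis",
    "Sex",
    "DeathCause",
    "Endpoint",
    "CANNOT_PERFORM",
    "PatientRecord",
    "ScoreBreakdown",
    "EndpointOutcome",
    "component_points",
    "gap_stage",
    "risk_group",
    "outcome_3yr",
    "DEFAULT_HORIZON_DAYS",
]

#: "3 years" on a follow-up clock recorded in days.
DEFAULT_HORIZON_DAYS = 1095

#: Sentinel for a DLco measurement the patient could not perform.
CANNOT_PERFORM = "cannot_perform"


class Diagnosis(str, enum.Enum):
    IPF = "IPF"
    UC_ILD = "UC_ILD"
    CVD_IP = "CVD_IP"
    iNSIP = "iNSIP"
    CHP = "CHP"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class DeathCause(str, enum.Enum):
    respiratory = "respiratory"
    non_respiratory = "non_respiratory"
    none = "none"


class Endpoint(str, enum.Enum):
    """The two 3-year study endpoints."""

    ild_events = "ild_events"      # first AE or respiratory death
    all_cause = "all_cause"        # death from any cause


@dataclass
class PatientRecord:
    """One patient: baseline covariates plus follow-up outcome fields.

    ``dlco_pct`` is either percent-predicted DLco (> 0) or the string
    :data:`CANNOT_PERFORM`.  ``ae_day`` / ``death_day`` are days from the
    baseline pulmonary function test; ``None`` means the event was not
    observed during follow-up.
    """

    patient_id: str
    diagnosis: Diagnosis
    sex: Sex
    age: float
    fvc_pct: float
    dlco_pct: float | str
    ccis: int
    followup_days: float = 0.0
    ae_day: float | None = None
    death_day: float | None = None
    death_cause: DeathCause = DeathCause.none

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        self.sex = Sex(self.sex)
        self.death_cause = DeathCause(self.death_cause)
        if self.age < 0:
            raise ValueError(f"{self.patient_id}: age must be >= 0")
        if self.fvc_pct <= 0:
            raise ValueError(f"{self.patient_id}: fvc_pct must be > 0")
        if self.dlco_pct != CANNOT_PERFORM:
            if not isinstance(self.dlco_pct, (int, float)) or self.dlco_pct <= 0:
                raise ValueError(
                    f"{self.patient_id}: dlco_pct must be > 0 or "
                    f"{CANNOT_PERFORM!r}"
                )
        if self.ccis < 0:
            raise ValueError(f"{self.patient_id}: ccis must be >= 0")
        for name in ("ae_day", "death_day"):
            day = getattr(self, name)
            if day is not None and not day <= self.followup_days:
                raise ValueError(
                    f"{self.patient_id}: {name}={day} exceeds "
                    f"followup_days={self.followup_days}"
                )
        if (self.death_day is None) != (self.death_cause is DeathCause.none):
            raise ValueError(
                f"{self.patient_id}: death_day and death_cause must be "
                "jointly present or jointly absent"
            )


class ScoreBreakdown(NamedTuple):
    """Per-component points and the two model totals."""

    diagnosis_pts: int
    sex_pts: int
    age_pts: int
    fvc_pts: int
    dlco_pts: int
    ccis_pts: int
    ild_gap_total: int
    ild_gapc_total: int


_DIAGNOSIS_PTS = {
    Diagnosis.IPF: 0,
    Diagnosis.UC_ILD: 0,
    Diagnosis.CVD_IP: -2,
    Diagnosis.iNSIP: -2,
    Diagnosis.CHP: -2,
}


def _age_pts(age: float) -> int:
    if age <= 60:
        return 0
    if age <= 65:
        return 1
    return 2


def _fvc_pts(fvc: float) -> int:
    if fvc > 75:
        return 0
    if fvc >= 50:
        return 1
    return 2


def _dlco_pts(dlco: float | str) -> int:
    if dlco == CANNOT_PERFORM:
        return 3
    if dlco > 55:
        return 0
    if dlco > 35:
        return 1
    return 2


def component_points(record: PatientRecord) -> ScoreBreakdown:
    """Assign per-component points and totals for both models."""
    d = _DIAGNOSIS_PTS[Diagnosis(record.diagnosis)]
    s = 1 if Sex(record.sex) is Sex.male else 0
    a = _age_pts(record.age)
    f = _fvc_pts(record.fvc_pct)
    dl = _dlco_pts(record.dlco_pct)
    c = ccis_points(record.ccis)
    gap = d + s + a + f + dl
    return ScoreBreakdown(d, s, a, f, dl, c, gap, gap + c)


class GapStage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class RiskGroup(str, enum.Enum):
    low = "low"
    moderate = "moderate"
    high = "high"


def gap_stage(ild_gap_total: int) -> GapStage:
    """Map an ILD-GAP total to stage I–IV (I <=1, II 2-3, III 4-5, IV >5)."""
    if not -2 <= ild_gap_total <= 8:
        raise ValueError(
            f"ILD-GAP total must lie in [-2, 8], got {ild_gap_total}"
        )
    if ild_gap_total <= 1:
        return GapStage.I
    if ild_gap_total <= 3:
        return GapStage.II
    if ild_gap_total <= 5:
        return GapStage.III
    return GapStage.IV


def risk_group(total: int) -> RiskGroup:
    """Map an ILD-GAP or ILD-GAPC total to low / moderate / high risk.

    low <=1, moderate 2-3, high >=4; identical cutpoints for both models.
    """
    if not -2 <= total <= 10:
        raise ValueError(f"score total must lie in [-2, 10], got {total}")
    if total <= 1:
        return RiskGroup.low
    if total <= 3:
        return RiskGroup.moderate
    return RiskGroup.high


class EndpointOutcome(NamedTuple):
    """Right-censored outcome for one patient under one endpoint."""

    event_time: float
    event_flag: int
    analysis_eligible: bool


def outcome_3yr(
    record: PatientRecord,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    *,
    nonresp_death_handling: str = "exclude",
) -> dict[Endpoint, EndpointOutcome]:
    """Derive the two 3-year endpoints from a patient's follow-up fields.

    ILD-related events
        Composite of first acute exacerbation or respiratory death within
        the horizon.  Patients who died of a non-respiratory cause without
        a prior AE are, by default, excluded from this endpoint
        (``analysis_eligible=False``); with
        ``nonresp_death_handling="censor"`` they are instead censored at
        the day of death.

    All-cause mortality
        Death from any cause within the horizon; every patient is eligible.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    if nonresp_death_handling not in ("exclude", "censor"):
        raise ValueError(
            "nonresp_death_handling must be 'exclude' or 'censor', got "
            f"{nonresp_death_handling!r}"
        )

    resp_death_day = (
        record.death_day
        if record.death_cause is DeathCause.respiratory
        else None
    )
    nonresp_death_day = (
        record.death_day
        if record.death_cause is DeathCause.non_respiratory
        else None
    )

    # --- ILD-related: first AE or respiratory death ---
    ild_event_day = min(
        (d for d in (record.ae_day, resp_death_day) if d is not None),
        default=None,
    )
    eligible = True
    if ild_event_day is not None and ild_event_day <= horizon_days:
        ild = EndpointOutcome(ild_event_day, 1, True)
    else:
        censor = min(record.followup_days, horizon_days)
        if (
            nonresp_death_day is not None
            and nonresp_death_day <= horizon_days
            and (record.ae_day is None or record.ae_day > horizon_days)
        ):
            # died of a non-respiratory cause with no AE inside the horizon
            if nonresp_death_handling == "exclude":
                eligible = False
            else:
                censor = min(nonresp_death_day, horizon_days)
        ild = EndpointOutcome(censor, 0, eligible)

    # --- all-cause mortality ---
    if record.death_day is not None and record.death_day <= horizon_days:
        ac = EndpointOutcome(record.death_day, 1, True)
    else:
        ac = EndpointOutcome(min(record.followup_days, horizon_days), 0, True)

    return {Endpoint.ild_events: ild, Endpoint.all_cause: ac}
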