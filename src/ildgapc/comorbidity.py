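"""Charlson Comorbidity Index scoring.

The Charlson Comorbidity Index Score (CCIS) is a weighted sum over 19
comorbid conditions, each carrying a severity weight of 1, 2, 3 or 6
(Charlson et al., 1987).  The index was developed to quantify the risk of
death attributable to comorbid disease and is used here as the "C" term of
the ILD-GAPC prognostic model: the integer CCIS is collapsed to a 3-level
point category (0–1 → 0, 2–3 → 1, ≥4 → 2) before being added to the
ILD-GAP total.

Three condition pairs are graded forms of the same disease and are mutually
exclusive by construction: uncomplicated diabetes vs. diabetes with
end-organ damage, mild vs. moderate/severe liver disease, and any (solid)
tumor vs. metastatic solid tumor.  The severer form supersedes the milder
one; profiles asserting both are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "CHARLSON_WEIGHTS",
    "MAX_CCIS",
    "ComorbidityProfile",
    "charlson_score",
    "ccis_points",
]

#: Original 1987 Charlson weights, one per condition slot.
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "connective_tissue_disease": 1,
    "peptic_ulcer": 1,
    "mild_liver_disease": 1,
    "diabetes_uncomplicated": 1,
    "hemiplegia": 2,
    "moderate_severe_renal_disease": 2,
    "diabetes_end_organ_damage": 2,
    "any_tumor": 2,
    "leukemia": 2,
    "lymphoma": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids": 6,
}

#: Graded-severity pairs: (milder, severer) cannot both be flagged.
_EXCLUSIVE_PAIRS: tuple[tuple[str, str], ...] = (
    ("diabetes_uncomplicated", "diabetes_end_organ_damage"),
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("any_tumor", "metastatic_solid_tumor"),
)

#: Largest score a valid profile can attain (all conditions true, keeping
#: only the severer member of each exclusive pair).
MAX_CCIS: int = sum(CHARLSON_WEIGHTS.values()) - sum(
    CHARLSON_WEIGHTS[mild] for mild, _ in _EXCLUSIVE_PAIRS
)

_AGE_DECADE_START = 50  # age-adjusted variant: +1 point per decade from 50


@dataclass(frozen=True)
class ComorbidityProfile:
    """Boolean flags for the 19 Charlson conditions.

    All flags default to False, so profiles are typically built by naming
    only the conditions present, e.g.
    ``ComorbidityProfile(diabetes_uncomplicated=True)``.
    """

    myocardial_infarction: bool = False
    congestive_heart_failure: bool = False
    peripheral_vascular_disease: bool = False
    cerebrovascular_disease: bool = False
    dementia: bool = False
    chronic_pulmonary_disease: bool = False
    connective_tissue_disease: bool = False
    peptic_ulcer: bool = False
    mild_liver_disease: bool = False
    diabetes_uncomplicated: bool = False
    hemiplegia: bool = False
    moderate_severe_renal_disease: bool = False
    diabetes_end_organ_damage: bool = False
    any_tumor: bool = False
    leukemia: bool = False
    lymphoma: bool = False
    moderate_severe_liver_disease: bool = False
    metastatic_solid_tumor: bool = False
    aids: bool = False

    def __post_init__(self) -> None:
        for mild, severe in _EXCLUSIVE_PAIRS:
            if getattr(self, mild) and getattr(self, severe):
                raise ValueError(
                    f"mutually exclusive conditions both set: {mild!r} and "
                    f"{severe!r} (the severer form supersedes the milder)"
                )

    def active_conditions(self) -> list[str]:
        """Names of conditions flagged True, in canonical order."""
        return [f.name for f in fields(self) if getattr(self, f.name)]


def charlson_score(
    profile: ComorbidityProfile,
    *,
    age: float | None = None,
    age_adjusted: bool = False,
    exclude_index_disease: bool = False,
) -> int:
    """Weighted Charlson sum over the flagged conditions.

    Parameters
    ----------
    profile
        Validated comorbidity flags.
    age, age_adjusted
        When ``age_adjusted`` is True, add one point per decade of age
        starting at 50 (50–59 → +1, …, ≥80 → +4).  Off by default: the
        ILD-GAPC model uses the unadjusted 19-condition index (age enters
        the model separately through the ILD-GAP age bands).
    exclude_index_disease
        Drop ``chronic_pulmonary_disease`` from the sum.  In an ILD cohort
        the index disease itself is a chronic pulmonary disease; counting
        the flag double-counts it.  Default False: the flag is taken at
        face value and the caller decides what it records.

    Returns
    -------
    int
        Score in ``[0, MAX_CCIS]`` (plus the age term if requested).
    """
    score = sum(
        w for name, w in CHARLSON_WEIGHTS.items() if getattr(profile, name)
    )
    if exclude_index_disease and profile.chronic_pulmonary_disease:
        score -= CHARLSON_WEIGHTS["chronic_pulmonary_disease"]
    if age_adjusted:
        if age is None:
            raise ValueError("age_adjusted=True requires age")
        if age >= _AGE_DECADE_START:
            score += min((int(age) - _AGE_DECADE_START) // 10 + 1, 4)
    return score


def ccis_points(ccis: int) -> int:
    """Collapse an integer CCIS to the 3-level ILD-GAPC point category.

    0–1 → 0 points, 2–3 → 1 point, ≥4 → 2 points.
    """
    if ccis < 0:
        raise ValueError(f"CCIS must be non-negative, got {ccis}")
    if ccis <= 1:
        return 0
    if ccis <= 3:
        return 1
    return 2
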