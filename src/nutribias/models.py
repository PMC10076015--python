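"""Shared domain vocabulary: nutrients, outcomes, column schema, OutcomeModel.

Four nutrients are tracked, each with a self-reported (SR) and a biomarker
(BIO) measurement: energy (EI, kcal/day; doubly labeled water), sodium
(SI, mg/day; 24-hr urine), potassium (PoI, mg/day; 24-hr urine) and protein
(PrI, g/day; urinary nitrogen). Six health outcomes: body weight (kg), waist
circumference (cm), post-fitness-test heart rate (beats/min), resting
systolic/diastolic blood pressure (mmHg) and VO2 max (L/min).

Units are encoded in the CSV column suffixes to keep mg/g mix-ups visible.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "NUTRIENTS",
    "OUTCOMES",
    "NUTRIENT_COLUMNS",
    "OUTCOME_COLUMNS",
    "FFM_COLUMN",
    "ID_COLUMN",
    "COHORT_COLUMNS",
    "sr_column",
    "bio_column",
    "outcome_column",
    "OutcomeModel",
]

NUTRIENTS: tuple[str, ...] = ("EI", "SI", "PoI", "PrI")
OUTCOMES: tuple[str, ...] = ("BW", "WC", "HR", "SBP", "DBP", "VO2")

#: nutrient -> (self-report column, biomarker column)
NUTRIENT_COLUMNS: dict[str, tuple[str, str]] = {
    "EI": ("ei_sr_kcal", "ei_bio_kcal"),
    "SI": ("si_sr_mg", "si_bio_mg"),
    "PoI": ("poi_sr_mg", "poi_bio_mg"),
    "PrI": ("pri_sr_g", "pri_bio_g"),
}

OUTCOME_COLUMNS: dict[str, str] = {
    "BW": "bw_kg",
    "WC": "wc_cm",
    "HR": "hr_bpm",
    "SBP": "sbp_mmhg",
    "DBP": "dbp_mmhg",
    "VO2": "vo2_lmin",
}

FFM_COLUMN = "ffm_kg"
ID_COLUMN = "id"

COHORT_COLUMNS: tuple[str, ...] = (
    ID_COLUMN,
    FFM_COLUMN,
    "ei_bio_kcal",
    "ei_sr_kcal",
    "si_bio_mg",
    "si_sr_mg",
    "poi_bio_mg",
    "poi_sr_mg",
    "pri_bio_g",
    "pri_sr_g",
    *OUTCOME_COLUMNS.values(),
)


def sr_column(nutrient: str) -> str:
    return NUTRIENT_COLUMNS[nutrient][0]


def bio_column(nutrient: str) -> str:
    return NUTRIENT_COLUMNS[nutrient][1]


def outcome_column(outcome: str) -> str:
    return OUTCOME_COLUMNS[outcome]


@dataclass(frozen=True)
class OutcomeModel:
    """Linear outcome model HO = a0 + a1 * NI_BIO + N(0, eta^2).

    a0 is the intercept (outcome units), a1 the slope (outcome units per
    nutrient unit) and eta the residual SD. In the simulation the fitted a1
    doubles as the true association beta1 against which bias is measured.
    """

    a0: float
    a1: float
    eta: float

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
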