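"""Goldberg cutoffs: plausibility screening of self-reported energy intake.

The rule compares each participant's reported energy intake (EI_SR) with the
energy expenditure (EE) predicted from body composition: EE = PAL * BMR, with
BMR predicted linearly from fat-free mass (BMR = 370 + 21.6 * FFM, kcal/day).
A report is plausible when the ratio EI_SR : EE lies strictly inside
exp(-2S/100) .. exp(+2S/100), where S aggregates the within-subject variation
of reported intake (CV_wEI, shrunk by the number of assessment days d), of BMR
(CV_wB), and the total variation of the physical-activity level (CV_tP):

    S = sqrt(CV_wEI^2 / d + CV_wB^2 + CV_tP^2)   [percent]

Participants outside the interval are classified as under-/over-reporters.
Classification uses energy intake only; downstream analyses propagate the
exclusion to all nutrients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GoldbergParams",
    "GoldbergResult",
    "predict_bmr",
    "predict_ee",
    "cutoff_s",
    "cutoff_bounds",
    "classify",
    "screen_cohort",
]

#: Coefficients of the FFM-based BMR prediction (kcal/day).
BMR_INTERCEPT = 370.0
BMR_SLOPE = 21.6  # kcal/day per kg fat-free mass


@dataclass(frozen=True)
class GoldbergParams:
    """Inputs of the cutoff computation.

    pal
        Physical activity level (dimensionless multiplier on BMR).
    cv_ei, cv_b, cv_p
        Within-subject CV of reported energy intake, within-subject CV of
        BMR, and total CV of PAL, all in percent.
    d
        Number of days of diet assessment.
    """

    pal: float = 1.75
    cv_ei: float = 23.0
    cv_b: float = 8.5
    cv_p: float = 15.0
    d: int = 7

    def __post_init__(self) -> None:
        for name in ("pal", "cv_ei", "cv_b", "cv_p", "d"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"GoldbergParams.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class GoldbergResult:
    """Per-participant screening outcome."""

    bmr: float  # kcal/day
    ee: float  # kcal/day
    ratio: float  # EI_SR : EE
    s: float  # percent
    lower: float
    upper: float
    accepted: bool


def predict_bmr(ffm: float) -> float:
    """Predict basal metabolic rate (kcal/day) from fat-free mass (kg)."""
    if ffm is None or not np.isfinite(ffm) or ffm <= 0:
        raise ValueError(f"fat-free mass must be a positive finite number, got {ffm!r}")
    return BMR_INTERCEPT + BMR_SLOPE * ffm


def predict_ee(bmr: float, pal: float) -> float:
    """Predict total energy expenditure (kcal/day) as PAL * BMR."""
    if not np.isfinite(bmr) or bmr <= 0:
        raise ValueError(f"bmr must be positive, got {bmr!r}")
    if not np.isfinite(pal) or pal <= 0:
        raise ValueError(f"pal must be positive, got {pal!r}")
    return pal * bmr


def cutoff_s(params: GoldbergParams) -> float:
    """Aggregate variation S (percent) entering the cutoff exponent."""
    return math.sqrt(params.cv_ei**2 / params.d + params.cv_b**2 + params.cv_p**2)


def cutoff_bounds(s: float) -> tuple[float, float]:
    """Plausibility interval exp(-2s/100) .. exp(+2s/100) for the EI:EE ratio."""
    if not np.isfinite(s) or s < 0:
        raise ValueError(f"s must be non-negative, got {s!r}")
    half_width = 2.0 * s / 100.0
    return math.exp(-half_width), math.exp(half_width)


def classify(ei_sr: float, ffm: float, params: GoldbergParams | None = None) -> GoldbergResult:
    """Screen one participant's reported energy intake.

    The acceptance condition is the strict double inequality
    lower < EI_SR/EE < upper; a ratio exactly at either bound is rejected.

    Raises
    ------
    ValueError
        If ``ei_sr`` or ``ffm`` is missing/non-finite (the caller decides
        whether to exclude the participant), or ``ei_sr`` is negative.
    """
    params = params or GoldbergParams()
    if ei_sr is None or not np.isfinite(ei_sr) or ei_sr < 0:
        raise ValueError(f"ei_sr must be a non-negative finite number, got {ei_sr!r}")
    bmr = predict_bmr(ffm)
    ee = predict_ee(bmr, params.pal)
    s = cutoff_s(params)
    lower, upper = cutoff_bounds(s)
    ratio = ei_sr / ee
    accepted = bool(lower < ratio < upper)
    return GoldbergResult(bmr=bmr, ee=ee, ratio=ratio, s=s, lower=lower, upper=upper, accepted=accepted)


def screen_cohort(
    cohort: pd.DataFrame,
    params: GoldbergParams | None = None,
    ei_sr_col: str = "ei_sr_kcal",
    ffm_col: str = "ffm_kg",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into Goldberg-accepted and -rejected participants.

    Rows with missing EI_SR or FFM are dropped (from both partitions) with a
    logged count, mirroring the usual exclusion of participants lacking the
    screening inputs. Classification depends only on the individual's own
    values, so the partition is invariant to the presence of other rows.

    Returns
    -------
    (accepted, rejected, results)
        ``accepted`` and ``rejected`` are disjoint row subsets of ``cohort``;
        ``results`` holds bmr, ee, ratio, lower, upper, accepted per retained
        row (indexed like the retained cohort).
    """
    params = params or GoldbergParams()
    if cohort.empty:
        logger.warning("screen_cohort called on an empty cohort")
        empty = cohort.iloc[0:0]
        cols = ["bmr", "ee", "ratio", "lower", "upper", "accepted"]
        return empty, empty.copy(), pd.DataFrame(columns=cols)

    usable = cohort[ei_sr_col].notna() & cohort[ffm_col].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("screen_cohort: dropped %d rows with missing %s/%s", n_dropped, ei_sr_col, ffm_col)
    data = cohort.loc[usable]

    ffm = data[ffm_col].to_numpy(dtype=float)
    ei_sr = data[ei_sr_col].to_numpy(dtype=float)
    if (ffm <= 0).any() or (ei_sr < 0).any():
        raise ValueError("screen_cohort: non-positive FFM or negative EI_SR in cohort")

    bmr = BMR_INTERCEPT + BMR_SLOPE * ffm
    ee = params.pal * bmr
    s = cutoff_s(params)
    lower, upper = cutoff_bounds(s)
    ratio = ei_sr / ee
    accepted = (ratio > lower) & (ratio < upper)

    results = pd.DataFrame(
        {
            "bmr": bmr,
            "ee": ee,
            "ratio": ratio,
            "lower": lower,
            "upper": upper,
            "accepted": accepted,
        },
        index=data.index,
    )
    return data.loc[accepted], data.loc[~accepted], results
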