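"""Empirical-cohort analysis: mean-bias tests, group comparisons, bias table.

Reproduces, on any cohort table, the analyses run on the real study data:

* one-sample t tests of the mean reporting error (NI_SR - NI_BIO) against
  zero, on all participants and on the Goldberg-accepted subset;
* Welch t comparisons of accepted vs rejected participants (bias,
  self-report, biomarker, per nutrient);
* a jackknife test of the whole-cohort vs accepted-subset mean (the two
  groups overlap, so an independent-samples test does not apply);
* the 24-pair association table: slopes beta_BIO, beta_SR, beta_G, percent
  bias b, percent remaining bias r, with leave-one-out jackknife CIs.

All regressions are bivariate (no covariate adjustment) and all tests are
two-tailed at alpha = 0.05 with no multiplicity correction. Leave-one-out
slopes use exact O(n) downdates of the OLS sufficient statistics, and the
per-individual Goldberg classification is held fixed across leave-one-out
subsets (the rule depends only on the individual's own values, so
re-screening each subset would change nothing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .goldberg import GoldbergParams, screen_cohort
from .metrics import UnstableDenominatorError, association_flags, jackknife_se, percent_bias
from .models import NUTRIENTS, OUTCOMES, bio_column, outcome_column, sr_column

__all__ = [
    "one_sample_t",
    "welch_t",
    "paired_jackknife_test",
    "mean_bias_table",
    "group_comparison_table",
    "association_bias_table",
]


def one_sample_t(values, null_mean: float = 0.0) -> tuple[float, float]:
    """Classical one-sample t test, two-tailed."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance")
    t = (v.mean() - null_mean) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t), p


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t test with Satterthwaite df, two-tailed."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    sa, sb = va / a.size, vb / b.size
    if sa + sb == 0:
        raise ValueError("degenerate groups: zero variance and unequal means")
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), p


def paired_jackknife_test(values, accepted_mask) -> tuple[float, tuple[float, float], float]:
    """Jackknife test of mean(all) - mean(accepted subset).

    The two means share participants, so the leave-one-out jackknife over the
    whole cohort provides the SE of their difference; the p-value is from the
    normal approximation. If the statistic is constant under leave-one-out
    (zero SE), the exact difference is reported with p = 1 when it is zero.

    Returns (difference, (ci_low, ci_high), p).
    """
    v = np.asarray(values, dtype=float)
    mask = np.asarray(accepted_mask, dtype=bool)
    if v.shape != mask.shape:
        raise ValueError("values and accepted_mask must have equal length")
    n = v.size
    na = int(mask.sum())
    if na <= 1:
        raise ValueError("accepted subset must contain at least 2 observations")

    diff = v.mean() - v[mask].mean()
    s_all, s_acc = v.sum(), v[mask].sum()
    loo_all = (s_all - v) / (n - 1)
    loo_acc = np.where(mask, (s_acc - v) / (na - 1), s_acc / na)
    se = jackknife_se(loo_all - loo_acc)
    z = float(stats.norm.ppf(0.975))
    ci = (diff - z * se, diff + z * se)
    if se == 0.0:
        return float(diff), ci, 1.0 if diff == 0.0 else 0.0
    p = 2.0 * float(stats.norm.sf(abs(diff) / se))
    return float(diff), ci, p


def mean_bias_table(
    cohort: pd.DataFrame, params: GoldbergParams | None = None, nutrients=NUTRIENTS
) -> pd.DataFrame:
    """Per-nutrient mean reporting error with t tests, all vs accepted rows."""
    accepted, _, _ = screen_cohort(cohort, params)
    rows = []
    for nut in nutrients:
        for group, frame in (("all", cohort), ("accepted", accepted)):
            bias = (frame[sr_column(nut)] - frame[bio_column(nut)]).to_numpy(dtype=float)
            t, p = one_sample_t(bias, 0.0)
            rows.append(
                dict(
                    nutrient=nut,
                    group=group,
                    n=bias.size,
                    mean_bias=bias.mean(),
                    sd=bias.std(ddof=1),
                    se=bias.std(ddof=1) / math.sqrt(bias.size),
                    t=t,
                    p=p,
                )
            )
    return pd.DataFrame(rows)


def group_comparison_table(
    cohort: pd.DataFrame, params: GoldbergParams | None = None, nutrients=NUTRIENTS
) -> pd.DataFrame:
    """Accepted vs rejected comparison of bias, self-report and biomarker.

    Reports both SD and SE per group (published tables are ambiguous about
    which they print) and a Welch t p-value per nutrient and measure.
    """
    accepted, rejected, _ = screen_cohort(cohort, params)
    rows = []
    for nut in nutrients:
        sr_col, bio_col = sr_column(nut), bio_column(nut)
        measures = {
            "bias": lambda f: (f[sr_col] - f[bio_col]).to_numpy(dtype=float),
            "self_report": lambda f: f[sr_col].to_numpy(dtype=float),
            "biomarker": lambda f: f[bio_col].to_numpy(dtype=float),
        }
        for measure, getter in measures.items():
            va, vr = getter(accepted), getter(rejected)
            t, p = welch_t(va, vr)
            rows.append(
                dict(
                    nutrient=nut,
                    measure=measure,
                    n_accepted=va.size,
                    n_rejected=vr.size,
                    accepted_mean=va.mean(),
                    accepted_sd=va.std(ddof=1),
                    accepted_se=va.std(ddof=1) / math.sqrt(va.size),
                    rejected_mean=vr.mean(),
                    rejected_sd=vr.std(ddof=1),
                    rejected_se=vr.std(ddof=1) / math.sqrt(vr.size),
                    t=t,
                    p=p,
                )
            )
    return pd.DataFrame(rows)


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    sx, sy = x.sum(), y.sum()
    denom = n * float(x @ x) - sx * sx
    if denom == 0:
        raise ValueError("constant predictor")
    return (n * float(x @ y) - sx * sy) / denom


def _loo_slopes(x: np.ndarray, y: np.ndarray, subset: np.ndarray) -> tuple[float, np.ndarray]:
    """Full-subset slope plus the slope with each cohort row left out.

    Exact downdating of (n, Sx, Sy, Sxx, Sxy); leaving out a row outside the
    regression subset returns the full-subset slope unchanged.
    """
    xs, ys = x[subset], y[subset]
    m = xs.size
    if m < 4:
        raise ValueError("subset too small for leave-one-out slopes")
    sx, sy = xs.sum(), ys.sum()
    sxx, sxy = float(xs @ xs), float(xs @ ys)
    denom_full = m * sxx - sx * sx
    if denom_full == 0:
        raise ValueError("constant predictor")
    full = (m * sxy - sx * sy) / denom_full

    slopes = np.full(x.size, full)
    mp = m - 1
    sx_, sy_ = sx - xs, sy - ys
    sxx_, sxy_ = sxx - xs * xs, sxy - xs * ys
    denom = mp * sxx_ - sx_ * sx_
    if np.any(denom == 0):
        bad = int(np.where(subset)[0][np.argmax(denom == 0)])
        raise RuntimeError(f"degenerate regression after removing index {bad}")
    slopes[np.where(subset)[0]] = (mp * sxy_ - sx_ * sy_) / denom
    return full, slopes


def association_bias_table(
    cohort: pd.DataFrame,
    params: GoldbergParams | None = None,
    nutrients=NUTRIENTS,
    outcomes=OUTCOMES,
    ci: bool = True,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percent bias and percent remaining bias for every nutrient-outcome pair.

    For each pair, fits outcome-on-intake slopes beta_BIO and beta_SR on all
    rows and beta_G on the Goldberg-accepted rows, and derives b and r with
    jackknife CIs (``ci=False`` skips the CIs for speed on large cohorts).
    Pairs whose beta_BIO is below the denominator tolerance are flagged
    unstable with undefined CIs.
    """
    _, _, screening = screen_cohort(cohort, params)
    accepted = screening["accepted"].to_numpy(dtype=bool)
    all_rows = np.ones(len(cohort), dtype=bool)
    z = float(stats.norm.ppf(0.5 + level / 2))

    records = []
    for nut in nutrients:
        x_bio = cohort[bio_column(nut)].to_numpy(dtype=float)
        x_sr = cohort[sr_column(nut)].to_numpy(dtype=float)
        for out in outcomes:
            y = cohort[outcome_column(out)].to_numpy(dtype=float)
            rec = dict(nutrient=nut, outcome=out, n=len(cohort), n_accepted=int(accepted.sum()))
            if ci:
                beta_bio, loo_bio = _loo_slopes(x_bio, y, all_rows)
                beta_sr, loo_sr = _loo_slopes(x_sr, y, all_rows)
                beta_g, loo_g = _loo_slopes(x_sr, y, accepted)
            else:
                beta_bio = _slope(x_bio, y)
                beta_sr = _slope(x_sr, y)
                beta_g = _slope(x_sr[accepted], y[accepted])
            rec.update(beta_bio=beta_bio, beta_sr=beta_sr, beta_g=beta_g)
            try:
                b = percent_bias(beta_sr, beta_bio)
                r = percent_bias(beta_g, beta_bio)
            except UnstableDenominatorError:
                rec.update(
                    b=np.nan, b_lo=np.nan, b_hi=np.nan, r=np.nan, r_lo=np.nan, r_hi=np.nan,
                    significant_bias=False, significant_remaining=False,
                    significant_reduction=False, unstable=True,
                )
                records.append(rec)
                continue
            rec.update(b=b, r=r, unstable=False)
            if ci:
                loo_b = (loo_sr - loo_bio) / loo_bio * 100.0
                loo_r = (loo_g - loo_bio) / loo_bio * 100.0
                se_b, se_r = jackknife_se(loo_b), jackknife_se(loo_r)
                b_lo, b_hi = b - z * se_b, b + z * se_b
                r_lo, r_hi = r - z * se_r, r + z * se_r
                sig_b, sig_r, sig_red = association_flags(b_lo, b_hi, r_lo, r_hi)
                rec.update(
                    b_lo=b_lo, b_hi=b_hi, r_lo=r_lo, r_hi=r_hi,
                    significant_bias=sig_b, significant_remaining=sig_r,
                    significant_reduction=sig_red,
                )
            else:
                rec.update(
                    b_lo=np.nan, b_hi=np.nan, r_lo=np.nan, r_hi=np.nan,
                    significant_bias=False, significant_remaining=False,
                    significant_reduction=False,
                )
            records.append(rec)
    return pd.DataFrame(records)
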