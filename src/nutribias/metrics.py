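"""Estimator-performance metrics across replicates, and empirical bias metrics.

Simulation metrics for an estimator of the association beta1, from the i = 1..n
replicate point estimates beta_hat_i and their 95% CIs:

    Bias = mean(beta_hat) - beta1
    MSE  = (1/n) sum (beta_hat_i - mean(beta_hat))^2 + Bias^2
    P    = fraction of replicates with ci_low < beta1 < ci_high  (strict)

MSE uses the population-variance (1/n) convention, so it equals
(1/n) sum (beta_hat_i - beta1)^2 exactly. Empirical metrics compare the three
regression slopes fitted on one dataset: percent bias b = (beta_SR -
beta_BIO)/beta_BIO * 100 and percent remaining bias r = (beta_G -
beta_BIO)/beta_BIO * 100, with leave-one-out jackknife confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformanceSummary",
    "AssociationBias",
    "percent_bias",
    "percent_remaining_bias",
    "jackknife_ci",
    "jackknife_se",
    "summarize_performance",
    "summarize_simulation",
]

#: relative denominator tolerance below which percent bias is unstable
DENOM_RTOL = 1e-12


class UnstableDenominatorError(ZeroDivisionError):
    """beta_BIO too close to zero for a meaningful percent bias."""


@dataclass(frozen=True)
class PerformanceSummary:
    bias: float
    mse: float
    coverage: float
    beta1: float
    n_replicates_used: int

    def __post_init__(self) -> None:
        if self.mse < -1e-12 or not (0.0 <= self.coverage <= 1.0):
            raise ValueError("invalid performance summary")


@dataclass(frozen=True)
class AssociationBias:
    """Empirical percent bias / remaining bias for one nutrient-outcome pair."""

    b: float
    b_lo: float
    b_hi: float
    r: float
    r_lo: float
    r_hi: float
    significant_bias: bool  # b CI excludes 0
    significant_remaining: bool  # r CI excludes 0
    significant_reduction: bool  # r CI within (-100, 100)


def _percent_ratio(num: float, den: float, scale: float | None = None) -> float:
    scale = scale if scale is not None else max(abs(num), abs(den), 1.0)
    if abs(den) <= DENOM_RTOL * scale:
        raise UnstableDenominatorError(f"denominator {den!r} below tolerance")
    return (num - den) / den * 100.0


def percent_bias(beta_sr: float, beta_bio: float) -> float:
    """b = (beta_SR - beta_BIO)/beta_BIO * 100 (percent)."""
    return _percent_ratio(beta_sr, beta_bio)


def percent_remaining_bias(beta_g: float, beta_bio: float) -> float:
    """r = (beta_G - beta_BIO)/beta_BIO * 100 (percent)."""
    return _percent_ratio(beta_g, beta_bio)


def jackknife_se(loo_values) -> float:
    """Jackknife SE from the leave-one-out replicates theta_hat(i)."""
    theta = np.asarray(loo_values, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("need at least 2 leave-one-out values")
    dev = theta - theta.mean()
    return float(np.sqrt((n - 1) / n * np.sum(dev**2)))


def jackknife_ci(data, statistic, level: float = 0.95) -> tuple[float, float, float]:
    """Leave-one-out jackknife CI of ``statistic`` over rows of ``data``.

    The CI is the normal approximation around the full-sample point estimate:
    estimate +/- z * SE, with SE = sqrt((n-1)/n * sum (theta_i - theta_.)^2).
    Deterministic (no resampling randomness). A failing leave-one-out subset
    raises an error naming the offending index.
    """
    n = len(data)
    if n < 3:
        raise ValueError("jackknife needs at least 3 observations")
    estimate = float(statistic(data))
    is_frame = isinstance(data, (pd.DataFrame, pd.Series))
    loo = np.empty(n)
    for i in range(n):
        subset = data.drop(data.index[i]) if is_frame else np.delete(np.asarray(data), i, axis=0)
        try:
            loo[i] = statistic(subset)
        except Exception as exc:
            raise RuntimeError(f"jackknife statistic failed on leave-one-out index {i}") from exc
    se = jackknife_se(loo)
    z = float(stats.norm.ppf(0.5 + level / 2))
    return estimate, estimate - z * se, estimate + z * se


def summarize_performance(beta_hats, ci_lows, ci_highs, beta1: float) -> PerformanceSummary:
    """Bias, MSE and coverage of one estimator over simulation replicates.

    NaN replicates (e.g. a Goldberg-accepted subset too small to fit) are
    excluded, and the count of replicates actually used is reported.
    """
    b = np.asarray(beta_hats, dtype=float)
    lo = np.asarray(ci_lows, dtype=float)
    hi = np.asarray(ci_highs, dtype=float)
    ok = np.isfinite(b) & np.isfinite(lo) & np.isfinite(hi)
    b, lo, hi = b[ok], lo[ok], hi[ok]
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 usable replicates")
    mean_b = float(b.mean())
    bias = mean_b - beta1
    mse = float(np.mean((b - mean_b) ** 2)) + bias**2
    coverage = float(np.mean((lo < beta1) & (beta1 < hi)))  # strict inequalities
    return PerformanceSummary(bias=bias, mse=mse, coverage=coverage, beta1=beta1, n_replicates_used=n)


def summarize_simulation(
    results: pd.DataFrame,
    beta1_map: dict[tuple[str, str], float],
) -> pd.DataFrame:
    """Per (nutrient, outcome, estimator) performance table from engine output.

    ``beta1_map`` gives the true slope per pair (the a1 fitted from the
    source cohort). Output columns: nutrient, outcome, estimator, bias, mse,
    coverage, beta1, n_replicates_used.
    """
    rows = []
    for (nut, out, est), grp in results.groupby(["nutrient", "outcome", "estimator"], sort=False):
        beta1 = beta1_map[(nut, out)]
        summary = summarize_performance(grp["beta_hat"], grp["ci_low"], grp["ci_high"], beta1)
        rows.append(
            dict(
                nutrient=nut,
                outcome=out,
                estimator=est,
                bias=summary.bias,
                mse=summary.mse,
                coverage=summary.coverage,
                beta1=beta1,
                n_replicates_used=summary.n_replicates_used,
            )
        )
    return pd.DataFrame(rows)


def association_flags(
    b_lo: float, b_hi: float, r_lo: float, r_hi: float
) -> tuple[bool, bool, bool]:
    """Significance flags: bias (b CI excludes 0), remaining bias (r CI
    excludes 0), bias reduction (r CI within (-100, 100))."""
    significant_bias = not (b_lo <= 0.0 <= b_hi)
    significant_remaining = not (r_lo <= 0.0 <= r_hi)
    significant_reduction = (-100.0 < r_lo) and (r_hi < 100.0)
    return significant_bias, significant_remaining, significant_reduction
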