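"""Percentile-dependent reporting-error model for self-reported intake.

For one nutrient, the reporting error of participant *i* is
e_i = NI_SR,i - NI_BIO,i. Its mean is modelled as a polynomial in the
percentile p of NI_BIO in a fixed reference distribution,

    mu(p) = sum_{k=0..K} m_k p^k,

with a constant standard deviation sigma (homoskedasticity is checked with a
Goldfeld-Quandt variance-ratio test). The polynomial order K is selected by
k-fold cross-validation over candidate orders (1..5 by default), choosing the
order with the smallest out-of-fold MSE.

Percentiles follow the Hazen convention p = (rank - 0.5)/n evaluated against
the fixed reference sample (the full source cohort), so mu is always evaluated
on the scale it was fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats


__all__ = [
    "PercentileRef",
    "ErrorModel",
    "empirical_percentile",
    "mean_error",
    "fit_mean_error",
    "select_order_cv",
    "estimate_sigma",
    "goldfeld_quandt",
    "fit_error_model",
]


@dataclass(frozen=True)
class PercentileRef:
    """Fixed reference distribution of one nutrient's biomarker intake."""

    values: np.ndarray  # sorted ascending
    convention: str = "hazen"

    @classmethod
    def from_sample(cls, sample) -> "PercentileRef":
        arr = np.sort(np.asarray(sample, dtype=float))
        if arr.size == 0:
            raise ValueError("percentile reference must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("percentile reference contains non-finite values")
        return cls(values=arr)

    def __len__(self) -> int:
        return self.values.size


def empirical_percentile(ref: PercentileRef, x) -> np.ndarray | float:
    """Hazen percentile of ``x`` in the reference distribution.

    p = (rank - 0.5)/n where rank counts reference values <= x; results are
    clamped to [0.5/n, 1 - 0.5/n] so out-of-range values map to the extreme
    in-sample percentiles. Monotone non-decreasing in x.
    """
    if len(ref) == 0:
        raise ValueError("empty percentile reference")
    n = len(ref)
    scalar = np.isscalar(x)
    xv = np.asarray(x, dtype=float)
    rank = np.searchsorted(ref.values, xv, side="right")
    p = np.clip((rank - 0.5) / n, 0.5 / n, 1.0 - 0.5 / n)
    return float(p) if scalar else p


@dataclass(frozen=True)
class ErrorModel:
    """Fitted (or generating-truth) reporting-error model for one nutrient.

    coefficients
        m_0..m_K ascending in the percentile power (nutrient units).
    order
        Polynomial order K (1..5).
    sigma
        Constant error SD, nutrient units.
    reference
        Percentile reference the polynomial was fitted against.
    """

    coefficients: np.ndarray
    order: int
    sigma: float
    reference: PercentileRef
    cv_mse: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.size != self.order + 1:
            raise ValueError(f"expected {self.order + 1} coefficients, got {coef.size}")
        if not (1 <= self.order <= 5):
            raise ValueError(f"polynomial order must be in 1..5, got {self.order}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def mean(self, p) -> np.ndarray | float:
        return mean_error(self, p)

    def mean_at(self, x) -> np.ndarray | float:
        """mu evaluated at raw biomarker values via the stored reference."""
        return mean_error(self, empirical_percentile(self.reference, x))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "order": self.order,
            "sigma": self.sigma,
            "reference": self.reference.values.tolist(),
            "cv_mse": {str(k): v for k, v in self.cv_mse.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ErrorModel":
        return cls(
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            order=int(payload["order"]),
            sigma=float(payload["sigma"]),
            reference=PercentileRef.from_sample(payload["reference"]),
            cv_mse={int(k): float(v) for k, v in payload.get("cv_mse", {}).items()},
        )


def mean_error(model: ErrorModel, p) -> np.ndarray | float:
    """Evaluate the polynomial mean-error function mu at percentile(s) p."""
    pv = np.asarray(p, dtype=float)
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("percentiles must lie in [0, 1]")
    out = npoly.polyval(pv, model.coefficients)
    return float(out) if np.isscalar(p) else out


def fit_mean_error(percentiles, errors, order: int) -> np.ndarray:
    """Least-squares polynomial m_0..m_K of errors on percentile powers."""
    p = np.asarray(percentiles, dtype=float)
    e = np.asarray(errors, dtype=float)
    if p.shape != e.shape:
        raise ValueError("percentiles and errors must have equal length")
    if p.size < order + 1:
        raise ValueError(f"need at least {order + 1} observations to fit order {order}")
    if np.ptp(p) == 0:
        raise ValueError("degenerate design: all percentiles identical")
    # Vandermonde LS; orders <= 5 on [0,1] are well conditioned.
    coef, (_, rank, _, _) = np.polynomial.polynomial.polyfit(p, e, deg=order, full=True)
    if rank < order + 1:
        raise ValueError("rank-deficient polynomial design")
    return coef


def select_order_cv(
    percentiles,
    errors,
    k_range=(1, 2, 3, 4, 5),
    folds: int = 10,
    rng: np.random.Generator | None = None,
    return_mse: bool = False,
):
    """Select the polynomial order by k-fold cross-validated MSE.

    Folds are a seeded uniform random partition into near-equal parts. Ties
    in CV-MSE (within 1e-10 relative) resolve to the smaller order.
    """
    p = np.asarray(percentiles, dtype=float)
    e = np.asarray(errors, dtype=float)
    n = p.size
    if n < folds:
        raise ValueError(f"n={n} is smaller than the number of folds ({folds})")
    candidates = sorted(set(int(k) for k in k_range))
    if not candidates:
        raise ValueError("empty candidate order set")
    rng = rng or np.random.default_rng()

    idx = rng.permutation(n)
    fold_ids = np.array_split(idx, folds)

    cv_mse: dict[int, float] = {}
    for order in candidates:
        sq_errs = np.empty(n)
        pos = 0
        for test_idx in fold_ids:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            coef = fit_mean_error(p[train_mask], e[train_mask], order)
            pred = npoly.polyval(p[test_idx], coef)
            k = test_idx.size
            sq_errs[pos : pos + k] = (e[test_idx] - pred) ** 2
            pos += k
        cv_mse[order] = float(sq_errs.mean())

    best = min(cv_mse.values())
    # parsimony tie-break: smallest order within relative tolerance of the
    # best; the data variance sets the scale so exactly-fit (noiseless) data
    # count as ties rather than comparing rounding noise
    scale = max(abs(best), float(np.var(e)), 1e-300)
    selected = min(k for k, v in cv_mse.items() if (v - best) / scale <= 1e-10)
    if return_mse:
        return selected, cv_mse
    return selected


def estimate_sigma(percentiles, errors, coefficients) -> float:
    """Residual SD of e - mu(p) with denominator n - (K+1)."""
    p = np.asarray(percentiles, dtype=float)
    e = np.asarray(errors, dtype=float)
    coef = np.asarray(coefficients, dtype=float)
    n, k_plus_1 = e.size, coef.size
    if n <= k_plus_1:
        raise ValueError(f"need n > K+1 residual df (n={n}, K+1={k_plus_1})")
    resid = e - npoly.polyval(p, coef)
    return float(np.sqrt(np.sum(resid**2) / (n - k_plus_1)))


def goldfeld_quandt(errors, ordering, middle_frac: float = 0.2) -> tuple[float, float, int]:
    """Goldfeld-Quandt homoskedasticity check on reporting errors.

    Observations are sorted by ``ordering`` (typically biomarker intake), the
    central round(n * middle_frac) observations are discarded (round half up;
    303 at 20% discards 61), and F is the ratio (larger/smaller) of the
    variances of the errors about their own group means in the high vs low
    groups. The p-value is two-sided from the F distribution.

    Returns (F, p, n_discarded).
    """
    e = np.asarray(errors, dtype=float)
    o = np.asarray(ordering, dtype=float)
    if e.shape != o.shape:
        raise ValueError("errors and ordering must have equal length")
    n = e.size
    if not (0 <= middle_frac < 1):
        raise ValueError("middle_frac must lie in [0, 1)")
    n_discard = int(np.floor(n * middle_frac + 0.5))  # round half up
    n_keep = n - n_discard
    n_low = n_keep // 2
    n_high = n_keep - n_low
    if min(n_low, n_high) < 2:
        raise ValueError("groups too small after discarding the middle band")

    e_sorted = e[np.argsort(o, kind="stable")]
    low = e_sorted[:n_low]
    high = e_sorted[n - n_high :]
    var_low = float(np.var(low, ddof=1))
    var_high = float(np.var(high, ddof=1))
    if var_low == 0 and var_high == 0:
        return 1.0, 1.0, n_discard
    if var_high >= var_low:
        f_stat = var_high / var_low
        dfn, dfd = n_high - 1, n_low - 1
    else:
        f_stat = var_low / var_high
        dfn, dfd = n_low - 1, n_high - 1
    p_value = min(1.0, 2.0 * float(stats.f.sf(f_stat, dfn, dfd)))
    return f_stat, p_value, n_discard


def fit_error_model(
    cohort,
    nutrient_sr_col: str,
    nutrient_bio_col: str,
    folds: int = 10,
    k_range=(1, 2, 3, 4, 5),
    rng: np.random.Generator | None = None,
) -> ErrorModel:
    """Fit the full reporting-error model for one nutrient from a cohort table.

    Computes e = NI_SR - NI_BIO, Hazen percentiles of NI_BIO against the
    cohort itself, selects the polynomial order by CV, fits the coefficients
    on all rows, and estimates the constant sigma.
    """
    data = cohort[[nutrient_sr_col, nutrient_bio_col]].dropna()
    sr = data[nutrient_sr_col].to_numpy(dtype=float)
    bio = data[nutrient_bio_col].to_numpy(dtype=float)
    errors = sr - bio
    ref = PercentileRef.from_sample(bio)
    p = empirical_percentile(ref, bio)
    order, cv_mse = select_order_cv(p, errors, k_range=k_range, folds=folds, rng=rng, return_mse=True)
    coef = fit_mean_error(p, errors, order)
    sigma = estimate_sigma(p, errors, coef)
    return ErrorModel(coefficients=coef, order=order, sigma=sigma, reference=ref, cv_mse=cv_mse)
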