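"""Synthetic IDATA-like cohort generator.

Stands in for the restricted empirical dataset: draws (FFM, four biomarker
intakes) from a truncated multivariate normal whose marginal means/SDs match
the published cohort summaries, then builds each self-report as
NI_SR = NI_BIO + mu(p(NI_BIO)) + N(0, sigma^2), truncated positive, and each
health outcome from a linear model on its designated nutrient's biomarker.

Calibration solves the generating-truth error model (polynomial mean-error
function plus constant SD) from three printed summaries per nutrient: the mean
reporting error, its SD, and the error-biomarker correlation implied by the
published SDs through Var(SR - BIO) = Var(SR) + Var(BIO) - 2 Cov(SR, BIO).
The mean-error polynomial is parameterised in the shifted Legendre basis on
[0, 1] (orthogonal under the uniform percentile distribution), which makes the
mean, variance and covariance constraints separable:

    mu(p) = mean + sum_k c_k q_k(p),   Var(mu) = sum_k c_k^2 / (2k + 1),
    Cov(e, BIO) = sd_bio * sum_k c_k g_k,  g_k = E[q_k(Phi(Z)) Z],

with g_k computed by Gauss-Hermite quadrature. The top-degree coefficient of
each nutrient's truth polynomial (orders 1, 3, 3, 5 for energy, sodium,
potassium, protein) is fixed at half the error SD — large enough, by a paired
cross-validation power argument, for 10-fold CV at n = 303 to recover the
generating order — and the linear coefficient is solved for the correlation
target; sigma^2 absorbs the remaining variance budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Legendre, Polynomial
from scipy import stats
from scipy.special import roots_hermitenorm

from .error_model import ErrorModel, PercentileRef, empirical_percentile
from .models import (
    FFM_COLUMN,
    ID_COLUMN,
    NUTRIENTS,
    OUTCOMES,
    OutcomeModel,
    bio_column,
    outcome_column,
    sr_column,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NutrientSpec",
    "OutcomeSpec",
    "CohortConfig",
    "CohortTruth",
    "derive_sr_bio_correlation",
    "derive_error_bio_correlation",
    "calibrate_linear_mu",
    "calibrate_error_truth",
    "generate",
]


class CalibrationError(ValueError):
    """Printed summaries admit no consistent generating model."""


@dataclass(frozen=True)
class NutrientSpec:
    """Per-nutrient calibration targets (published cohort summaries)."""

    sr_mean: float
    sr_sd: float
    bio_mean: float
    bio_sd: float
    bias_mean: float  # mean of NI_SR - NI_BIO
    bias_sd: float
    order: int  # generating-truth polynomial order


@dataclass(frozen=True)
class OutcomeSpec:
    """Marginal moments of one outcome and its designated generating nutrient.

    ``published`` marks marginals taken from the cohort summary table; the
    others (HR, SBP, DBP, VO2 and every correlation) are plausible,
    configurable defaults chosen for this generator.
    """

    nutrient: str
    mean: float
    sd: float
    corr: float  # correlation with the designated nutrient's biomarker
    published: bool = False


#: Published marginals: means/SDs of self-report, biomarker and their
#: difference per nutrient, and the generating polynomial orders 1, 3, 3, 5.
DEFAULT_NUTRIENTS: dict[str, NutrientSpec] = {
    "EI": NutrientSpec(2048.0, 783.4, 2400.3, 492.8, -352.3, 811.0, order=1),
    "SI": NutrientSpec(3457.9, 1440.8, 4015.0, 1995.7, -557.0, 2075.2, order=3),
    "PoI": NutrientSpec(2931.4, 1136.9, 3210.9, 1253.9, -279.5, 1404.8, order=3),
    "PrI": NutrientSpec(83.0, 38.8, 94.5, 38.3, -11.5, 41.6, order=5),
}

#: Outcome marginals. BW/WC are published; the rest are plausible defaults.
DEFAULT_OUTCOMES: dict[str, OutcomeSpec] = {
    "BW": OutcomeSpec("EI", 79.4, 17.1, corr=0.40, published=True),
    "WC": OutcomeSpec("EI", 92.0, 14.2, corr=0.45, published=True),
    "HR": OutcomeSpec("EI", 120.0, 15.0, corr=0.15),
    "SBP": OutcomeSpec("SI", 125.0, 15.0, corr=0.25),
    "DBP": OutcomeSpec("SI", 75.0, 10.0, corr=0.20),
    "VO2": OutcomeSpec("PoI", 2.2, 0.6, corr=0.35),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the published summaries."""

    n: int = 303
    nutrients: dict[str, NutrientSpec] = field(default_factory=lambda: dict(DEFAULT_NUTRIENTS))
    outcomes: dict[str, OutcomeSpec] = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    ffm_mean: float = 48.9  # kg, published
    ffm_sd: float = 10.9
    ffm_ei_corr: float = 0.6  # not published; physiologically motivated default
    cross_nutrient_corr: float = 0.5  # not published; configurable default
    shape_amplitude: float = 0.5  # top Legendre coefficient, units of bias SD
    error_factor_loading: float = 0.5  # shared misreporting factor loading, in [0, 1)
    pilot_n: int = 50000  # pilot size for the truncation moment-matching

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for name, spec in self.nutrients.items():
            if spec.sr_sd < 0 or spec.bio_sd < 0 or spec.bias_sd < 0:
                raise ValueError(f"negative SD in nutrient spec {name}")
        if not (-1 < self.ffm_ei_corr < 1 and -1 < self.cross_nutrient_corr < 1):
            raise ValueError("correlations must lie in (-1, 1)")
        if not (0 <= self.error_factor_loading < 1):
            raise ValueError("error_factor_loading must lie in [0, 1)")


@dataclass(frozen=True)
class CohortTruth:
    """The generating models actually used for one synthetic draw."""

    error_models: dict[str, ErrorModel]
    outcome_models: dict[tuple[str, str], OutcomeModel]


def derive_sr_bio_correlation(sd_sr: float, sd_bio: float, sd_bias: float) -> float:
    """corr(SR, BIO) implied by the three printed SDs.

    From Var(SR - BIO) = Var(SR) + Var(BIO) - 2 Cov(SR, BIO).
    """
    if sd_sr <= 0 or sd_bio <= 0 or sd_bias < 0:
        raise ValueError("SDs must be positive (bias SD non-negative)")
    rho = (sd_sr**2 + sd_bio**2 - sd_bias**2) / (2.0 * sd_sr * sd_bio)
    if abs(rho) >= 1:
        raise CalibrationError(f"implied corr(SR, BIO) = {rho:.4f} is outside (-1, 1)")
    return rho


def derive_error_bio_correlation(sd_sr: float, sd_bio: float, sd_bias: float) -> float:
    """corr(SR - BIO, BIO) implied by the printed SDs.

    Cov(e, BIO) = Cov(SR, BIO) - Var(BIO) = (sd_SR^2 - sd_BIO^2 - sd_e^2)/2.
    """
    if sd_bias <= 0:
        raise ValueError("bias SD must be positive")
    derive_sr_bio_correlation(sd_sr, sd_bio, sd_bias)  # feasibility check
    cov_e_bio = (sd_sr**2 - sd_bio**2 - sd_bias**2) / 2.0
    rho = cov_e_bio / (sd_bias * sd_bio)
    if abs(rho) >= 1:
        raise CalibrationError(f"implied corr(e, BIO) = {rho:.4f} is outside (-1, 1)")
    return rho


def _legendre_q(k: int) -> Polynomial:
    """Shifted Legendre polynomial q_k on [0, 1] in the power basis."""
    coef = np.zeros(k + 1)
    coef[k] = 1.0
    return Legendre(coef, domain=[0, 1]).convert(kind=Polynomial)


def _gauss_hermite_gk(max_k: int, n_nodes: int = 120) -> np.ndarray:
    """g_k = E[q_k(Phi(Z)) * Z] for Z ~ N(0,1), k = 0..max_k."""
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / np.sqrt(2.0 * np.pi)
    u = stats.norm.cdf(nodes)
    out = np.empty(max_k + 1)
    for k in range(max_k + 1):
        out[k] = float(np.sum(weights * _legendre_q(k)(u) * nodes))
    return out


def _legendre_to_power(c: np.ndarray, mean: float) -> np.ndarray:
    """Power-basis m_0..m_K from zero-mean Legendre coefficients c_1..c_K."""
    order = c.size - 1
    poly = Polynomial([mean])
    for k in range(1, order + 1):
        poly = poly + c[k] * _legendre_q(k)
    coef = np.zeros(order + 1)
    coef[: len(poly.coef)] = poly.coef
    return coef


def _solve_legendre(spec: NutrientSpec, shape_amplitude: float) -> tuple[np.ndarray, float]:
    """Closed-form Legendre solution of the calibration under exact normality."""
    order = spec.order
    target_corr = derive_error_bio_correlation(spec.sr_sd, spec.bio_sd, spec.bias_sd)
    g = _gauss_hermite_gk(order)

    c = np.zeros(order + 1)  # c[0] is the mean slot, handled separately
    if order >= 2:
        c[order] = shape_amplitude * spec.bias_sd * np.sign(target_corr if target_corr != 0 else 1.0)
    # linear coefficient carries the remainder of the covariance target
    c[1] = (target_corr * spec.bias_sd - float(c[2:] @ g[2:] if order >= 2 else 0.0)) / g[1]

    var_mu = float(sum(c[k] ** 2 / (2 * k + 1) for k in range(1, order + 1)))
    var_noise = spec.bias_sd**2 - var_mu
    if var_noise <= 0:
        raise CalibrationError(
            f"no feasible sigma: mean-error polynomial already needs variance {var_mu:.1f} "
            f"against a budget of {spec.bias_sd**2:.1f}"
        )
    return c, float(np.sqrt(var_noise))


def calibrate_error_truth(
    spec: NutrientSpec,
    shape_amplitude: float = 0.5,
    corr_tolerance: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Solve a generating-truth (mu polynomial, sigma) from printed summaries.

    Returns power-basis coefficients m_0..m_K and sigma. The achieved
    (mean, SD, correlation) triple is verified analytically against the
    targets; an infeasible triple raises ``CalibrationError``.
    """
    c, sigma = _solve_legendre(spec, shape_amplitude)
    g = _gauss_hermite_gk(spec.order)
    target_corr = derive_error_bio_correlation(spec.sr_sd, spec.bio_sd, spec.bias_sd)
    achieved_corr = float(c[1:] @ g[1:]) / spec.bias_sd
    if abs(achieved_corr - target_corr) > corr_tolerance:
        raise CalibrationError(
            f"calibration reached corr {achieved_corr:.4f}, target {target_corr:.4f}"
        )
    return _legendre_to_power(c, spec.bias_mean), sigma


def _refine_error_truth(
    spec: NutrientSpec,
    shape_amplitude: float,
    bio_pilot: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 3,
) -> tuple[np.ndarray, float]:
    """Fixed-point refinement of (c_1, sigma) against a pilot biomarker draw.

    The closed-form solution assumes an exactly normal biomarker marginal and
    no self-report truncation; joint zero-truncation perturbs both. Pilot
    error draws nudge the linear coefficient until the realized error to
    biomarker correlation is on target and sigma until the error SD is, each
    time restoring the mean analytically.
    """
    c, sigma = _solve_legendre(spec, shape_amplitude)
    target_corr = derive_error_bio_correlation(spec.sr_sd, spec.bio_sd, spec.bias_sd)
    g1 = float(_gauss_hermite_gk(1)[1])
    ref = PercentileRef.from_sample(bio_pilot)
    p = empirical_percentile(ref, bio_pilot)
    for _ in range(n_iter):
        coef = _legendre_to_power(c, spec.bias_mean)
        mu = np.polynomial.polynomial.polyval(p, coef)
        coef0_shift = _solve_truncation_offset(bio_pilot, mu, sigma)
        e = _draw_sr_error(bio_pilot, mu - coef0_shift, sigma, rng)
        sd_e = float(e.std(ddof=1))
        corr = float(np.corrcoef(e, bio_pilot)[0, 1])
        c[1] += (target_corr - corr) * sd_e / g1
        var_noise = sigma**2 + spec.bias_sd**2 - sd_e**2
        if var_noise <= 0:
            raise CalibrationError("sigma refinement collapsed; targets inconsistent")
        sigma = float(np.sqrt(var_noise))
    return c, sigma


def calibrate_linear_mu(
    target_bias_mean: float,
    target_bias_sd: float,
    target_error_bio_corr: float,
) -> tuple[float, float, float]:
    """Linear-mu special case: solve (m_0, m_1, sigma) from the three targets.

    With p uniform on (0, 1): m_0 + m_1/2 = mean, m_1^2/12 + sigma^2 =
    variance, and the slope's sign/magnitude follow the correlation target.
    """
    if not np.isfinite(target_error_bio_corr) or abs(target_error_bio_corr) >= 1:
        raise CalibrationError("target correlation must lie in (-1, 1)")
    if target_bias_sd <= 0:
        raise ValueError("bias SD must be positive")
    g1 = float(_gauss_hermite_gk(1)[1])  # E[(2 Phi(Z) - 1) Z] = 1/sqrt(pi)
    c1 = target_error_bio_corr * target_bias_sd / g1
    var_mu = c1**2 / 3.0
    if var_mu >= target_bias_sd**2:
        raise CalibrationError("correlation target too strong for a linear mean-error model")
    sigma = float(np.sqrt(target_bias_sd**2 - var_mu))
    m1 = 2.0 * c1  # q_1(p) = 2p - 1
    m0 = target_bias_mean - c1
    return m0, m1, sigma


def _build_joint(config: CohortConfig, nutrient_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance of (FFM, biomarkers) on the natural scale."""
    means = [config.ffm_mean] + [config.nutrients[n].bio_mean for n in nutrient_names]
    sds = [config.ffm_sd] + [config.nutrients[n].bio_sd for n in nutrient_names]
    k = len(means)
    corr = np.full((k, k), config.cross_nutrient_corr)
    np.fill_diagonal(corr, 1.0)
    for j, name in enumerate(nutrient_names, start=1):
        corr[0, j] = corr[j, 0] = (
            config.ffm_ei_corr if name == "EI" else config.ffm_ei_corr * config.cross_nutrient_corr
        )
    cov = np.outer(sds, sds) * corr
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError("configured correlations are not positive definite") from exc
    return np.asarray(means), cov


def _draw_truncated_mvn(
    mean: np.ndarray, cov: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """MVN draw with rows containing non-positive values redrawn."""
    draw = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    for _ in range(_MAX_ROUNDS):
        bad = (draw <= 0).any(axis=1)
        if not bad.any():
            break
        draw[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="cholesky")
    else:
        draw = np.maximum(draw, 1e-6)
    return draw


_MAX_ROUNDS = 100


def _match_truncated_moments(
    mean: np.ndarray,
    cov: np.ndarray,
    pilot_n: int,
    rng: np.random.Generator,
    n_iter: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust the latent mean/scale so the truncated draw hits the targets.

    Zero-truncation shifts the realized means upward and shrinks the SDs
    (noticeably for sodium, whose mean sits about two SDs above zero). Pilot
    draws iterate a fixed-point update of the latent mean vector and the
    per-coordinate scales, keeping the configured correlation structure.
    """
    sd_target = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd_target, sd_target)
    mean_lat = mean.copy()
    sd_lat = sd_target.copy()
    for _ in range(n_iter):
        cov_lat = np.outer(sd_lat, sd_lat) * corr
        pilot = _draw_truncated_mvn(mean_lat, cov_lat, pilot_n, rng)
        mean_lat += mean - pilot.mean(axis=0)
        sd_lat *= sd_target / pilot.std(axis=0, ddof=1)
    return mean_lat, np.outer(sd_lat, sd_lat) * corr


def _truncation_mean_shift(bio: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    """Mean shift in e caused by redrawing noise until NI_BIO + e > 0.

    Per row, redraw-until-accept makes e a normal truncated below at -bio;
    the expected shift is sigma * phi(alpha) / (1 - Phi(alpha)) with
    alpha = (-bio - mu)/sigma. Averaged over rows; analytic, no sampling.
    """
    if sigma <= 0:
        return 0.0
    alpha = (-bio - mu) / sigma
    # hazard of the standard normal, numerically safe for very negative alpha
    shift = sigma * np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha))
    return float(np.mean(shift))


def _solve_truncation_offset(bio: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    """Offset delta with mean(redrawn e | mu - delta) back on target.

    Subtracting the shift lowers mu, which itself increases the shift
    (second order); a few fixed-point steps of delta = shift(mu - delta)
    remove that residual.
    """
    delta = 0.0
    for _ in range(3):
        delta = _truncation_mean_shift(bio, mu - delta, sigma)
    return delta


def generate(
    config: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a synthetic cohort and return it with its generating truths.

    Calibration contract: at large n the mean and SD of each nutrient's
    reporting error match the configured targets, the error-biomarker
    correlation is negative (for the default targets), and every intake and
    FFM value is strictly positive. A one-step mean adjustment after a pilot
    draw corrects the small truncation distortion of the biomarker marginals,
    and an analytic constant-offset correction keeps the mean reporting error
    on target despite the NI_SR > 0 truncation.
    """
    config = config or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    nutrient_names = [n for n in NUTRIENTS if n in config.nutrients]

    # Closed-form calibration up front so infeasible targets fail early.
    for name in nutrient_names:
        if config.nutrients[name].bias_sd > 0:
            calibrate_error_truth(config.nutrients[name], config.shape_amplitude)

    mean, cov = _build_joint(config, nutrient_names)
    mean_adj, cov_adj = _match_truncated_moments(mean, cov, config.pilot_n, rng)
    pilot = _draw_truncated_mvn(mean_adj, cov_adj, config.pilot_n, rng)

    truth_coef: dict[str, np.ndarray] = {}
    truth_sigma: dict[str, float] = {}
    for j, name in enumerate(nutrient_names, start=1):
        spec = config.nutrients[name]
        if spec.bias_sd == 0:  # degenerate: deterministic shift (or identity)
            truth_coef[name] = np.array([spec.bias_mean, 0.0])
            truth_sigma[name] = 0.0
            continue
        c, sigma = _refine_error_truth(spec, config.shape_amplitude, pilot[:, j], rng)
        truth_coef[name] = _legendre_to_power(c, spec.bias_mean)
        truth_sigma[name] = sigma

    joint = _draw_truncated_mvn(mean_adj, cov_adj, config.n, rng)

    ffm = joint[:, 0]
    data = {ID_COLUMN: np.arange(1, config.n + 1), FFM_COLUMN: ffm}
    error_models: dict[str, ErrorModel] = {}
    # shared person-level misreporting factor: someone who under-reports
    # energy tends to under-report the other nutrients too; loadings leave
    # each nutrient's marginal error distribution unchanged
    lam = config.error_factor_loading
    u_shared = rng.standard_normal(config.n)
    for j, name in enumerate(nutrient_names, start=1):
        bio = joint[:, j]
        ref = PercentileRef.from_sample(bio)
        p = empirical_percentile(ref, bio)
        coef = truth_coef[name].copy()
        sigma = truth_sigma[name]
        sigma_idio = sigma * float(np.sqrt(1.0 - lam**2))
        mu_eff = np.polynomial.polynomial.polyval(p, coef) + sigma * lam * u_shared
        # analytic one-step offset so the SR>0 truncation leaves the mean on target
        shift = _solve_truncation_offset(bio, mu_eff, sigma_idio)
        coef[0] -= shift
        model = ErrorModel(
            coefficients=coef,
            order=config.nutrients[name].order,
            sigma=sigma,
            reference=ref,
        )
        e = _draw_sr_error(bio, mu_eff - shift, sigma_idio, rng)
        data[bio_column(name)] = bio
        data[sr_column(name)] = bio + e
        error_models[name] = model

    outcome_models: dict[tuple[str, str], OutcomeModel] = {}
    for out_name in OUTCOMES:
        if out_name not in config.outcomes:
            continue
        spec = config.outcomes[out_name]
        nspec = config.nutrients[spec.nutrient]
        a1 = spec.corr * spec.sd / nspec.bio_sd
        a0 = spec.mean - a1 * nspec.bio_mean
        eta = spec.sd * float(np.sqrt(1.0 - spec.corr**2))
        om = OutcomeModel(a0=a0, a1=a1, eta=eta)
        bio = data[bio_column(spec.nutrient)]
        data[outcome_column(out_name)] = om.a0 + om.a1 * bio + om.eta * rng.standard_normal(config.n)
        outcome_models[(spec.nutrient, out_name)] = om

    df = pd.DataFrame(data)
    return df, CohortTruth(error_models=error_models, outcome_models=outcome_models)


def _draw_sr_error(bio: np.ndarray, mu: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Noise draw with redraw-until-positive truncation of NI_SR."""
    e = mu + sigma * rng.standard_normal(bio.size)
    if sigma > 0:
        bad = bio + e <= 0
        rounds = 0
        while bad.any() and rounds < _MAX_ROUNDS:
            e[bad] = mu[bad] + sigma * rng.standard_normal(int(bad.sum()))
            bad = bio + e <= 0
            rounds += 1
        if bad.any():
            logger.warning("clamping %d synthetic self-reports to 1", int(bad.sum()))
            e[bad] = 1.0 - bio[bad]
    else:
        e = np.where(bio + e <= 0, 1.0 - bio, e)
    return e
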