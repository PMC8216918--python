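"""The measurement-error regression model: densities, transforms, priors.

The model links an observed survival rate ``D_i`` (a probability, reported
with a standard error ``se_i``) and an observed covariate ``W_i`` (e.g.
standard body length in cm, with measurement-error variance ``var_u_i``)
to latent true quantities through four layers:

  observation, rate:       D_i | p_i        ~ Beta(p_i phi_i, (1-p_i) phi_i)
  observation, covariate:  W_i | X_i        ~ Normal(X_i, var_u_i)
  regression (logit):      Y   | X, params  ~ MVN(alpha + beta X, sigma2_eps * Sigma_k)
  covariate population:    X   | params     ~ MVN(mu_x 1, sigma2_x * Sigma_k(lambda))

with ``p_i = inv_logit(Y_i)`` and the beta precision ``phi_i`` chosen so the
observation distribution has mean ``p_i`` and standard deviation ``se_i``.
``Sigma_k`` is one of K candidate phylogenetic correlation matrices (discrete
uniform prior over k); Pagel's lambda discounts the phylogenetic correlation
of the covariate population.  Everything here is a pure function of a
:class:`ModelState`; the sampler composes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln, logit as _sp_logit

from .trees import CovarianceSet, lambda_transform

__all__ = [
    "SpeciesRecord",
    "Priors",
    "ModelState",
    "logit",
    "inv_logit",
    "phi_from_se",
    "beta_shapes",
    "log_obs_rate",
    "log_obs_cov",
    "log_latent_regression",
    "log_latent_cov_population",
    "log_joint",
    "log_joint_terms",
]

LOG2PI = math.log(2.0 * math.pi)
#: smallest admissible Cholesky pivot (relative) for MVN covariance factors
PIVOT_TOL = 1e-10


def logit(p):
    """log(p / (1-p)); errors outside the open unit interval."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires 0 < p < 1")
    out = _sp_logit(p)
    return float(out) if out.ndim == 0 else out


def inv_logit(y):
    """Logistic function, bounded in (0, 1)."""
    out = expit(np.asarray(y, dtype=float))
    return float(out) if out.ndim == 0 else out


def phi_from_se(p: float, se: float) -> float:
    """Beta precision giving mean ``p`` and standard deviation ``se``.

    ``phi = p(1-p)/se^2 - 1``; a Beta(p*phi, (1-p)*phi) variable then has
    variance ``se^2``.  Requires ``se^2 < p(1-p)`` (beta feasibility).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    v = p * (1.0 - p)
    if se * se >= v:
        raise ValueError(
            f"se={se} infeasible for rate p={p}: se^2 must be < p(1-p) = {v:.6g}"
        )
    return v / (se * se) - 1.0


def beta_shapes(p: float, phi: float) -> tuple[float, float]:
    """Mean-precision beta shapes ``(p*phi, (1-p)*phi)``."""
    return p * phi, (1.0 - p) * phi


def log_obs_rate(D: float, p: float, phi: float) -> float:
    """Log density of an observed rate under Beta(p*phi, (1-p)*phi)."""
    if not 0 < D < 1:
        raise ValueError(f"observed rate must be strictly inside (0,1), got {D}")
    a, b = beta_shapes(p, phi)
    return float(
        gammaln(a + b) - gammaln(a) - gammaln(b)
        + (a - 1.0) * math.log(D) + (b - 1.0) * math.log1p(-D)
    )


def log_obs_cov(W: float, X: float, var_u: float) -> float:
    """Normal log density of the observed covariate given the true value.

    ``var_u = 0`` is the degenerate no-error case: W is X and the term
    contributes 0 to the joint.
    """
    if var_u < 0:
        raise ValueError(f"measurement-error variance must be >= 0, got {var_u}")
    if var_u == 0:
        return 0.0
    return float(-0.5 * (LOG2PI + math.log(var_u) + (W - X) ** 2 / var_u))


def _chol(C: np.ndarray):
    """Cholesky factor with a relative smallest-pivot check.

    Failure here means a genuinely singular/indefinite matrix and raises; it
    is never mapped to -inf (that is reserved for prior-support violations).
    """
    try:
        cf = cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"covariance matrix is not positive definite: {exc}") from exc
    piv = np.diag(cf[0])
    if np.min(piv) < PIVOT_TOL * np.max(piv):
        raise ValueError("covariance matrix is singular beyond tolerance 1e-10")
    return cf


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, C: np.ndarray, scale: float) -> float:
    """MVN log density with covariance ``scale * C`` via Cholesky of C."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if scale <= 0:
        raise ValueError(f"covariance scale must be > 0, got {scale}")
    cf = _chol(np.asarray(C, dtype=float))
    r = x - mean
    z = cho_solve(cf, r, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0])))) + n * math.log(scale)
    return float(-0.5 * (n * LOG2PI + logdet + r @ z / scale))


def log_latent_regression(Y, X, alpha, beta, sigma2_eps, C) -> float:
    """MVN log density of the latent logit survival rates.

    mean = alpha + beta*X, covariance = sigma2_eps * C.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    return mvn_logpdf(Y, alpha + beta * X, C, sigma2_eps)


def log_latent_cov_population(X, mu_x, sigma2_x, C_lam) -> float:
    """MVN log density of the latent covariate population.

    mean = mu_x * 1, covariance = sigma2_x * C_lam (lambda-transformed).
    """
    X = np.asarray(X, dtype=float)
    return mvn_logpdf(X, np.full(X.shape[0], mu_x), C_lam, sigma2_x)


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' observed data.

    D is the observed survival rate on (0,1), se_D its standard error, W the
    observed covariate value and var_u the covariate measurement-error
    variance (squared standard error).
    """

    species: str
    D: float
    se_D: float
    W: float = 0.0
    var_u: float = 0.0

    def __post_init__(self):
        if not 0 < self.D < 1:
            raise ValueError(
                f"{self.species}: rate {self.D} outside (0,1); rates of exactly 0 or 1 "
                "are unsupported — supply a CI-derived SE and a nudged rate instead"
            )
        if self.se_D <= 0:
            raise ValueError(f"{self.species}: se_D must be > 0")
        if self.se_D**2 >= self.D * (1 - self.D):
            raise ValueError(
                f"{self.species}: se_D={self.se_D} beta-infeasible for rate {self.D}"
            )
        if not np.isfinite(self.var_u) or self.var_u < 0:
            raise ValueError(f"{self.species}: var_u must be finite and >= 0")


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the weakly informative default priors.

    Regression coefficients: Normal(0, 4).  Residual and covariate-population
    precisions: Gamma(1, 1).  Covariate population mean: Uniform(100, 700)
    (chosen for body lengths in cm).  Pagel's lambda: Uniform(0, 1).
    """

    coef_mean: float = 0.0
    coef_var: float = 4.0
    resid_prec_shape: float = 1.0
    resid_prec_rate: float = 1.0
    x_mean_lower: float = 100.0
    x_mean_upper: float = 700.0
    x_prec_shape: float = 1.0
    x_prec_rate: float = 1.0
    lambda_lower: float = 0.0
    lambda_upper: float = 1.0

    def __post_init__(self):
        if self.coef_var <= 0 or self.resid_prec_rate <= 0 or self.x_prec_rate <= 0:
            raise ValueError("prior variances/rates must be > 0")
        if self.resid_prec_shape <= 0 or self.x_prec_shape <= 0:
            raise ValueError("prior shapes must be > 0")
        if not (self.x_mean_lower < self.x_mean_upper):
            raise ValueError("x_mean bounds must satisfy lower < upper")
        if not (self.lambda_lower < self.lambda_upper):
            raise ValueError("lambda bounds must satisfy lower < upper")


@dataclass
class ModelState:
    """All latent quantities and parameters at one point in the chain."""

    Y: np.ndarray
    X: np.ndarray
    alpha: float
    beta: float
    sigma2_eps: float
    mu_x: float
    sigma2_x: float
    lam: float
    k: int = 0  # 0-based tree index

    def copy(self) -> "ModelState":
        return replace(self, Y=self.Y.copy(), X=self.X.copy())


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    return float(shape * math.log(rate) - gammaln(shape) + (shape - 1) * math.log(x) - rate * x)


def _log_normal_pdf(x: float, mean: float, var: float) -> float:
    return float(-0.5 * (LOG2PI + math.log(var) + (x - mean) ** 2 / var))


def log_joint_terms(
    state: ModelState,
    data: list[SpeciesRecord],
    covs: CovarianceSet,
    priors: Priors,
    lambda_on_residual: bool = False,
    observation_likelihood: bool = True,
) -> dict[str, float]:
    """Component log terms of the joint density, keyed by name.

    Support violations (mu_x outside its uniform bounds, lambda outside
    [0,1], non-positive variances, rates escaping (0,1), beta infeasibility)
    return -inf in the ``prior``/``obs_rate`` slots; numerical faults raise.
    """
    n = len(data)
    if covs.n != n:
        raise ValueError(f"{n} species records but {covs.n} species in covariance set")
    terms = dict.fromkeys(
        ["obs_rate", "obs_cov", "latent_regression", "latent_population", "prior"], 0.0
    )
    neg_inf = float("-inf")

    # prior support
    if not (priors.x_mean_lower <= state.mu_x <= priors.x_mean_upper):
        terms["prior"] = neg_inf
        return terms
    if not (priors.lambda_lower <= state.lam <= priors.lambda_upper):
        terms["prior"] = neg_inf
        return terms
    if state.sigma2_eps <= 0 or state.sigma2_x <= 0 or not (0 <= state.k < covs.K):
        terms["prior"] = neg_inf
        return terms

    p = inv_logit(state.Y)
    if observation_likelihood:
        for i, rec in enumerate(data):
            if not 0 < p[i] < 1:
                terms["obs_rate"] = neg_inf
                return terms
            if rec.se_D**2 >= p[i] * (1 - p[i]):
                terms["obs_rate"] = neg_inf  # latent rate too extreme for this SE
                return terms
            terms["obs_rate"] += log_obs_rate(rec.D, p[i], phi_from_se(p[i], rec.se_D))
            terms["obs_cov"] += log_obs_cov(rec.W, state.X[i], rec.var_u)

    C = covs.matrices[state.k]
    C_resid = lambda_transform(C, state.lam) if lambda_on_residual else C
    C_pop = lambda_transform(C, state.lam)
    terms["latent_regression"] = log_latent_regression(
        state.Y, state.X, state.alpha, state.beta, state.sigma2_eps, C_resid
    )
    terms["latent_population"] = log_latent_cov_population(
        state.X, state.mu_x, state.sigma2_x, C_pop
    )

    lp = _log_normal_pdf(state.alpha, priors.coef_mean, priors.coef_var)
    lp += _log_normal_pdf(state.beta, priors.coef_mean, priors.coef_var)
    lp += _log_gamma_pdf(1.0 / state.sigma2_eps, priors.resid_prec_shape, priors.resid_prec_rate)
    lp += _log_gamma_pdf(1.0 / state.sigma2_x, priors.x_prec_shape, priors.x_prec_rate)
    lp += -math.log(priors.x_mean_upper - priors.x_mean_lower)
    lp += -math.log(priors.lambda_upper - priors.lambda_lower)
    lp += -math.log(covs.K)
    terms["prior"] = lp
    return terms


def log_joint(
    state: ModelState,
    data: list[SpeciesRecord],
    covs: CovarianceSet,
    priors: Priors,
    **kwargs,
) -> float:
    """Unnormalised log joint density; -inf exactly on support violations."""
    return float(sum(log_joint_terms(state, data, covs, priors, **kwargs).values()))
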