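"""Metropolis-within-Gibbs sampler for the measurement-error regression.

The update scheme exploits every conditional conjugacy the model offers:

* ``(alpha, beta)`` — joint bivariate-normal draw (normal-normal conjugacy
  given the latent logit rates, latent covariates and residual covariance);
* ``1/sigma2_eps`` and ``1/sigma2_x`` — gamma draws;
* ``X`` — one joint multivariate-normal draw of the latent covariate vector
  (all of its dependencies are Gaussian); species with zero measurement-error
  variance are clamped to their observed value and the free block is drawn
  from its conditional;
* ``Y_i`` — per-species random-walk Metropolis (the beta observation term
  breaks conjugacy), with step sizes adapted toward 44% acceptance during
  the adaptation phase and frozen afterwards;
* ``mu_x`` — truncated-normal draw on its uniform prior support;
* ``lambda`` — random-walk Metropolis with reflection at the [0, 1]
  boundaries (reflection avoids sticky edges when posterior mass sits near 1);
* ``k`` — exact categorical draw from its discrete full conditional via
  log-sum-exp over the K candidate correlation matrices.

Per-chain generators are derived from the master seed, so runs are
bit-reproducible given (seed, config, inputs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import ndtr, ndtri

from . import __version__ as _pkg_version
from .model import (
    ModelState,
    Priors,
    SpeciesRecord,
    log_joint_terms,
    logit,
    mvn_logpdf,
)
from .trees import CovarianceSet, lambda_transform

__all__ = ["McmcConfig", "Chains", "fit", "initialize", "sample_tree_index"]

_DEFAULT_MONITOR = ("alpha", "beta", "sigma_eps", "lam", "mu_x", "sigma_x", "k")


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings; defaults follow the simulation-study tuning
    (3 chains, adapt 5,000, burn-in 15,000, thin 4, 35,000 retained draws)."""

    n_chains: int = 3
    n_adapt: int = 5000
    n_burn: int = 15000
    thin: int = 4
    n_keep: int = 35000
    seed: int = 0
    monitor: tuple[str, ...] = _DEFAULT_MONITOR
    monitor_latent: bool = False
    cri_level: float = 0.95

    def __post_init__(self):
        if min(self.n_chains, self.n_adapt, self.n_burn, self.n_keep) < 0:
            raise ValueError("chain counts must be non-negative")
        if self.n_chains < 1 or self.n_keep < 1:
            raise ValueError("need at least one chain and one retained draw")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.cri_level < 1:
            raise ValueError("cri_level must be in (0, 1)")


@dataclass
class Chains:
    """Posterior draws: one array of shape (n_chains, n_keep) per parameter
    (latent vectors, if monitored, have shape (n_chains, n_keep, n))."""

    draws: dict[str, np.ndarray]
    config: McmcConfig
    seed: int
    species: list[str]
    acceptance: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_keep(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def scalar_params(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per retained iteration per chain."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_keep),
                "iteration": np.tile(np.arange(self.n_keep), self.n_chains)}
        for name in self.scalar_params():
            cols[name] = self.draws[name].reshape(-1)
        for name, v in self.draws.items():
            if v.ndim == 3:
                for j, sp in enumerate(self.species):
                    cols[f"{name}[{sp}]"] = v[:, :, j].reshape(-1)
        return pd.DataFrame(cols)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "species": self.species,
            "phylosurv_version": _pkg_version,
        }

    def to_csv(self, path, manifest_path=None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest(), fh, indent=2)


def _chain_rng(seed: int, chain: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(chain)])


def initialize(
    data: list[SpeciesRecord],
    covs: CovarianceSet,
    priors: Priors,
    seed: int,
    chain: int = 0,
    fixed: dict | None = None,
    rng: np.random.Generator | None = None,
) -> ModelState:
    """Deterministic, chain-jittered starting state with finite log joint."""
    fixed = fixed or {}
    if rng is None:
        rng = _chain_rng(seed, chain)
    D = np.array([r.D for r in data])
    W = np.array([r.W for r in data])
    jitter = 0.1 * rng.standard_normal(2)
    state = ModelState(
        Y=logit(D),
        X=W.copy(),
        alpha=priors.coef_mean + jitter[0],
        beta=priors.coef_mean + jitter[1],
        sigma2_eps=0.25,
        mu_x=float(np.clip(np.mean(W), priors.x_mean_lower, priors.x_mean_upper)),
        sigma2_x=float(np.var(W)) if np.var(W) > 0 else 1.0,
        lam=0.5,
        k=int(rng.integers(covs.K)),
    )
    for name, value in fixed.items():
        setattr(state, name, value)
    return state


def _priors_for_check(priors: Priors, fixed: dict) -> Priors:
    """Fixing a parameter replaces its prior by a point mass; widen the
    support bounds so the init finiteness check accepts the fixed value."""
    if "mu_x" in fixed:
        priors = replace(
            priors,
            x_mean_lower=min(priors.x_mean_lower, fixed["mu_x"]),
            x_mean_upper=max(priors.x_mean_upper, fixed["mu_x"]),
        )
    return priors


def _truncnorm_draw(rng, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    pa, pb = ndtr(a), ndtr(b)
    if pb - pa < 1e-14:  # mass far outside the window: fall back to nearer bound
        return lo if a > 0 else hi
    u = rng.uniform(pa, pb)
    return float(mean + sd * ndtri(u))


def _reflect01(x: float) -> float:
    # reflection at 0 and 1 is the period-2 triangular map
    x = math.fmod(abs(x), 2.0)
    return 2.0 - x if x > 1.0 else x


class _Kernel:
    """Per-chain sampler state and update sweeps."""

    def __init__(self, data, covs, priors, *, fixed, lambda_on_residual,
                 observation_likelihood, rng, state):
        self.data = data
        self.covs = covs
        self.priors = priors
        self.fixed = fixed
        self.lam_on_resid = lambda_on_residual
        self.obs_like = observation_likelihood
        self.rng = rng
        self.s = state
        self.n = covs.n
        self.D = np.array([r.D for r in data])
        self.seD = np.array([r.se_D for r in data])
        self.seD2 = self.seD**2
        self.logD = np.log(self.D)
        self.log1mD = np.log1p(-self.D)
        self.W = np.array([r.W for r in data])
        self.var_u = np.array([r.var_u for r in data])
        self.clamped = self.obs_like & (self.var_u == 0)
        if self.obs_like:
            self.s.X[self.clamped] = self.W[self.clamped]
        self.ones = np.ones(self.n)
        # adaptive Metropolis steps
        self.step_Y = np.full(self.n, 0.5)
        self.step_lam = 0.25
        self.acc_Y = np.zeros(self.n)
        self.acc_lam = 0.0
        self.n_lam_updates = 0
        self.n_Y_sweeps = 0
        self._refresh_cov_caches()

    # -- covariance caches -------------------------------------------------
    def _factor(self, C):
        cf = cho_factor(C, lower=True, check_finite=False)
        inv = cho_solve(cf, np.eye(self.n), check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return cf, inv, logdet

    def _refresh_cov_caches(self):
        C = self.covs.matrices[self.s.k]
        C_resid = lambda_transform(C, self.s.lam) if self.lam_on_resid else C
        C_pop = lambda_transform(C, self.s.lam)
        self.cfY, self.invY, self.logdetY = self._factor(C_resid)
        self.cfX, self.invX, self.logdetX = self._factor(C_pop)

    # -- conjugate draws ---------------------------------------------------
    def update_coeffs(self):
        pr = self.priors
        M = np.column_stack([self.ones, self.s.X])
        QM = self.invY @ M / self.s.sigma2_eps
        A = M.T @ QM + np.eye(2) / pr.coef_var
        b = QM.T @ self.s.Y + pr.coef_mean / pr.coef_var
        L = np.linalg.cholesky(A)
        mean = cho_solve((L, True), b)
        z = self.rng.standard_normal(2)
        theta = mean + np.linalg.solve(L.T, z)
        self.s.alpha, self.s.beta = float(theta[0]), float(theta[1])

    def update_sigma2_eps(self):
        pr = self.priors
        r = self.s.Y - self.s.alpha - self.s.beta * self.s.X
        quad = float(r @ self.invY @ r)
        tau = self.rng.gamma(pr.resid_prec_shape + 0.5 * self.n,
                             1.0 / (pr.resid_prec_rate + 0.5 * quad))
        self.s.sigma2_eps = 1.0 / tau

    def update_X(self):
        if self.obs_like and bool(np.all(self.clamped)):
            return
        s = self.s
        P = (s.beta**2 / s.sigma2_eps) * self.invY + self.invX / s.sigma2_x
        b = (s.beta / s.sigma2_eps) * (self.invY @ (s.Y - s.alpha)) \
            + (s.mu_x / s.sigma2_x) * (self.invX @ self.ones)
        if self.obs_like:
            free = ~self.clamped
            P = P + np.diag(np.where(free, 1.0 / np.where(free, self.var_u, 1.0), 0.0))
            b = b + np.where(free, self.W / np.where(free, self.var_u, 1.0), 0.0)
            if not np.all(free):
                idx = np.where(free)[0]
                fidx = np.where(~free)[0]
                b = b[idx] - P[np.ix_(idx, fidx)] @ s.X[fidx]
                P = P[np.ix_(idx, idx)]
                L = np.linalg.cholesky(P)
                mean = cho_solve((L, True), b)
                s.X[idx] = mean + np.linalg.solve(L.T, self.rng.standard_normal(idx.size))
                return
        L = np.linalg.cholesky(P)
        mean = cho_solve((L, True), b)
        s.X = mean + np.linalg.solve(L.T, self.rng.standard_normal(self.n))

    def update_mu_x(self):
        s, pr = self.s, self.priors
        w = self.invX @ self.ones
        prec = float(self.ones @ w) / s.sigma2_x
        mean = float(w @ s.X) / float(self.ones @ w)
        s.mu_x = _truncnorm_draw(self.rng, mean, math.sqrt(1.0 / prec),
                                 pr.x_mean_lower, pr.x_mean_upper)

    def update_sigma2_x(self):
        s, pr = self.s, self.priors
        r = s.X - s.mu_x
        quad = float(r @ self.invX @ r)
        tau = self.rng.gamma(pr.x_prec_shape + 0.5 * self.n,
                             1.0 / (pr.x_prec_rate + 0.5 * quad))
        s.sigma2_x = 1.0 / tau

    # -- Metropolis steps --------------------------------------------------
    def _beta_logterm(self, i: int, y: float) -> float:
        # scalar fast path of log_obs_rate(D, p, phi_from_se(p, se)); the
        # vectorised model functions are the tested reference implementation
        if not self.obs_like:
            return 0.0
        if y >= 0.0:
            p = 1.0 / (1.0 + math.exp(-y))
        else:
            e = math.exp(y)
            p = e / (1.0 + e)
        se2 = self.seD2[i]
        v = p * (1.0 - p)
        if not (0.0 < p < 1.0) or se2 >= v:
            return -math.inf
        phi = v / se2 - 1.0
        a = p * phi
        b = phi - a
        return (math.lgamma(phi) - math.lgamma(a) - math.lgamma(b)
                + (a - 1.0) * self.logD[i] + (b - 1.0) * self.log1mD[i])

    def update_Y(self, adapt_scale: float | None):
        s = self.s
        Q = self.invY / s.sigma2_eps
        mu = s.alpha + s.beta * s.X
        grad = Q @ (s.Y - mu)
        acc = np.zeros(self.n)
        for i in range(self.n):
            tau = Q[i, i]
            m = s.Y[i] - grad[i] / tau
            y0, y1 = s.Y[i], s.Y[i] + self.step_Y[i] * self.rng.standard_normal()
            logr = (self._beta_logterm(i, y1) - self._beta_logterm(i, y0)
                    - 0.5 * tau * ((y1 - m) ** 2 - (y0 - m) ** 2))
            if logr >= 0 or math.log(self.rng.uniform()) < logr:
                grad += Q[:, i] * (y1 - y0)
                s.Y[i] = y1
                acc[i] = 1.0
        self.acc_Y += acc
        self.n_Y_sweeps += 1
        if adapt_scale is not None:
            self.step_Y = np.minimum(
                np.exp(adapt_scale * (acc - 0.44)) * self.step_Y, 50.0
            )

    def _lambda_logtarget(self, lam: float):
        C = self.covs.matrices[self.s.k]
        C_pop = lambda_transform(C, lam)
        lp = mvn_logpdf(self.s.X, self.s.mu_x * self.ones, C_pop, self.s.sigma2_x)
        if self.lam_on_resid:
            C_resid = lambda_transform(C, lam)
            lp += mvn_logpdf(self.s.Y, self.s.alpha + self.s.beta * self.s.X,
                             C_resid, self.s.sigma2_eps)
        return lp

    def update_lambda(self, adapt_scale: float | None):
        s, pr = self.s, self.priors
        lam1 = _reflect01(s.lam + self.step_lam * self.rng.standard_normal())
        accepted = 0.0
        if pr.lambda_lower <= lam1 <= pr.lambda_upper:
            try:
                logr = self._lambda_logtarget(lam1) - self._lambda_logtarget(s.lam)
            except ValueError:  # proposed matrix numerically singular
                logr = -math.inf
            if logr >= 0 or math.log(self.rng.uniform()) < logr:
                s.lam = lam1
                accepted = 1.0
                self._refresh_cov_caches()
        self.acc_lam += accepted
        self.n_lam_updates += 1
        if adapt_scale is not None:
            # cap: with boundary reflection any step beyond the period is
            # equivalent, and an uncapped step diverges on a flat target
            self.step_lam = min(self.step_lam * math.exp(adapt_scale * (accepted - 0.44)), 2.0)

    def update_k(self):
        s = self.s
        logw = _tree_log_weights(s, self.covs, lambda_on_residual=self.lam_on_resid)
        k_new = _categorical_from_log(logw, self.rng)
        if k_new != s.k:
            s.k = k_new
            self._refresh_cov_caches()

    # -- one full sweep ----------------------------------------------------
    def sweep(self, t: int, adapting: bool):
        scale = min(0.25, 1.0 / math.sqrt(t + 1.0)) if adapting else None
        self.update_coeffs()
        self.update_sigma2_eps()
        self.update_X()
        self.update_Y(scale)
        if "mu_x" not in self.fixed:
            self.update_mu_x()
        if "sigma2_x" not in self.fixed:
            self.update_sigma2_x()
        if "lam" not in self.fixed:
            self.update_lambda(scale)
        if self.covs.K > 1:
            self.update_k()


def _tree_log_weights(state: ModelState, covs: CovarianceSet,
                      lambda_on_residual: bool = False) -> np.ndarray:
    """Unnormalised log full-conditional weights of the tree index."""
    n = covs.n
    ones = np.ones(n)
    logw = np.empty(covs.K)
    for k in range(covs.K):
        C = covs.matrices[k]
        C_resid = lambda_transform(C, state.lam) if lambda_on_residual else C
        C_pop = lambda_transform(C, state.lam)
        logw[k] = (
            mvn_logpdf(state.Y, state.alpha + state.beta * state.X, C_resid, state.sigma2_eps)
            + mvn_logpdf(state.X, state.mu_x * ones, C_pop, state.sigma2_x)
        )
    return logw


def _categorical_from_log(logw: np.ndarray, rng: np.random.Generator) -> int:
    if not np.any(np.isfinite(logw)):
        raise ValueError("all tree-index weights are -inf")
    w = np.exp(logw - np.max(logw))
    w /= w.sum()
    return int(rng.choice(w.size, p=w))


def sample_tree_index(state: ModelState, data, covs: CovarianceSet, priors: Priors,
                      rng: np.random.Generator | None = None,
                      lambda_on_residual: bool = False) -> int:
    """One exact draw from p(k | everything else); 0-based index."""
    if rng is None:
        rng = np.random.default_rng()
    return _categorical_from_log(
        _tree_log_weights(state, covs, lambda_on_residual), rng
    )


def fit(
    data: list[SpeciesRecord],
    covs: CovarianceSet,
    priors: Priors | None = None,
    config: McmcConfig | None = None,
    *,
    fixed: dict | None = None,
    lambda_on_residual: bool = False,
    observation_likelihood: bool = True,
) -> Chains:
    """Run the Metropolis-within-Gibbs sampler and return retained draws.

    ``fixed`` maps parameter names (``lam``, ``mu_x``, ``sigma2_x``) to
    values held constant throughout — their priors become point masses.
    """
    priors = priors or Priors()
    config = config or McmcConfig()
    fixed = dict(fixed or {})
    if observation_likelihood and len(data) < 3:
        raise ValueError("need at least 3 species")
    check_priors = _priors_for_check(priors, fixed)

    names = list(config.monitor)
    latent_names = ["Y", "X"] if config.monitor_latent else []
    draws = {name: np.empty((config.n_chains, config.n_keep)) for name in names}
    for name in latent_names:
        draws[name] = np.empty((config.n_chains, config.n_keep, covs.n))
    acc = {"Y": np.empty(config.n_chains), "lam": np.full(config.n_chains, np.nan)}

    for chain in range(config.n_chains):
        rng = _chain_rng(config.seed, chain)
        state = initialize(data, covs, priors, config.seed, chain, fixed, rng=rng)
        terms = log_joint_terms(state, data, covs, check_priors,
                                lambda_on_residual=lambda_on_residual,
                                observation_likelihood=observation_likelihood)
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite log joint at initialization; offending terms: {bad}")
        kern = _Kernel(data, covs, priors, fixed=fixed,
                       lambda_on_residual=lambda_on_residual,
                       observation_likelihood=observation_likelihood,
                       rng=rng, state=state)
        for t in range(config.n_adapt):
            kern.sweep(t, adapting=True)
        kern.acc_Y[:] = 0.0
        kern.acc_lam = 0.0
        kern.n_Y_sweeps = 0
        kern.n_lam_updates = 0
        for t in range(config.n_burn):
            kern.sweep(t, adapting=False)
        for it in range(config.n_keep):
            for _ in range(config.thin):
                kern.sweep(0, adapting=False)
            s = kern.s
            vals = {"alpha": s.alpha, "beta": s.beta,
                    "sigma_eps": math.sqrt(s.sigma2_eps), "lam": s.lam,
                    "mu_x": s.mu_x, "sigma_x": math.sqrt(s.sigma2_x),
                    "k": float(s.k + 1)}
            for name in names:
                draws[name][chain, it] = vals[name]
            if latent_names:
                draws["Y"][chain, it] = s.Y
                draws["X"][chain, it] = s.X
        acc["Y"][chain] = float(np.mean(kern.acc_Y / max(kern.n_Y_sweeps, 1)))
        if kern.n_lam_updates:
            acc["lam"][chain] = kern.acc_lam / kern.n_lam_updates

    return Chains(draws=draws, config=config, seed=config.seed,
                  species=list(covs.species_order), acceptance=acc)
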