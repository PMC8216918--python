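"""Convergence diagnostics, posterior summaries and goodness-of-fit exports.

All functions are pure functions of the draws.  Conventions match the
classic JAGS-era toolchain: Gelman-Rubin R-hat in its original (non-split,
non-rank-normalised) between/within form, effective sample size by
initial-positive-sequence autocorrelation truncation, equal-tailed quantile
credible intervals with type-7 (linear-interpolation) quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SpeciesRecord, logit

__all__ = [
    "ParamSummary",
    "gelman_rubin",
    "effective_n",
    "geweke",
    "summarize",
    "covers",
    "residuals_and_ppc",
]


@dataclass(frozen=True)
class ParamSummary:
    """Posterior summary of one monitored parameter."""

    name: str
    mean: float
    lower: float
    upper: float
    level: float
    rhat: float
    ess: float
    geweke_z: float

    def width(self) -> float:
        return self.upper - self.lower


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor (classic between/within form).

    ``chains`` is (m, n) with m >= 2 chains of equal length n; ``split=True``
    halves each chain first (useful with a single chain of length >= 20).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected a 2-D (n_chains, n_draws) array")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = chains.shape
    if m < 2:
        raise ValueError("R-hat needs >= 2 chains; use split=True for a single chain")
    if n < 10:
        raise ValueError("chains too short for R-hat (need length >= 10)")
    means = chains.mean(axis=1)
    W = float(np.mean(chains.var(axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))  # = B / n
    if W == 0.0:
        return 1.0
    var_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(var_hat / W))


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = x.size
    x = x - x.mean()
    # FFT autocovariance, biased (divide by n) as in standard ESS estimators
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[: max_lag + 1].real / n
    return acov


def effective_n(chain: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence.

    Sums adjacent autocorrelation pairs while the pair sums stay positive;
    ``ESS = n / (1 + 2 * sum(rho))``.  Chains shorter than 100 draws return
    their length with a warning; constant chains return their length.
    """
    x = np.asarray(chain, dtype=float).reshape(-1)
    n = x.size
    if n < 100:
        warnings.warn(f"chain of length {n} too short for a stable ESS; returning length")
        return float(n)
    if np.all(x == x[0]):
        return float(n)
    acov = _autocovariances(x, n - 1)
    rho = acov / acov[0]
    total = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        total += pair
        t += 2
    ess = n / (1.0 + 2.0 * total)
    return float(min(ess, n))


def _mean_variance(x: np.ndarray) -> float:
    """Autocorrelation-corrected variance of the sample mean (spectral
    variance at frequency zero divided by the segment length)."""
    n = x.size
    if n < 2 or np.all(x == x[0]):
        return 0.0
    ess = effective_n(x) if n >= 100 else float(n)
    return float(np.var(x, ddof=1) / ess)


def geweke(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z-score comparing the means of the first 10% and last 50%.

    Variances of the segment means use the autocorrelation-corrected
    (spectral) estimate.  A constant chain returns z = 0 by convention.
    """
    x = np.asarray(chain, dtype=float).reshape(-1)
    if np.all(x == x[0]):
        return 0.0
    a = x[: max(int(first * x.size), 2)]
    b = x[-max(int(last * x.size), 2):]
    va, vb = _mean_variance(a), _mean_variance(b)
    if va + vb == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def summarize(chains, level: float | None = None) -> list[ParamSummary]:
    """Posterior mean, equal-tailed credible interval and diagnostics for
    every monitored scalar parameter of a :class:`~phylosurv.mcmc.Chains`.

    Scale parameters are summarized on the scale they were monitored on
    (sigma_eps and sigma_x are standard deviations, lam is Pagel's lambda).
    """
    if level is None:
        level = chains.config.cri_level
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    out = []
    tail = (1.0 - level) / 2.0
    for name in chains.scalar_params():
        d = chains.draws[name]
        if d.size == 0:
            raise ValueError("empty chains")
        flat = d.reshape(-1)
        lo, hi = np.quantile(flat, [tail, 1.0 - tail])  # type-7 interpolation
        rhat = gelman_rubin(d) if d.shape[0] >= 2 else gelman_rubin(d, split=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(sum(effective_n(row) for row in d))
        out.append(ParamSummary(name=name, mean=float(flat.mean()),
                                lower=float(lo), upper=float(hi), level=level,
                                rhat=rhat, ess=min(ess, d.size),
                                geweke_z=geweke(flat)))
    return out


def summary_frame(summaries: list[ParamSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [s.name for s in summaries],
            "mean": [s.mean for s in summaries],
            "lower": [s.lower for s in summaries],
            "upper": [s.upper for s in summaries],
            "level": [s.level for s in summaries],
            "rhat": [s.rhat for s in summaries],
            "ess": [s.ess for s in summaries],
            "geweke_z": [s.geweke_z for s in summaries],
        }
    )


def covers(summary: ParamSummary, truth: float) -> bool:
    """Whether the credible interval contains the truth (closed endpoints)."""
    return bool(summary.lower <= truth <= summary.upper)


def residuals_and_ppc(
    chains, data: list[SpeciesRecord], n_lines: int = 100, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residuals on the logit scale and posterior regression lines.

    Residual for species i = observed logit rate minus the posterior-mean
    predicted logit rate (alpha + beta * X_i, with the posterior mean of the
    latent covariate when monitored, else the observed covariate).  The
    second frame is a thinned sample of (alpha, beta) draws for overplotting
    posterior predictive regression lines against the observations.
    """
    for needed in ("alpha", "beta"):
        if needed not in chains.draws:
            raise ValueError(f"monitor '{needed}' missing from chains; re-run with it monitored")
    a = chains.flat("alpha")
    b = chains.flat("beta")
    if "X" in chains.draws:
        x = chains.flat("X").mean(axis=0)
    else:
        x = np.array([r.W for r in data])
    pred = a.mean() + b.mean() * x
    obs = logit(np.array([r.D for r in data]))
    resid = pd.DataFrame(
        {
            "species": [r.species for r in data],
            "observed_logit": obs,
            "predicted_logit": pred,
            "residual": obs - pred,
        }
    )
    rng = np.random.default_rng(seed)
    idx = rng.choice(a.size, size=min(n_lines, a.size), replace=False)
    lines = pd.DataFrame({"draw": idx, "alpha": a[idx], "beta": b[idx]})
    return resid, lines
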