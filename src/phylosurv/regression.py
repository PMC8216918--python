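"""Model/Results front end, in the style of statsmodels.

:class:`PhyloSurvivalRegression` bundles the species data, the candidate
phylogenetic correlation matrices and the priors; ``fit()`` runs the MCMC
and returns a :class:`PhyloSurvivalResults` carrying the draws, posterior
summaries, convergence diagnostics and goodness-of-fit exports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .mcmc import Chains, McmcConfig, fit as _fit
from .model import Priors, SpeciesRecord
from .trees import CovarianceSet

__all__ = ["PhyloSurvivalRegression", "PhyloSurvivalResults"]


class PhyloSurvivalRegression:
    """Bayesian phylogenetically controlled regression of a survival rate
    on a species-level covariate, with measurement error on both.

    Parameters
    ----------
    data
        One :class:`~phylosurv.model.SpeciesRecord` per species.
    covariances
        Candidate phylogenetic correlation matrices; reordered to the data's
        species order (species missing from the phylogeny are an error).
    priors
        Prior hyperparameters; defaults are the weakly informative set.
    fixed
        Parameters held at known values (``lam``, ``mu_x``, ``sigma2_x``),
        e.g. ``{"lam": 1.0}`` to assume full Brownian covariance.
    lambda_on_residual
        If True, Pagel's lambda also discounts the residual covariance of
        the regression (sensitivity-analysis variant); by default it applies
        only to the covariate population distribution.
    """

    def __init__(
        self,
        data: list[SpeciesRecord],
        covariances: CovarianceSet,
        priors: Priors | None = None,
        *,
        fixed: dict | None = None,
        lambda_on_residual: bool = False,
    ):
        species = [r.species for r in data]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species in data")
        if covariances.species_order != species:
            covariances = covariances.reorder(species)
        self.data = list(data)
        self.covariances = covariances
        self.priors = priors or Priors()
        self.fixed = dict(fixed or {})
        self.lambda_on_residual = lambda_on_residual

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariances: CovarianceSet,
        priors: Priors | None = None,
        **kwargs,
    ) -> "PhyloSurvivalRegression":
        """Build from a trait table with columns ``species``, ``rate``,
        ``rate_se``, ``covariate``, ``covariate_se``."""
        from .io import records_from_frame

        return cls(records_from_frame(df), covariances, priors, **kwargs)

    def fit(self, config: McmcConfig | None = None, **overrides) -> "PhyloSurvivalResults":
        """Run the sampler; keyword overrides update the config fields."""
        config = config or McmcConfig()
        if overrides:
            from dataclasses import replace

            config = replace(config, **overrides)
        chains = _fit(
            self.data,
            self.covariances,
            self.priors,
            config,
            fixed=self.fixed,
            lambda_on_residual=self.lambda_on_residual,
        )
        return PhyloSurvivalResults(self, chains)


class PhyloSurvivalResults:
    """Posterior draws plus summaries for a fitted model."""

    def __init__(self, model: PhyloSurvivalRegression, chains: Chains):
        self.model = model
        self.chains = chains

    # -- point estimates ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means of the monitored scalar parameters."""
        return pd.Series(
            {name: float(self.chains.flat(name).mean())
             for name in self.chains.scalar_params()}
        )

    def summary(self, level: float | None = None) -> pd.DataFrame:
        """Posterior mean, credible interval, R-hat, ESS and Geweke z per
        parameter (equal-tailed interval at ``level``, default the config's)."""
        return diag.summary_frame(diag.summarize(self.chains, level))

    def param_summaries(self, level: float | None = None):
        return {s.name: s for s in diag.summarize(self.chains, level)}

    @property
    def rhat(self) -> pd.Series:
        return pd.Series({s.name: s.rhat for s in diag.summarize(self.chains)})

    @property
    def ess(self) -> pd.Series:
        return pd.Series({s.name: s.ess for s in diag.summarize(self.chains)})

    # -- goodness of fit ---------------------------------------------------
    def residuals(self) -> pd.DataFrame:
        resid, _ = diag.residuals_and_ppc(self.chains, self.model.data)
        return resid

    def ppc_lines(self, n_lines: int = 100, seed: int = 0) -> pd.DataFrame:
        _, lines = diag.residuals_and_ppc(self.chains, self.model.data,
                                          n_lines=n_lines, seed=seed)
        return lines

    def tree_posterior(self) -> pd.Series:
        """Posterior frequency of each candidate tree index (1-based)."""
        K = self.model.covariances.K
        k = self.chains.flat("k").astype(int)
        counts = np.bincount(k, minlength=K + 1)[1:]
        return pd.Series(counts / counts.sum(), index=np.arange(1, K + 1))

    def to_csv(self, chains_path, summary_path=None, manifest_path=None, level=None):
        self.chains.to_csv(chains_path, manifest_path=manifest_path)
        if summary_path is not None:
            self.summary(level).to_csv(summary_path, index=False)
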