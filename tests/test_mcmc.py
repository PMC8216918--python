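"""Sampler correctness: determinism, initialization, the tree-index Gibbs
step, conjugate-update targeting (GLS agreement) and a joint-distribution
(successive-conditional) check of the whole transition kernel."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phylosurv.mcmc import (
    Chains,
    McmcConfig,
    _Kernel,
    fit,
    initialize,
    sample_tree_index,
)
from phylosurv.model import ModelState, Priors, SpeciesRecord, inv_logit, logit
from phylosurv.simulate import GenParams, generate_dataset
from phylosurv.trees import CovarianceSet, random_tree, scale_vcv, tree_vcv

QUICK = McmcConfig(n_chains=2, n_adapt=200, n_burn=200, thin=1, n_keep=500, seed=11)


class TestDeterminism:
    def test_identical_seed_identical_chains(self, small_problem):
        ds, covs = small_problem
        fixed = {"mu_x": 0.0, "sigma2_x": 0.25, "lam": 1.0}
        c1 = fit(ds.records, covs, Priors(), QUICK, fixed=fixed)
        c2 = fit(ds.records, covs, Priors(), QUICK, fixed=fixed)
        for name in c1.draws:
            assert np.array_equal(c1.draws[name], c2.draws[name])

    def test_different_seed_differs(self, small_problem):
        ds, covs = small_problem
        fixed = {"mu_x": 0.0, "sigma2_x": 0.25, "lam": 1.0}
        from dataclasses import replace

        c1 = fit(ds.records, covs, Priors(), QUICK, fixed=fixed)
        c2 = fit(ds.records, covs, Priors(), replace(QUICK, seed=12), fixed=fixed)
        assert not np.array_equal(c1.draws["alpha"], c2.draws["alpha"])


class TestInitialize:
    def _data(self):
        recs = [
            SpeciesRecord("a", D=0.9, se_D=0.02, W=850.0, var_u=1.0),
            SpeciesRecord("b", D=0.8, se_D=0.02, W=850.0, var_u=1.0),
        ]
        covs = CovarianceSet([np.eye(2)], ["a", "b"])
        return recs, covs

    def test_logit_start_and_clipping(self):
        recs, covs = self._data()
        state = initialize(recs, covs, Priors(), seed=1)
        assert state.Y == pytest.approx([2.1972246, 1.3862944])
        assert state.mu_x == 700.0  # mean(W)=850 clipped into the prior support
        assert state.lam == 0.5 and state.sigma2_eps == 0.25

    def test_chain_jitters_distinct_but_deterministic(self):
        recs, covs = self._data()
        s0 = initialize(recs, covs, Priors(), seed=1, chain=0)
        s1 = initialize(recs, covs, Priors(), seed=1, chain=1)
        s0b = initialize(recs, covs, Priors(), seed=1, chain=0)
        assert (s0.alpha, s0.beta) != (s1.alpha, s1.beta)
        assert (s0.alpha, s0.beta) == (s0b.alpha, s0b.beta)


def _fixed_state(n, rng):
    return ModelState(
        Y=rng.normal(0.5, 0.3, n), X=rng.normal(0, 0.5, n), alpha=0.2,
        beta=-1.0, sigma2_eps=0.3, mu_x=0.0, sigma2_x=0.25, lam=1.0, k=0,
    )


class TestSampleTreeIndex:
    def test_single_matrix_always_selected(self, rng):
        C = np.eye(4)
        covs = CovarianceSet([C], list("abcd"))
        state = _fixed_state(4, rng)
        assert all(
            sample_tree_index(state, [], covs, Priors(), rng) == 0 for _ in range(20)
        )

    def test_identical_matrices_uniform(self, rng):
        C = scale_vcv(tree_vcv(random_tree(4, seed=8))[0])
        covs = CovarianceSet([C.copy() for _ in range(4)], [f"t{i+1}" for i in range(4)])
        state = _fixed_state(4, rng)
        draws = [sample_tree_index(state, [], covs, Priors(), rng) for _ in range(10_000)]
        freqs = np.bincount(draws, minlength=4) / 10_000
        se = math.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freqs - 0.25) < 3 * se + 1e-9)

    def test_two_matrix_softmax_oracle(self, rng):
        """K=2: frequency ratio matches exp(log-weight gap) computed with an
        independent MVN density."""
        C1 = np.eye(3)
        C2 = scale_vcv(tree_vcv(random_tree(3, seed=6))[0])
        covs = CovarianceSet([C1, C2], [f"t{i+1}" for i in range(3)])
        state = _fixed_state(3, rng)
        logw = []
        for C in (C1, C2):
            lw = multivariate_normal(state.alpha + state.beta * state.X,
                                     state.sigma2_eps * C).logpdf(state.Y)
            lw += multivariate_normal(np.zeros(3), state.sigma2_x * C).logpdf(state.X)
            logw.append(lw)
        p2 = 1.0 / (1.0 + math.exp(logw[0] - logw[1]))
        draws = np.array(
            [sample_tree_index(state, [], covs, Priors(), rng) for _ in range(10_000)]
        )
        p2_hat = draws.mean()
        se = math.sqrt(p2 * (1 - p2) / 10_000)
        assert abs(p2_hat - p2) < 4 * se


class TestGlsAgreement:
    def test_posterior_mean_matches_gls_without_measurement_error(self):
        """With the observation noise switched off (tiny SEs, no covariate
        error) the posterior of (alpha, beta) must centre on the
        generalized-least-squares solution on the same data."""
        gp = GenParams(n_species=20, me_fraction=0.0, se_lower=1e-4, se_upper=2e-4)
        tree = random_tree(20, seed=17)
        V, labels = tree_vcv(tree)
        C = scale_vcv(V)
        ds = generate_dataset(gp, C, seed=5, species=labels)
        covs = CovarianceSet([C], labels)
        chains = fit(ds.records, covs, Priors(), QUICK,
                     fixed={"mu_x": 0.0, "sigma2_x": 0.25, "lam": 1.0})
        Ylog = logit(np.array([r.D for r in ds.records]))
        M = np.column_stack([np.ones(20), [r.W for r in ds.records]])
        Ci = np.linalg.inv(C)
        gls = np.linalg.solve(M.T @ Ci @ M, M.T @ Ci @ Ylog)
        for j, name in enumerate(("alpha", "beta")):
            d = chains.flat(name)
            assert abs(d.mean() - gls[j]) < 3 * d.std()


class TestAcceptanceRates:
    def test_adapted_metropolis_acceptance_in_range(self, small_problem):
        ds, covs = small_problem
        chains = fit(ds.records, covs, Priors(), QUICK,
                     fixed={"mu_x": 0.0, "sigma2_x": 0.25, "lam": 1.0})
        assert np.all((chains.acceptance["Y"] > 0.2) & (chains.acceptance["Y"] < 0.6))

    def test_lambda_step_and_tree_mixing_run(self, small_problem):
        """Full model: lambda estimated, two candidate trees."""
        ds, covs = small_problem
        C2 = scale_vcv(tree_vcv(random_tree(6, seed=77))[0])
        covs2 = CovarianceSet([covs.matrices[0], C2], covs.species_order)
        chains = fit(ds.records, covs2, Priors(), QUICK,
                     fixed={"mu_x": 0.0, "sigma2_x": 0.25})
        lam = chains.flat("lam")
        assert 0.0 <= lam.min() and lam.max() <= 1.0
        assert lam.std() > 0.01  # the lambda chain actually moves
        ks = chains.flat("k")
        assert set(np.unique(ks)) <= {1.0, 2.0}
        assert len(np.unique(ks)) == 2  # both candidate trees visited


class TestJointDistribution:
    def test_successive_conditional_simulation_matches_forward(self):
        """Geweke-style joint-distribution check on a 5-species problem.

        Alternating one full Gibbs sweep with a redraw of the data given the
        current latent state must leave the prior marginals of alpha, beta
        and the residual precision invariant; their moments are compared to
        direct forward simulation within Monte-Carlo error.
        """
        n = 5
        rng = np.random.default_rng(2024)
        priors = Priors(coef_var=0.25, resid_prec_shape=3.0, resid_prec_rate=0.5)
        fixed = {"mu_x": 0.0, "sigma2_x": 0.25, "lam": 1.0}
        C = scale_vcv(tree_vcv(random_tree(n, seed=4))[0])
        labels = [f"t{i+1}" for i in range(n)]
        covs = CovarianceSet([C], labels)
        L = np.linalg.cholesky(C)
        se = np.full(n, 0.01)
        var_u = np.full(n, 0.02)

        def forward(rng):
            alpha, beta = rng.normal(0, 0.5, 2)
            tau = rng.gamma(3.0, 1 / 0.5)
            s2 = 1 / tau
            X = 0.5 * (L @ rng.standard_normal(n))
            Y = alpha + beta * X + math.sqrt(s2) * (L @ rng.standard_normal(n))
            return alpha, beta, tau, X, Y

        def draw_data(rng, X, Y):
            p = inv_logit(Y)
            phi = p * (1 - p) / se**2 - 1.0
            assert np.all(phi > 0)
            D = rng.beta(p * phi, (1 - p) * phi)
            W = X + np.sqrt(var_u) * rng.standard_normal(n)
            return D, W

        # forward reference sample
        fwd = np.array([forward(rng)[:3] for _ in range(40_000)])

        # successive-conditional chain
        alpha, beta, tau, X, Y = forward(rng)
        D, W = draw_data(rng, X, Y)
        recs = [SpeciesRecord(labels[i], D=float(D[i]), se_D=0.01,
                              W=float(W[i]), var_u=0.02) for i in range(n)]
        state = ModelState(Y=Y.copy(), X=X.copy(), alpha=alpha, beta=beta,
                           sigma2_eps=1 / tau, mu_x=0.0, sigma2_x=0.25, lam=1.0, k=0)
        kern = _Kernel(recs, covs, priors, fixed=fixed, lambda_on_residual=False,
                       observation_likelihood=True, rng=rng, state=state)
        M = 6000
        sc = np.empty((M, 3))
        for t in range(M):
            kern.sweep(t, adapting=(t < 500))
            D, W = draw_data(rng, kern.s.X, kern.s.Y)
            kern.D, kern.W = D, W
            kern.seD2 = se**2
            kern.logD, kern.log1mD = np.log(D), np.log1p(-D)
            sc[t] = (kern.s.alpha, kern.s.beta, 1.0 / kern.s.sigma2_eps)
        sc = sc[500:]

        from phylosurv.diagnostics import effective_n

        for j, name in enumerate(("alpha", "beta", "precision")):
            ess = effective_n(sc[:, j])
            mc_se = sc[:, j].std() / math.sqrt(ess)
            fwd_se = fwd[:, j].std() / math.sqrt(fwd.shape[0])
            tol = 3 * math.sqrt(mc_se**2 + fwd_se**2)
            assert abs(sc[:, j].mean() - fwd[:, j].mean()) < tol, name
            # variances agree within 3 relative MC errors
            v_sc, v_f = sc[:, j].var(), fwd[:, j].var()
            v_tol = 3 * v_f * math.sqrt(2 / ess + 2 / fwd.shape[0])
            assert abs(v_sc - v_f) < v_tol, name
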