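import dataclasses

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal

from conftest import hand_params, posterior_from_draws
from mlcmm import synthcohort
from mlcmm.dynamics import (_conditionals, forecast, membership_trace,
                            update_membership)
from mlcmm.likelihood import membership_prior
from mlcmm.basis import SplineConfig, spline_basis

SPEC = dataclasses.replace(synthcohort.SimConfig().model_spec(), L=2)
COV = {"male": 1.0, "black_race": 0.0, "diffuse": 1.0, "late_onset": 0.0}


def _hand_posterior(n_draws=3, duplicate_clusters=False, zero_alpha=False,
                    zero_G=False):
    thetas = []
    for s in range(n_draws):
        t = hand_params(seed=50 + s)
        if duplicate_clusters:
            t.beta_V[1] = t.beta_V[0]
            t.G[1] = t.G[0]
        if zero_alpha:
            t.alpha[:] = 0.0
        if zero_G:
            t.G[:] = 1e-12 * np.eye(2)
        thetas.append(t)
    return posterior_from_draws(SPEC, thetas)


def _fixed_mean(theta, ell, times, x):
    S = spline_basis(np.asarray(times, float), SplineConfig())
    V = np.column_stack([np.ones(len(times)), S])
    U = np.column_stack([np.tile(x, (len(times), 1)),
                         np.einsum("jd,p->jdp", S, x).reshape(len(times), -1)])
    return V @ theta.beta_V[ell] + U @ theta.beta_U


class TestUpdateMembership:
    def test_empty_history_is_posterior_averaged_prior_exactly(self):
        ps = _hand_posterior(zero_alpha=True)
        p = update_membership(ps, SPEC, [], np.zeros((0, 2)), COV)
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_empty_history_general_alpha(self):
        ps = _hand_posterior()
        p = update_membership(ps, SPEC, [], np.zeros((0, 2)), COV)
        w = np.array([COV[n] for n in SPEC.w_names])
        expected = np.mean([membership_prior(w, ps.draw(0, i).alpha)
                            for i in range(3)], axis=0)
        assert np.allclose(p, expected, atol=1e-12)

    def test_duplicated_cluster_parameters_leave_prior_unchanged(self):
        """If both clusters share identical parameters, biomarker data
        carry no membership information at any time."""
        ps = _hand_posterior(duplicate_clusters=True)
        w = np.array([COV[n] for n in SPEC.w_names])
        prior = np.mean([membership_prior(w, ps.draw(0, i).alpha)
                         for i in range(3)], axis=0)
        rng = np.random.default_rng(0)
        for J in (1, 2, 5):
            t = np.sort(rng.uniform(0, 10, J))
            y = rng.normal(size=(J, 2))
            p = update_membership(ps, SPEC, t, y, COV)
            assert np.allclose(p, prior, atol=1e-10)

    def test_matches_quadrature_bayes_oracle(self):
        """Per-draw Bayes arithmetic with Gauss-Hermite integration of
        the random intercept reproduces the sequential update."""
        ps = _hand_posterior(n_draws=3)
        times = np.array([1.0, 4.0])
        y = np.array([[0.2, -0.1], [-0.6, -0.4]])
        x = np.array([COV[n] for n in SPEC.x_names])
        w = np.array([COV[n] for n in SPEC.w_names])

        nodes, weights = hermegauss(60)   # weight e^{-z^2/2}
        z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
        zz = np.column_stack([z1.ravel(), z2.ravel()])
        ww = np.outer(weights, weights).ravel() / (2 * np.pi)

        per_draw = []
        for i in range(3):
            theta = ps.draw(0, i)
            unnorm = np.empty(2)
            for ell in range(2):
                b = zz @ np.linalg.cholesky(theta.G[ell]).T
                mean = _fixed_mean(theta, ell, times, x)
                dens = np.ones(len(b))
                for j in range(2):
                    dens *= multivariate_normal.pdf(y[j] - b, mean=mean[j],
                                                    cov=theta.R)
                integral = float(ww @ dens)
                unnorm[ell] = membership_prior(w, theta.alpha)[ell] * integral
            per_draw.append(unnorm / unnorm.sum())
        oracle = np.mean(per_draw, axis=0)
        p = update_membership(ps, SPEC, times, y, COV)
        assert np.allclose(p, oracle, atol=1e-6)

    def test_missing_covariate_is_an_error(self):
        ps = _hand_posterior()
        with pytest.raises(KeyError):
            update_membership(ps, SPEC, [], np.zeros((0, 2)), {"male": 1.0})


class TestMembershipTrace:
    def test_prefix_count_and_normalization(self):
        ps = _hand_posterior()
        rng = np.random.default_rng(1)
        t = np.array([0.5, 2.0, 3.5])
        y = rng.normal(size=(3, 2))
        tr = membership_trace(ps, SPEC, t, y, COV)
        assert len(tr.times) == 4
        assert tr.times[0] == 0.0
        assert np.allclose(tr.probs.sum(axis=1), 1.0, atol=1e-12)
        # baseline entry uses covariates only
        p0 = update_membership(ps, SPEC, [], np.zeros((0, 2)), COV)
        assert np.allclose(tr.probs[0], p0, atol=1e-14)


class TestForecast:
    def test_empty_history_unconditional_moments(self):
        """With no history the cluster-conditional predictive is the
        fixed-effect mean with covariance G + R at each timepoint."""
        ps = _hand_posterior(n_draws=1)
        theta = ps.draw(0, 0)
        horizon = np.array([2.0, 6.0])
        x = np.array([COV[n] for n in SPEC.x_names])
        mean, cov = _conditionals(ps, SPEC, np.zeros(0), np.zeros((0, 2)),
                                  x, horizon)
        expected_mean = _fixed_mean(theta, 0, horizon, x).reshape(-1)
        assert np.allclose(mean[0, 0], expected_mean, atol=1e-10)
        blk = cov[0, 0][:2, :2]
        assert np.allclose(blk, theta.G[0] + theta.R, atol=1e-10)

    def test_zero_G_history_is_uninformative(self):
        """Without random intercepts, past visits share nothing with
        the future, so the conditional mean is the fixed-effect mean."""
        ps = _hand_posterior(n_draws=1, zero_G=True)
        theta = ps.draw(0, 0)
        x = np.array([COV[n] for n in SPEC.x_names])
        times = np.array([1.0, 3.0])
        y = np.array([[5.0, 5.0], [-5.0, -5.0]])   # wild history
        mean, _ = _conditionals(ps, SPEC, times, y, x, np.array([7.0]))
        expected = _fixed_mean(theta, 1, np.array([7.0]), x).reshape(-1)
        assert np.allclose(mean[0, 1], expected, atol=1e-5)

    def test_conditional_matches_intercept_propagation_oracle(self):
        """Sampling the random intercept from its conditional given the
        history and propagating forward reproduces the conditional
        moments within Monte Carlo error."""
        ps = _hand_posterior(n_draws=1)
        theta = ps.draw(0, 0)
        ell = 0
        times = np.array([1.0, 4.0])
        y = np.array([[0.3, 0.1], [-0.5, -0.2]])
        x = np.array([COV[n] for n in SPEC.x_names])
        horizon = np.array([6.0, 9.0])
        mean, cov = _conditionals(ps, SPEC, times, y, x, horizon)

        # oracle: b | history is Gaussian with precision Ginv + J Rinv
        Ginv = np.linalg.inv(theta.G[ell])
        Rinv = np.linalg.inv(theta.R)
        hist_mean = _fixed_mean(theta, ell, times, x)
        post_prec = Ginv + len(times) * Rinv
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ Rinv @ (y - hist_mean).sum(axis=0)
        rng = np.random.default_rng(12)
        M = 400_000
        b = rng.multivariate_normal(post_mean, post_cov, size=M)
        eps = rng.multivariate_normal(np.zeros(2), theta.R, size=(M, 2))
        fut_mean = _fixed_mean(theta, ell, horizon, x)
        sims = (fut_mean[None] + b[:, None, :] + eps).reshape(M, 4)
        se = sims.std(0) / np.sqrt(M)
        assert (np.abs(sims.mean(0) - mean[0, ell]) < 3 * se + 1e-9).all()
        assert np.allclose(np.cov(sims.T), cov[0, ell], atol=0.01)

    def test_high_confidence_calls_are_calibrated(self):
        """Across replicate cohorts at the default (moderate)
        separation, subjects assigned final probability >= 0.9 for the
        declining cluster really belong to it at least 85% of the
        time."""
        from mlcmm.pipeline import fit_model

        n_hi = n_hi_true = 0
        for rep in range(4):
            cfg = dataclasses.replace(synthcohort.SimConfig(),
                                      n_subjects=100)
            cohort, truth = synthcohort.generate(cfg, seed=7100 + rep)
            fr = fit_model(cohort, SPEC, n_chains=2, n_burn=300, n_post=300,
                           seed=rep, quantile_normalize=False)
            p = fr.posterior.pooled_member_prob()
            hi = p[:, 0] >= 0.9
            n_hi += int(hi.sum())
            n_hi_true += int((truth.cluster[hi] == 0).sum())
        assert n_hi > 0
        assert n_hi_true / n_hi >= 0.85

    def test_weak_separation_does_not_manufacture_certainty(self):
        """On the weakly-separated fixture the updater should leave
        most subjects uncertain rather than inventing confident
        labels."""
        from mlcmm.pipeline import fit_model

        cohort, _ = synthcohort.make_fixture("overlapping", n_subjects=100)
        fr = fit_model(cohort, SPEC, n_chains=2, n_burn=300, n_post=300,
                       seed=0, quantile_normalize=False)
        p = fr.posterior.pooled_member_prob()
        assert (p.max(axis=1) >= 0.9).mean() < 0.25

    def test_forecast_draw_count_and_summaries(self):
        ps = _hand_posterior(n_draws=3)
        fc = forecast(ps, SPEC, [1.0], [[0.1, 0.0]], COV, cluster=0,
                      horizon_times=[3.0, 5.0], seed=4)
        assert fc.draws.shape == (3, 2, 2)
        s = fc.summaries()
        assert (s["lower95"] <= s["mean"]).all()
        assert (s["mean"] <= s["upper95"]).all()
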