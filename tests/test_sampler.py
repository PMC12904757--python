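import dataclasses

import numpy as np
import pytest

from conftest import hand_params, posterior_from_draws
from mlcmm import synthcohort
from mlcmm.likelihood import build_design, cluster_marginal_loglik, \
    mixture_loglik
from mlcmm.sampler import (PosteriorSet, _FitData, _marginal_loglik_matrix,
                           _sample_beta, multivariate_psrf, ordering_stat,
                           posterior_mean_params, psrf, relabel, run_mcmc)


def _tiny_setup():
    cohort, truth = synthcohort.make_fixture("tiny")
    spec = dataclasses.replace(synthcohort.SimConfig().model_spec(), L=2)
    designs = build_design(cohort, spec)
    return spec, designs, truth


class TestMarginalLikelihoodFastPath:
    def test_woodbury_matches_dense_route(self):
        """The sampler's batched Woodbury likelihood equals the dense
        per-subject marginal Gaussian for every subject and cluster."""
        spec, designs, _ = _tiny_setup()
        theta = hand_params()
        fd = _FitData(designs, spec)
        fast = _marginal_loglik_matrix(fd, theta.beta_U, theta.beta_V,
                                       theta.G, theta.R)
        for i, d in enumerate(designs):
            for ell in range(2):
                assert fast[i, ell] == pytest.approx(
                    cluster_marginal_loglik(d, theta, ell), rel=1e-10)


class TestBetaBlockConjugacy:
    def test_collapsed_beta_draws_match_dense_gls_posterior(self):
        """With labels, G and R held fixed, the collapsed coefficient
        update must target the closed-form Gaussian posterior (checked
        against a dense Kronecker construction)."""
        spec, designs, truth = _tiny_setup()
        fd = _FitData(designs, spec)
        theta = truth.params
        C = truth.cluster
        K, qV, qU, L = spec.K, spec.q_V, spec.q_U, spec.L
        q = L * qV + qU

        # dense oracle: accumulate D' Sigma^-1 D and D' Sigma^-1 y
        prec = np.eye(q * K) / spec.priors.beta_sd ** 2
        lin = np.zeros(q * K)
        for i, d in enumerate(designs):
            B = np.zeros((d.J, q))
            B[:, C[i] * qV:(C[i] + 1) * qV] = d.V
            B[:, L * qV:] = d.U
            D = np.kron(B, np.eye(K))
            sigma = (np.kron(np.ones((d.J, d.J)), theta.G[C[i]])
                     + np.kron(np.eye(d.J), theta.R))
            Sinv = np.linalg.inv(sigma)
            prec += D.T @ Sinv @ D
            lin += D.T @ Sinv @ d.y.reshape(-1)
        dense_mean = np.linalg.solve(prec, lin)
        dense_sd = np.sqrt(np.diag(np.linalg.inv(prec)))

        rng = np.random.default_rng(7)
        S = 1500
        draws = np.empty((S, q * K))
        for s in range(S):
            beta_V, beta_U = _sample_beta(fd, C, theta.G, theta.R, spec, rng)
            Theta = np.concatenate([beta_V.reshape(L * qV, K), beta_U])
            draws[s] = Theta.reshape(-1)
        err = np.abs(draws.mean(0) - dense_mean)
        assert (err < 4 * dense_sd / np.sqrt(S) + 1e-8).all()
        assert np.allclose(draws.std(0), dense_sd, rtol=0.15)


class TestRunMcmc:
    def test_seeded_determinism(self):
        spec, designs, _ = _tiny_setup()
        a = run_mcmc(designs, spec, n_chains=2, n_burn=20, n_post=20, seed=5)
        b = run_mcmc(designs, spec, n_chains=2, n_burn=20, n_post=20, seed=5)
        assert np.array_equal(a.beta_V, b.beta_V)
        assert np.array_equal(a.G, b.G)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.member_prob, b.member_prob)

    def test_different_seeds_differ(self):
        spec, designs, _ = _tiny_setup()
        a = run_mcmc(designs, spec, n_chains=1, n_burn=10, n_post=10, seed=5)
        b = run_mcmc(designs, spec, n_chains=1, n_burn=10, n_post=10, seed=6)
        assert not np.array_equal(a.beta_V, b.beta_V)

    def test_zero_posterior_draws_is_metadata_only(self):
        spec, designs, _ = _tiny_setup()
        ps = run_mcmc(designs, spec, n_chains=1, n_burn=5, n_post=0, seed=1)
        assert ps.n_post == 0
        assert ps.beta_V.shape[1] == 0
        assert ps.seed == 1

    def test_cluster_recovery_on_separated_data(self, separated_fit):
        fr, truth = separated_fit
        p = fr.posterior.pooled_member_prob()
        assert ((p.argmax(1) == truth.cluster).mean()) >= 0.95

    def test_posterior_centers_near_generating_trends(self, separated_fit):
        fr, truth = separated_fit
        pm = posterior_mean_params(fr.posterior)
        stat_fit = ordering_stat(pm.beta_V, fr.spec)
        stat_true = ordering_stat(truth.params.beta_V, fr.spec)
        assert np.allclose(stat_fit, stat_true, atol=0.35)


class TestRelabel:
    def _posterior_from_draws(self, spec, thetas):
        return posterior_from_draws(spec, thetas)

    def test_ordered_draw_unchanged(self):
        spec, designs, _ = _tiny_setup()
        theta = hand_params()
        # force cluster 0 to be the faster-declining one
        stat = ordering_stat(theta.beta_V, spec)
        if stat[0] > stat[1]:
            theta.beta_V = theta.beta_V[::-1].copy()
        ps = self._posterior_from_draws(spec, [theta])
        out = relabel(ps, spec)
        assert np.array_equal(out.beta_V, ps.beta_V)
        assert np.array_equal(out.alpha, ps.alpha)

    def test_swapped_draw_restored_and_likelihood_invariant(self):
        spec, designs, _ = _tiny_setup()
        theta = hand_params()
        swapped = theta.copy()
        swapped.beta_V = theta.beta_V[::-1].copy()
        swapped.G = theta.G[::-1].copy()
        swapped.alpha = -theta.alpha
        ps = self._posterior_from_draws(spec, [swapped])
        out = relabel(ps, spec)
        stat = ordering_stat(out.beta_V[0, 0], spec)
        assert (np.diff(stat) >= 0).all()
        assert mixture_loglik(designs, out.draw(0, 0)) == pytest.approx(
            mixture_loglik(designs, swapped), rel=1e-10)

    def test_random_orderings_all_sorted_after_relabel(self):
        spec, _, _ = _tiny_setup()
        rng = np.random.default_rng(3)
        thetas = []
        for _ in range(50):
            t = hand_params(seed=int(rng.integers(1e6)))
            t.beta_V = t.beta_V[rng.permutation(2)].copy()
            thetas.append(t)
        out = relabel(self._posterior_from_draws(spec, thetas), spec)
        for i in range(50):
            stat = ordering_stat(out.beta_V[0, i], spec)
            assert (np.diff(stat) >= 0).all()


class TestPsrf:
    def test_identical_chains_exact_value(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        chains = np.vstack([x, x])
        assert psrf(chains) == pytest.approx(np.sqrt(199 / 200), abs=1e-14)

    def test_drifted_chains_match_hand_arithmetic(self):
        rng = np.random.default_rng(1)
        n = 1000
        c1 = rng.normal(0, 1, n)
        c2 = rng.normal(10, 1, n)
        chains = np.vstack([c1, c2])
        W = (c1.var(ddof=1) + c2.var(ddof=1)) / 2
        B_over_n = np.var([c1.mean(), c2.mean()], ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert psrf(chains) == pytest.approx(expected, abs=1e-10)
        assert psrf(chains) > 1.2

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 20000))
        assert 1.0 <= psrf(chains) * 1.0000001  # numerical floor
        assert psrf(chains) < 1.01

    def test_degenerate_chain_is_an_error(self):
        with pytest.raises(ValueError):
            psrf(np.ones((2, 50)))


class TestMultivariatePsrf:
    def test_one_dimension_reduces_to_scalar(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 500))
        assert multivariate_psrf(chains[:, :, None]) == pytest.approx(
            psrf(chains), rel=1e-12)

    def test_identical_chains_below_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 3))
        assert multivariate_psrf(np.stack([x, x])) < 1.0

    def test_drifted_coordinate_dominates_stable_one(self):
        rng = np.random.default_rng(5)
        n = 2000
        stable = rng.normal(size=(2, n))
        drifted = np.stack([rng.normal(0, 1, n), rng.normal(3, 1, n)])
        chains = np.stack([np.column_stack([stable[c], drifted[c]])
                           for c in range(2)])
        assert multivariate_psrf(chains) > psrf(stable)

    def test_bounds_scalar_psrf_of_projections(self):
        rng = np.random.default_rng(6)
        chains = rng.normal(size=(3, 400, 4))
        chains[1] += 0.3  # mild shift on every coordinate
        mpsrf = multivariate_psrf(chains)
        for _ in range(20):
            a = rng.normal(size=4)
            proj = chains @ a
            assert psrf(proj) <= mpsrf + 1e-8


class TestSerialization:
    def test_posterior_round_trip(self, tmp_path):
        spec, designs, _ = _tiny_setup()
        ps = run_mcmc(designs, spec, n_chains=2, n_burn=10, n_post=15, seed=2)
        ps = relabel(ps, spec)
        ps.save(tmp_path / "post.csv")
        loaded = PosteriorSet.load(tmp_path / "post.csv")
        assert np.allclose(loaded.beta_V, ps.beta_V)
        assert np.allclose(loaded.G, ps.G)
        assert np.allclose(loaded.alpha, ps.alpha)
        assert np.allclose(loaded.loglik, ps.loglik)
        assert loaded.relabeled
        assert loaded.subject_ids == tuple(map(str, ps.subject_ids))
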