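"""Shared fixtures.

The expensive MCMC fit on strongly-separated synthetic data is
session-scoped and reused by the convergence, certainty-growth and
reporting tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlcmm import synthcohort
from mlcmm.pipeline import fit_model

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """6 subjects x 3 visits, with generating truth."""
    return synthcohort.make_fixture("tiny")


@pytest.fixture(scope="session")
def separated_fit():
    """A converged fit on strongly-separated data (120 subjects,
    2 chains x 500 burn-in / 500 draws), with the generating truth."""
    cohort, truth = synthcohort.make_fixture("separated", n_subjects=120)
    spec = dataclasses.replace(
        synthcohort.SimConfig().model_spec(), L=2)
    fr = fit_model(cohort, spec, n_chains=2, n_burn=500, n_post=500,
                   seed=11, quantile_normalize=False)
    return fr, truth


def posterior_from_draws(spec, thetas):
    """Assemble a one-chain PosteriorSet from explicit ParamDraws."""
    from mlcmm.sampler import PosteriorSet

    n = len(thetas)
    return PosteriorSet(
        spec=spec,
        beta_U=np.stack([t.beta_U for t in thetas])[None],
        beta_V=np.stack([t.beta_V for t in thetas])[None],
        alpha=np.stack([t.alpha for t in thetas])[None],
        G=np.stack([t.G for t in thetas])[None],
        R=np.stack([t.R for t in thetas])[None],
        member_prob=np.full((1, n, 1, spec.L), 1 / spec.L, np.float32),
        loglik=np.zeros((1, n)), n_burn=0, seed=0, relabeled=True)


def hand_params(L=2, K=2, df=2, p=4, seed=5):
    """A fixed, reproducible ParamDraw for oracle tests."""
    from mlcmm.likelihood import ParamDraw

    rng = np.random.default_rng(seed)
    beta_V = rng.normal(0, 0.5, (L, 1 + df, K))
    beta_U = rng.normal(0, 0.3, (p * (1 + df), K))
    alpha = rng.normal(0, 0.5, (L - 1, 1 + p))
    G = np.empty((L, K, K))
    for ell in range(L):
        g = np.array([[0.5, 0.25], [0.25, 0.4]])[:K, :K]
        G[ell] = g + 0.1 * ell * np.eye(K)
    R = np.array([[0.15, 0.06], [0.06, 0.15]])[:K, :K]
    return ParamDraw(beta_U=beta_U, beta_V=beta_V, alpha=alpha, G=G, R=R)
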