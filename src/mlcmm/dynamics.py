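"""Sequential membership updating and trajectory forecasting.

The latent cluster ``C_i`` is a fixed trait, but belief about it
evolves: after each visit the posterior probability ``p_it`` that the
subject belongs to each cluster is recomputed from the data observed so
far.  For every stored posterior draw ``theta`` the exact
(random-intercept-marginalized) likelihood of the observed prefix is
combined with the covariate-driven membership prior by Bayes' rule, and
``p_it`` is the average of those per-draw probabilities over the
posterior (a Rao-Blackwellized estimate — no cluster labels are
resampled).  With no biomarker history this reduces exactly to the
posterior-averaged prior.

Forecasts are cluster-conditional posterior predictives: under a draw
``theta`` and cluster ``l``, history and future values are jointly
Gaussian, so the future values are sampled from their conditional given
the history — one sample per posterior draw.  Horizon times a little
beyond the spline boundary use the basis's natural linear continuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .likelihood import LOG_2PI, ModelSpec
from .likelihood import _design_rows
from .preprocess import QuantileMap, inverse_transform
from .sampler import PosteriorSet

__all__ = ["MembershipTrace", "Forecast", "update_membership",
           "membership_trace", "forecast", "mixture_predictive_draws"]


@dataclass(frozen=True)
class MembershipTrace:
    """Per-prefix posterior membership probabilities for one subject."""

    subject_id: object
    times: np.ndarray   # (T,), starting with 0.0 (baseline, prior-only)
    probs: np.ndarray   # (T, L), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times})
        for ell in range(self.probs.shape[1]):
            df[f"prob_cluster_{ell + 1}"] = self.probs[:, ell]
        return df


@dataclass(frozen=True)
class Forecast:
    """Cluster-conditional posterior-predictive forecast."""

    subject_id: object
    cluster: int                 # 0-based
    horizon_times: np.ndarray    # (H,)
    draws: np.ndarray            # (n_draws, H, K), normalized scale
    k_names: tuple[str, ...]

    def summaries(self, maps: dict[str, QuantileMap] | None = None
                  ) -> pd.DataFrame:
        """Posterior-predictive mean and central 95% band per horizon
        time and biomarker; original-scale columns are added when
        quantile maps are supplied (each sample back-transformed, then
        summarized)."""
        rows = []
        for h, t in enumerate(self.horizon_times):
            for k, name in enumerate(self.k_names):
                z = self.draws[:, h, k]
                rec = {"time": float(t), "biomarker": name,
                       "mean": float(z.mean()),
                       "lower95": float(np.quantile(z, 0.025)),
                       "upper95": float(np.quantile(z, 0.975))}
                if maps is not None:
                    y = inverse_transform(maps[name], z)
                    rec.update(mean_orig=float(np.mean(y)),
                               lower95_orig=float(np.quantile(y, 0.025)),
                               upper95_orig=float(np.quantile(y, 0.975)))
                rows.append(rec)
        return pd.DataFrame(rows)


def _covariate_vectors(covariates, spec: ModelSpec
                       ) -> tuple[np.ndarray, np.ndarray]:
    def pick(names):
        try:
            return np.array([float(covariates[n]) for n in names])
        except KeyError as e:
            raise KeyError(f"subject covariates lack {e.args[0]!r} "
                           f"required by the model spec") from e
    return pick(spec.x_names), pick(spec.w_names)


def _stacked_params(ps: PosteriorSet):
    """Pool chains: beta_U (D,qU,K), beta_V (D,L,qV,K), alpha, G, R."""
    D = ps.n_draws
    flat = lambda a: a.reshape(D, *a.shape[2:])
    return (flat(ps.beta_U), flat(ps.beta_V), flat(ps.alpha),
            flat(ps.G), flat(ps.R))


def _prior_logp(alpha: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(D, L) log prior membership probabilities per draw."""
    D, Lm1, _ = alpha.shape
    wd = np.concatenate([[1.0], w])
    logits = np.zeros((D, Lm1 + 1))
    if Lm1:
        logits[:, :-1] = alpha @ wd
    return logits - logsumexp(logits, axis=1, keepdims=True)


def _fixed_means(V, U, beta_U, beta_V):
    """(D, L, J, K) fixed-effect means at the given design rows."""
    m = np.einsum("jq,dlqk->dljk", V, beta_V)
    if U.shape[1]:
        m = m + np.einsum("jq,dqk->djk", U, beta_U)[:, None]
    return m


def _joint_cov(G, R, J):
    """(D, L, JK, JK) marginal covariance: block (a,b) = G + [a==b] R."""
    D, L, K, _ = G.shape
    ones = np.ones((J, J))
    eye = np.eye(J)
    sig = (np.einsum("ab,dlij->dlaibj", ones, G)
           + np.einsum("ab,dlij->dlaibj", eye,
                       np.broadcast_to(R[:, None] if R.ndim == 3 else R,
                                       (D, L, K, K))))
    return sig.reshape(D, L, J * K, J * K)


def _history_loglik(times, y, x, spec: ModelSpec, beta_U, beta_V, G, R
                    ) -> np.ndarray:
    """(D, L) marginalized log likelihood of the observed prefix.

    Uses the Woodbury identity on the random-intercept structure so
    all per-draw algebra is K x K regardless of the prefix length.
    """
    J, K = y.shape
    D, L = G.shape[:2]
    V, U = _design_rows(np.asarray(times, float), x, spec.spline)
    means = _fixed_means(V, U, beta_U, beta_V)          # (D,L,J,K)
    resid = y[None, None] - means
    Rfull = np.broadcast_to(R[:, None] if R.ndim == 3 else R, (D, L, K, K))
    Rinv = np.linalg.inv(Rfull)
    Ginv = np.linalg.inv(G)
    W = Rinv @ np.linalg.inv(Ginv + J * Rinv) @ Rinv
    q1 = np.einsum("dljk,dlkm,dljm->dl", resid, Rinv, resid)
    u = resid.sum(axis=2)                               # (D,L,K)
    q2 = np.einsum("dlk,dlkm,dlm->dl", u, W, u)
    _, logdetR = np.linalg.slogdet(Rfull)
    _, logdet_corr = np.linalg.slogdet(np.eye(K) + J * (Rinv @ G))
    return -0.5 * (J * K * LOG_2PI + J * logdetR + logdet_corr + q1 - q2)


def _per_draw_probs(ps, spec, times, y, x, w) -> np.ndarray:
    """(D, L) per-draw posterior membership probabilities."""
    beta_U, beta_V, alpha, G, R = _stacked_params(ps)
    logp = _prior_logp(alpha, w)
    y = np.asarray(y, float).reshape(len(times), spec.K)
    if len(times):
        logp = logp + _history_loglik(times, y, x, spec, beta_U, beta_V, G, R)
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def update_membership(ps: PosteriorSet, spec: ModelSpec, times, y,
                      covariates) -> np.ndarray:
    """Posterior membership probabilities given visits through ``times``.

    ``times``/``y`` may be empty (baseline: prior-only, exact);
    ``covariates`` maps covariate names to values and must cover both
    the trajectory and membership covariate sets of ``spec``.
    Returns a length-L probability vector.
    """
    x, w = _covariate_vectors(covariates, spec)
    return _per_draw_probs(ps, spec, np.asarray(times, float), y, x, w
                           ).mean(axis=0)


def membership_trace(ps: PosteriorSet, spec: ModelSpec, times, y, covariates,
                     subject_id="subject") -> MembershipTrace:
    """Membership probabilities after every visit prefix (t=0 first)."""
    times = np.asarray(times, float)
    y = np.asarray(y, float).reshape(len(times), spec.K)
    probs = [update_membership(ps, spec, times[:j], y[:j], covariates)
             for j in range(len(times) + 1)]
    return MembershipTrace(subject_id=subject_id,
                           times=np.concatenate([[0.0], times]),
                           probs=np.asarray(probs))


def _conditionals(ps, spec, times, y, x, horizon_times):
    """Per-draw, per-cluster conditional mean (D,L,HK) and covariance
    (D,L,HK,HK) of the horizon values given the history."""
    beta_U, beta_V, alpha, G, R = _stacked_params(ps)
    J = len(times)
    H = len(horizon_times)
    K = spec.K
    all_t = np.concatenate([np.asarray(times, float),
                            np.asarray(horizon_times, float)])
    V, U = _design_rows(all_t, x, spec.spline)
    means = _fixed_means(V, U, beta_U, beta_V)            # (D,L,J+H,K)
    sig = _joint_cov(G, R, J + H)
    o = slice(0, J * K)
    h = slice(J * K, (J + H) * K)
    mean_h = means[:, :, J:].reshape(*means.shape[:2], H * K)
    if J == 0:
        return mean_h, sig[:, :, h, h]
    mean_o = means[:, :, :J].reshape(*means.shape[:2], J * K)
    resid = np.asarray(y, float).reshape(1, 1, J * K) - mean_o
    gain = np.linalg.solve(sig[:, :, o, o],
                           sig[:, :, o, h])               # (D,L,JK,HK)
    cond_mean = mean_h + np.einsum("dloh,dlo->dlh", gain, resid)
    cond_cov = sig[:, :, h, h] - np.einsum("dloh,dlog->dlhg",
                                           gain, sig[:, :, o, h])
    return cond_mean, cond_cov


def forecast(ps: PosteriorSet, spec: ModelSpec, times, y, covariates,
             cluster: int, horizon_times, seed: int = 0,
             subject_id="subject") -> Forecast:
    """Cluster-conditional posterior-predictive samples at the horizon.

    One sample per posterior draw (the predictive is represented by
    ``n_draws`` samples).  ``cluster`` is 0-based.
    """
    x, _w = _covariate_vectors(covariates, spec)
    times = np.asarray(times, float)
    y = np.asarray(y, float).reshape(len(times), spec.K)
    horizon_times = np.atleast_1d(np.asarray(horizon_times, float))
    cond_mean, cond_cov = _conditionals(ps, spec, times, y, x, horizon_times)
    mu = cond_mean[:, cluster]
    cov = cond_cov[:, cluster]
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(mu.shape)
    draws = mu + np.einsum("dab,db->da", chol, z)
    H = len(horizon_times)
    return Forecast(subject_id=subject_id, cluster=cluster,
                    horizon_times=horizon_times,
                    draws=draws.reshape(-1, H, spec.K),
                    k_names=spec.k_names)


def mixture_predictive_draws(ps: PosteriorSet, spec: ModelSpec, times, y,
                             covariates, horizon_times, seed: int = 0
                             ) -> np.ndarray:
    """Posterior-predictive samples with cluster membership integrated
    out: per draw, a cluster is sampled from that draw's membership
    posterior and the horizon values from its conditional.  Shape
    (n_draws, H, K)."""
    x, w = _covariate_vectors(covariates, spec)
    times = np.asarray(times, float)
    y = np.asarray(y, float).reshape(len(times), spec.K)
    horizon_times = np.atleast_1d(np.asarray(horizon_times, float))
    probs = _per_draw_probs(ps, spec, times, y, x, w)     # (D, L)
    cond_mean, cond_cov = _conditionals(ps, spec, times, y, x, horizon_times)
    rng = np.random.default_rng(seed)
    D, L = probs.shape
    g = rng.gumbel(size=(D, L))
    pick = np.argmax(np.log(np.maximum(probs, 1e-300)) + g, axis=1)
    idx = np.arange(D)
    mu = cond_mean[idx, pick]
    chol = np.linalg.cholesky(cond_cov[idx, pick])
    z = rng.standard_normal(mu.shape)
    draws = mu + np.einsum("dab,db->da", chol, z)
    return draws.reshape(D, len(horizon_times), spec.K)
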