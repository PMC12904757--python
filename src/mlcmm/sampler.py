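"""MCMC posterior estimation for the multivariate latent class model.

The sampler is Metropolis-within-Gibbs, exploiting the conditional
conjugacy of every linear-Gaussian block:

1. cluster labels ``C_i`` from their categorical full conditional,
   using the *marginalized* subject likelihood (random intercepts
   integrated out analytically), which mixes much better than
   conditioning on ``b_i``;
2. random intercepts ``b_i`` from their Gaussian full conditional;
3. all trajectory coefficients (shared and cluster-specific) jointly
   from a Gaussian full conditional;
4. ``G(l)`` and ``R`` from inverse-Wishart full conditionals;
5. membership coefficients ``alpha`` by random-walk Metropolis with a
   step size adapted during burn-in only.

Likelihood evaluations are batched across subjects with equal visit
counts, so one covariance factorization per (visit-count, cluster)
pair serves every subject in the group.

Label switching is resolved after sampling by :func:`relabel`, which
orders clusters by the fitted 10-year change of the first biomarker's
cluster trend (most negative — fastest progressing — first) and
re-expresses the membership coefficients against the new reference
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp
from scipy.stats import invwishart
from sklearn.cluster import KMeans

from .basis import spline_basis
from .likelihood import (LOG_2PI, ModelSpec, ParamDraw, SubjectDesign,
                         mixture_loglik)

__all__ = ["PosteriorSet", "run_mcmc", "relabel", "psrf", "multivariate_psrf",
           "posterior_mean_params"]


# --------------------------------------------------------------------------
# posterior container

@dataclass
class PosteriorSet:
    """Ordered posterior draws across chains.

    Array shapes lead with ``(n_chains, n_post, ...)``.  ``member_prob``
    holds the per-draw Rao-Blackwellized membership probabilities of
    the training subjects (float32, not serialized to CSV), and
    ``loglik`` the observed-data mixture log likelihood per draw.
    """

    spec: ModelSpec
    beta_U: np.ndarray       # (m, n, q_U, K)
    beta_V: np.ndarray       # (m, n, L, q_V, K)
    alpha: np.ndarray        # (m, n, L-1, 1+p_w)
    G: np.ndarray            # (m, n, L, K, K)
    R: np.ndarray            # (m, n, K, K) or (m, n, L, K, K)
    member_prob: np.ndarray  # (m, n, n_subjects, L) float32
    loglik: np.ndarray       # (m, n)
    n_burn: int
    seed: int
    relabeled: bool = False
    subject_ids: tuple = ()
    accept_alpha: float = float("nan")

    @property
    def n_chains(self) -> int:
        return self.beta_V.shape[0]

    @property
    def n_post(self) -> int:
        return self.beta_V.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_post

    def draw(self, chain: int, i: int) -> ParamDraw:
        return ParamDraw(beta_U=self.beta_U[chain, i],
                         beta_V=self.beta_V[chain, i],
                         alpha=self.alpha[chain, i],
                         G=self.G[chain, i], R=self.R[chain, i])

    def iter_draws(self):
        for c in range(self.n_chains):
            for i in range(self.n_post):
                yield self.draw(c, i)

    def pooled_member_prob(self) -> np.ndarray:
        """Posterior-mean membership probability per training subject."""
        return np.asarray(self.member_prob, float).mean(axis=(0, 1))

    # ---- flat-table serialization -------------------------------------

    def _scalar_columns(self) -> dict[str, np.ndarray]:
        m, n = self.n_chains, self.n_post
        cols: dict[str, np.ndarray] = {}

        def put(name, arr):
            cols[name] = arr.reshape(m * n)

        qU, K = self.beta_U.shape[2:]
        for j in range(qU):
            for k in range(K):
                put(f"beta_U[{j},{k}]", self.beta_U[:, :, j, k])
        L, qV = self.beta_V.shape[2:4]
        for ell in range(L):
            for j in range(qV):
                for k in range(K):
                    put(f"beta_V[{ell},{j},{k}]", self.beta_V[:, :, ell, j, k])
        for ell in range(self.alpha.shape[2]):
            for j in range(self.alpha.shape[3]):
                put(f"alpha[{ell},{j}]", self.alpha[:, :, ell, j])
        for ell in range(L):
            for i in range(K):
                for j in range(i, K):
                    put(f"G[{ell},{i},{j}]", self.G[:, :, ell, i, j])
        if self.R.ndim == 4:
            for i in range(K):
                for j in range(i, K):
                    put(f"R[{i},{j}]", self.R[:, :, i, j])
        else:
            for ell in range(L):
                for i in range(K):
                    for j in range(i, K):
                        put(f"R[{ell},{i},{j}]", self.R[:, :, ell, i, j])
        put("loglik", self.loglik)
        return cols

    def to_dataframe(self) -> pd.DataFrame:
        m, n = self.n_chains, self.n_post
        out = {"chain": np.repeat(np.arange(m), n),
               "iter": np.tile(np.arange(n), m)}
        out.update(self._scalar_columns())
        return pd.DataFrame(out)

    def save(self, csv_path, meta_path=None) -> None:
        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path, index=False)
        meta = {"spec": self.spec.to_dict(), "n_burn": self.n_burn,
                "n_post": self.n_post, "n_chains": self.n_chains,
                "seed": self.seed, "relabeled": self.relabeled,
                "subject_ids": list(map(str, self.subject_ids))}
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yaml")
        meta_path.write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, csv_path, meta_path=None) -> "PosteriorSet":
        csv_path = Path(csv_path)
        meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yaml")
        meta = yaml.safe_load(meta_path.read_text())
        spec = ModelSpec.from_dict(meta["spec"])
        df = pd.read_csv(csv_path)
        m, n = int(meta["n_chains"]), int(meta["n_post"])
        K, L, qV, qU = spec.K, spec.L, spec.q_V, spec.q_U
        p1 = 1 + len(spec.w_names)

        def get(name):
            return df[name].to_numpy(float).reshape(m, n)

        beta_U = np.empty((m, n, qU, K))
        for j in range(qU):
            for k in range(K):
                beta_U[:, :, j, k] = get(f"beta_U[{j},{k}]")
        beta_V = np.empty((m, n, L, qV, K))
        for ell in range(L):
            for j in range(qV):
                for k in range(K):
                    beta_V[:, :, ell, j, k] = get(f"beta_V[{ell},{j},{k}]")
        alpha = np.empty((m, n, L - 1, p1))
        for ell in range(L - 1):
            for j in range(p1):
                alpha[:, :, ell, j] = get(f"alpha[{ell},{j}]")
        G = np.empty((m, n, L, K, K))
        for ell in range(L):
            for i in range(K):
                for j in range(i, K):
                    G[:, :, ell, i, j] = G[:, :, ell, j, i] = get(f"G[{ell},{i},{j}]")
        if spec.shared_R:
            R = np.empty((m, n, K, K))
            for i in range(K):
                for j in range(i, K):
                    R[:, :, i, j] = R[:, :, j, i] = get(f"R[{i},{j}]")
        else:
            R = np.empty((m, n, L, K, K))
            for ell in range(L):
                for i in range(K):
                    for j in range(i, K):
                        R[:, :, ell, i, j] = R[:, :, ell, j, i] = \
                            get(f"R[{ell},{i},{j}]")
        n_subj = len(meta["subject_ids"])
        return cls(spec=spec, beta_U=beta_U, beta_V=beta_V, alpha=alpha,
                   G=G, R=R,
                   member_prob=np.full((m, n, n_subj, L), np.nan, np.float32),
                   loglik=get("loglik"), n_burn=int(meta["n_burn"]),
                   seed=int(meta["seed"]), relabeled=bool(meta["relabeled"]),
                   subject_ids=tuple(meta["subject_ids"]))


# --------------------------------------------------------------------------
# pre-computed fit data

class _FitData:
    """Designs flattened to global arrays, grouped by visit count."""

    def __init__(self, designs: list[SubjectDesign], spec: ModelSpec):
        self.spec = spec
        self.n = len(designs)
        self.J = np.array([d.J for d in designs])
        self.starts = np.concatenate([[0], np.cumsum(self.J)[:-1]])
        self.N = int(self.J.sum())
        self.V = np.concatenate([d.V for d in designs])            # (N, q_V)
        self.U = np.concatenate([d.U for d in designs])            # (N, q_U)
        self.y = np.concatenate([d.y for d in designs])            # (N, K)
        self.W = np.stack([d.w for d in designs]) if spec.w_names \
            else np.zeros((self.n, 0))
        self.Wd = np.column_stack([np.ones(self.n), self.W])
        self.subj_of_row = np.repeat(np.arange(self.n), self.J)
        self.subject_ids = tuple(d.subject_id for d in designs)
        self.uniq_J, self.J_index = np.unique(self.J, return_inverse=True)


def _woodbury_terms(G_ell: np.ndarray, R_ell: np.ndarray, uniq_J: np.ndarray):
    """Per unique visit count J, the correction matrix
    ``W_J = Rinv (Ginv + J Rinv)^{-1} Rinv`` and the log-determinant
    ``J log|R| + log|I + J Rinv G|`` of the marginal covariance
    ``1 1' (x) G + I (x) R``."""
    K = G_ell.shape[0]
    Rinv = np.linalg.inv(R_ell)
    Ginv = np.linalg.inv(G_ell)
    _, logdetR = np.linalg.slogdet(R_ell)
    Js = uniq_J[:, None, None]
    M = np.linalg.inv(Ginv[None] + Js * Rinv[None])
    W = Rinv[None] @ M @ Rinv[None]
    _, logdet_corr = np.linalg.slogdet(np.eye(K)[None]
                                       + Js * (Rinv @ G_ell)[None])
    logdet = uniq_J * logdetR + logdet_corr
    return Rinv, W, logdet


def _marginal_loglik_matrix(fd: _FitData, beta_U, beta_V, G, R) -> np.ndarray:
    """(n, L) matrix of marginalized cluster-conditional log
    likelihoods, via the Woodbury identity (all algebra is K x K)."""
    L = beta_V.shape[0]
    K = fd.y.shape[1]
    shared = fd.U @ beta_U if fd.U.shape[1] else 0.0
    ll = np.empty((fd.n, L))
    for ell in range(L):
        R_ell = R if R.ndim == 2 else R[ell]
        Rinv, W, logdet = _woodbury_terms(G[ell], R_ell, fd.uniq_J)
        resid = fd.y - (fd.V @ beta_V[ell] + shared)
        q1 = np.add.reduceat(np.einsum("nk,kl,nl->n", resid, Rinv, resid),
                             fd.starts)
        u = np.add.reduceat(resid, fd.starts, axis=0)          # (n, K)
        q2 = np.einsum("nk,nkl,nl->n", u, W[fd.J_index], u)
        ll[:, ell] = -0.5 * (fd.J * K * LOG_2PI + logdet[fd.J_index]
                             + q1 - q2)
    return ll


def _membership_logp(fd: _FitData, alpha: np.ndarray) -> np.ndarray:
    """(n, L) log prior membership probabilities (reference last)."""
    L = alpha.shape[0] + 1
    logits = np.zeros((fd.n, L))
    if L > 1:
        logits[:, :-1] = fd.Wd @ alpha.T
    return logits - logsumexp(logits, axis=1, keepdims=True)


# --------------------------------------------------------------------------
# initialization

def _init_state(fd: _FitData, spec: ModelSpec, rng: np.random.Generator,
                kmeans_seed: int):
    n, K, L = fd.n, spec.K, spec.L
    # per-subject OLS intercept/slope summaries per biomarker
    feats = np.empty((n, 2 * K))
    for i in range(n):
        sl = slice(fd.starts[i], fd.starts[i] + fd.J[i])
        t = fd.V[sl, 1] if fd.V.shape[1] > 1 else np.zeros(fd.J[i])
        X = np.column_stack([np.ones(fd.J[i]), t])
        coef, *_ = np.linalg.lstsq(X, fd.y[sl], rcond=None)
        feats[i] = coef.T.reshape(-1)
    # winsorize: per-subject OLS slopes are heavy-tailed when visit
    # times cluster, and outliers would dominate the standardization
    if n >= 20:
        lo, hi = np.quantile(feats, [0.05, 0.95], axis=0)
        feats = np.clip(feats, lo, hi)
    feats = (feats - feats.mean(0)) / np.maximum(feats.std(0), 1e-12)
    if L > 1:
        km = KMeans(n_clusters=L, n_init=10, random_state=kmeans_seed)
        C = km.fit_predict(feats)
    else:
        C = np.zeros(n, dtype=int)

    qV, qU = spec.q_V, spec.q_U
    beta_V = np.zeros((L, qV, K))
    beta_U = np.zeros((qU, K))
    AU = np.column_stack([fd.V, fd.U]) if qU else fd.V
    for ell in range(L):
        mask = C[fd.subj_of_row] == ell
        if mask.sum() >= AU.shape[1]:
            coef, *_ = np.linalg.lstsq(AU[mask], fd.y[mask], rcond=None)
            beta_V[ell] = coef[:qV]
            if qU:
                beta_U += coef[qV:] / L
    # chain-specific jitter to overdisperse initial points
    beta_V += 0.1 * rng.standard_normal(beta_V.shape)
    beta_U += 0.1 * rng.standard_normal(beta_U.shape)
    G = np.tile(0.3 * np.eye(K), (L, 1, 1))
    R = 0.3 * np.eye(K) if spec.shared_R else np.tile(0.3 * np.eye(K), (L, 1, 1))
    alpha = np.zeros((L - 1, 1 + len(spec.w_names)))
    b = np.zeros((n, K))
    return C, b, beta_V, beta_U, alpha, G, R


# --------------------------------------------------------------------------
# Gibbs blocks

def _sample_C(fd, ll, logp, rng):
    post = logp + ll
    post = post - logsumexp(post, axis=1, keepdims=True)
    g = rng.gumbel(size=post.shape)
    return np.argmax(post + g, axis=1), np.exp(post)


def _sample_b(fd, C, mean_assigned, G, R, spec, rng):
    K = spec.K
    e = fd.y - mean_assigned
    sums = np.add.reduceat(e, fd.starts, axis=0)       # (n, K)
    b = np.empty((fd.n, K))
    Ginv = np.linalg.inv(G)
    for ell in range(spec.L):
        R_ell = R if R.ndim == 2 else R[ell]
        Rinv = np.linalg.inv(R_ell)
        for jidx, Jv in enumerate(fd.uniq_J):
            mask = np.flatnonzero((C == ell) & (fd.J_index == jidx))
            if mask.size == 0:
                continue
            cov = np.linalg.inv(Ginv[ell] + Jv * Rinv)
            half = np.linalg.cholesky(cov)
            mean = sums[mask] @ (cov @ Rinv).T
            b[mask] = mean + rng.standard_normal((mask.size, K)) @ half.T
    return b


def _sample_beta(fd, C, G, R, spec, rng):
    """Joint Gaussian draw of all trajectory coefficients with the
    random intercepts integrated out (partially collapsed update —
    avoids the slow ridge between cluster intercepts and G).

    With design rows ``B`` mapping the coefficient matrix ``Theta``
    (q x K, C-order vec) to fixed-effect means, a subject contributes

        kron(B'B, Rinv) - kron(s s', W_J)

    to the posterior precision, where ``s`` is the column sum of the
    subject's rows and ``W_J`` the Woodbury correction for its visit
    count; the linear term follows the same structure.
    """
    L, K, qV, qU = spec.L, spec.K, spec.q_V, spec.q_U
    q = L * qV + qU
    A = np.zeros((fd.N, q))
    C_rows = C[fd.subj_of_row]
    for ell in range(L):
        mask = C_rows == ell
        A[mask, ell * qV:(ell + 1) * qV] = fd.V[mask]
    if qU:
        A[:, L * qV:] = fd.U
    s = np.add.reduceat(A, fd.starts, axis=0)          # (n, q)
    t_sum = np.add.reduceat(fd.y, fd.starts, axis=0)   # (n, K)

    prec = np.eye(q * K) / spec.priors.beta_sd ** 2
    lin = np.zeros(q * K)
    for ell in range(L):
        R_ell = R if R.ndim == 2 else R[ell]
        Rinv, W, _logdet = _woodbury_terms(G[ell], R_ell, fd.uniq_J)
        rows = C_rows == ell
        prec += np.kron(A[rows].T @ A[rows], Rinv)
        lin += (A[rows].T @ fd.y[rows] @ Rinv).reshape(-1)
        for jidx in range(len(fd.uniq_J)):
            mask = np.flatnonzero((C == ell) & (fd.J_index == jidx))
            if mask.size == 0:
                continue
            Wj = W[jidx]
            prec -= np.kron(s[mask].T @ s[mask], Wj)
            lin -= (s[mask].T @ (t_sum[mask] @ Wj)).reshape(-1)
    c = cho_factor(prec, lower=True)
    mean = cho_solve(c, lin)
    z = rng.standard_normal(q * K)
    theta = mean + solve_triangular(c[0].T, z, lower=False)
    Theta = theta.reshape(q, K)
    beta_V = np.stack([Theta[ell * qV:(ell + 1) * qV] for ell in range(L)])
    beta_U = Theta[L * qV:].copy() if qU else np.zeros((0, K))
    return beta_V, beta_U


def _sample_G(C, b, spec, rng):
    K = spec.K
    pri = spec.priors
    G = np.empty((spec.L, K, K))
    for ell in range(spec.L):
        bs = b[C == ell]
        scale = pri.wishart_scale * np.eye(K) + bs.T @ bs
        G[ell] = invwishart.rvs(df=K + pri.wishart_dof_extra + len(bs),
                                scale=scale, random_state=rng)
    return G


def _sample_R(fd, C, E, spec, rng):
    K = spec.K
    pri = spec.priors
    if spec.shared_R:
        scale = pri.wishart_scale * np.eye(K) + E.T @ E
        return invwishart.rvs(df=K + pri.wishart_dof_extra + len(E),
                              scale=scale, random_state=rng)
    R = np.empty((spec.L, K, K))
    C_rows = C[fd.subj_of_row]
    for ell in range(spec.L):
        Ee = E[C_rows == ell]
        scale = pri.wishart_scale * np.eye(K) + Ee.T @ Ee
        R[ell] = invwishart.rvs(df=K + pri.wishart_dof_extra + len(Ee),
                                scale=scale, random_state=rng)
    return R


def _alpha_logpost(fd, alpha, C, alpha_sd):
    logp = _membership_logp(fd, alpha)
    return (float(logp[np.arange(fd.n), C].sum())
            - 0.5 * float((alpha ** 2).sum()) / alpha_sd ** 2)


def _sample_alpha(fd, alpha, C, spec, rng, step, it, adapting, n_steps=10):
    """Random-walk Metropolis on the membership coefficients.

    Several cheap sub-steps per Gibbs scan (the target is a small
    logistic-regression posterior) keep this block's autocorrelation
    comparable to the conjugate blocks'; the step size adapts toward a
    0.3 acceptance rate during burn-in only.
    """
    if spec.L == 1:
        return alpha, step, 1.0
    cur = _alpha_logpost(fd, alpha, C, spec.priors.alpha_sd)
    acc_sum = 0.0
    for sub in range(n_steps):
        prop = alpha + step * rng.standard_normal(alpha.shape)
        new = _alpha_logpost(fd, prop, C, spec.priors.alpha_sd)
        acc_prob = min(1.0, float(np.exp(min(new - cur, 0.0))))
        acc_sum += acc_prob
        if np.log(rng.random()) < new - cur:
            alpha, cur = prop, new
        if adapting:
            step *= np.exp((acc_prob - 0.3) / (1 + it * n_steps + sub) ** 0.6)
    return alpha, step, acc_sum / n_steps


# --------------------------------------------------------------------------
# main loop

def run_mcmc(designs: list[SubjectDesign], spec: ModelSpec,
             n_chains: int = 4, n_burn: int = 2000, n_post: int = 3000,
             seed: int = 0, progress: bool = False) -> PosteriorSet:
    """Draw from the posterior; bitwise reproducible given ``seed``.

    Defaults: 2000 burn-in iterations before 3000 kept draws per chain.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    fd = _FitData(designs, spec)
    K, L = spec.K, spec.L
    m = n_chains
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(m)
    kmeans_seed = int(ss.generate_state(1)[0] % (2 ** 31))

    out = PosteriorSet(
        spec=spec,
        beta_U=np.empty((m, n_post, spec.q_U, K)),
        beta_V=np.empty((m, n_post, L, spec.q_V, K)),
        alpha=np.empty((m, n_post, L - 1, 1 + len(spec.w_names))),
        G=np.empty((m, n_post, L, K, K)),
        R=(np.empty((m, n_post, K, K)) if spec.shared_R
           else np.empty((m, n_post, L, K, K))),
        member_prob=np.empty((m, n_post, fd.n, L), dtype=np.float32),
        loglik=np.empty((m, n_post)),
        n_burn=n_burn, seed=seed, subject_ids=fd.subject_ids,
    )

    acc_total, acc_n = 0.0, 0
    for chain in range(m):
        rng = np.random.default_rng(chain_seeds[chain])
        C, b, beta_V, beta_U, alpha, G, R = _init_state(fd, spec, rng,
                                                        kmeans_seed)
        step = 0.2
        ll = _marginal_loglik_matrix(fd, beta_U, beta_V, G, R)
        logp = _membership_logp(fd, alpha)
        for it in range(n_burn + n_post):
            C, _ = _sample_C(fd, ll, logp, rng)
            beta_V, beta_U = _sample_beta(fd, C, G, R, spec, rng)
            shared = fd.U @ beta_U if spec.q_U else 0.0
            mean_assigned = (np.einsum("nq,nqk->nk", fd.V,
                                       beta_V[C[fd.subj_of_row]]) + shared)
            b = _sample_b(fd, C, mean_assigned, G, R, spec, rng)
            G = _sample_G(C, b, spec, rng)
            E = fd.y - mean_assigned - b[fd.subj_of_row]
            R = _sample_R(fd, C, E, spec, rng)
            alpha, step, acc = _sample_alpha(fd, alpha, C, spec, rng, step,
                                             it, adapting=it < n_burn)
            # likelihoods at the updated state feed both this draw's
            # stored membership probabilities and the next C update
            ll = _marginal_loglik_matrix(fd, beta_U, beta_V, G, R)
            logp = _membership_logp(fd, alpha)
            if it >= n_burn:
                i = it - n_burn
                post = logp + ll
                lse = logsumexp(post, axis=1)
                out.beta_U[chain, i] = beta_U
                out.beta_V[chain, i] = beta_V
                out.alpha[chain, i] = alpha
                out.G[chain, i] = G
                out.R[chain, i] = R
                out.member_prob[chain, i] = np.exp(post - lse[:, None])
                out.loglik[chain, i] = float(lse.sum())
                acc_total += acc
                acc_n += 1
            if progress and (it + 1) % 500 == 0:
                print(f"chain {chain}: iteration {it + 1}/{n_burn + n_post}")
    out.accept_alpha = acc_total / max(acc_n, 1)
    return out


# --------------------------------------------------------------------------
# relabeling

def ordering_stat(beta_V: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Fitted change of biomarker 1's cluster trend over the spline
    window, per cluster; relabeling sorts this most-negative (fastest
    progressing) first."""
    s_end = spline_basis(spec.spline.boundary[1], spec.spline)
    # beta_V: (L, 1+df, K); rows 1..df of biomarker 0 are the trend coefs
    return beta_V[:, 1:, 0] @ s_end


def _permute_alpha(alpha: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Re-express reference-coded membership coefficients under a
    cluster permutation (new label l takes old label perm[l])."""
    L = alpha.shape[0] + 1
    full = np.vstack([alpha, np.zeros((1, alpha.shape[1]))])
    new_full = full[perm] - full[perm[L - 1]]
    return new_full[:L - 1]


def relabel(ps: PosteriorSet, spec: ModelSpec | None = None) -> PosteriorSet:
    """Sort cluster labels within every draw by the ordering statistic.

    Returns a new PosteriorSet; the mixture likelihood of every draw is
    unchanged (label permutation is an exact symmetry of the model).
    """
    spec = spec or ps.spec
    out = PosteriorSet(spec=ps.spec, beta_U=ps.beta_U.copy(),
                       beta_V=ps.beta_V.copy(), alpha=ps.alpha.copy(),
                       G=ps.G.copy(), R=ps.R.copy(),
                       member_prob=ps.member_prob.copy(),
                       loglik=ps.loglik.copy(), n_burn=ps.n_burn,
                       seed=ps.seed, relabeled=True,
                       subject_ids=ps.subject_ids,
                       accept_alpha=ps.accept_alpha)
    for c in range(ps.n_chains):
        for i in range(ps.n_post):
            stat = ordering_stat(ps.beta_V[c, i], spec)
            perm = np.argsort(stat, kind="stable")
            if np.array_equal(perm, np.arange(len(stat))):
                continue
            out.beta_V[c, i] = ps.beta_V[c, i][perm]
            out.G[c, i] = ps.G[c, i][perm]
            if ps.R.ndim == 5:
                out.R[c, i] = ps.R[c, i][perm]
            out.alpha[c, i] = _permute_alpha(ps.alpha[c, i], perm)
            out.member_prob[c, i] = ps.member_prob[c, i][:, perm]
    return out


def posterior_mean_params(ps: PosteriorSet) -> ParamDraw:
    """Pooled posterior-mean parameter point (relabel first when L > 1)."""
    return ParamDraw(beta_U=ps.beta_U.mean(axis=(0, 1)),
                     beta_V=ps.beta_V.mean(axis=(0, 1)),
                     alpha=ps.alpha.mean(axis=(0, 1)),
                     G=ps.G.mean(axis=(0, 1)), R=ps.R.mean(axis=(0, 1)))


# --------------------------------------------------------------------------
# convergence diagnostics

def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for a scalar trace.

    ``chains`` is (m, n).  ``Rhat = sqrt(((n-1)/n W + B/n) / W)`` with
    ``W`` the mean within-chain variance and ``B/n`` the variance of
    the chain means.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    if W <= 0:
        raise ValueError("degenerate chain: zero within-chain variance")
    B_over_n = chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def multivariate_psrf(chains: np.ndarray) -> float:
    """Brooks-Gelman multivariate PSRF for vector traces (m, n, d).

    ``sqrt((n-1)/n + lambda_max(W^{-1} B/n))``; without the finite-chain
    ``(m+1)/m`` correction so the one-dimensional case reduces exactly
    to :func:`psrf`.  It bounds the scalar PSRF of every linear
    projection of the trace from above.
    """
    chains = np.asarray(chains, float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    if chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n, d = chains.shape
    W = np.zeros((d, d))
    for c in range(m):
        W += np.cov(chains[c].T, ddof=1).reshape(d, d)
    W /= m
    means = chains.mean(axis=1)
    B_over_n = np.cov(means.T, ddof=1).reshape(d, d)
    try:
        cw = cho_factor(W, lower=True)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular pooled within-chain covariance") from e
    lam = np.linalg.eigvals(cho_solve(cw, B_over_n))
    lam_max = float(np.max(lam.real))
    return float(np.sqrt((n - 1) / n + lam_max))
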