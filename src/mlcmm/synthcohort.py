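"""Seeded synthetic cohorts with the model's full generative structure.

The generator emulates the structure of a single-center scleroderma
registry restricted to a high-ILD-risk serologic subset: roughly 289
subjects, 3-28 visits each (median about 7) in the first 10 years after
disease onset, two latent clusters — one with both lung-function
biomarkers declining over the decade ("fast progressor"), one flat
("stable") — correlated random intercepts across biomarkers, and
correlated within-visit residuals.  Baseline covariates are four
independent Bernoulli indicators with registry-like prevalences (male
0.163, Black race 0.225, diffuse subtype 0.571, late onset 0.5), and
cluster membership follows a logistic model in those covariates tuned
to a roughly even split.

Biomarker values are generated directly on the model's standardized
(quantile-normalized) scale; true cluster labels, random intercepts and
the generating parameters are returned so that estimation and
calibration can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import SplineConfig, spline_basis
from .likelihood import ModelSpec, ParamDraw, membership_prior
from .longdata import SUBJECT_COL, TIME_COL, LongCohort, make_cohort

__all__ = ["SimConfig", "SimTruth", "generate", "make_fixture", "FIXTURES"]

K_NAMES = ("pfvc", "pdlco")
COV_NAMES = ("male", "black_race", "diffuse", "late_onset")
COV_PREVALENCE = (0.163, 0.225, 0.571, 0.5)

# membership logit coefficients (fast-progressor cluster vs reference):
# direction mirrors known risk factors (male protective, Black race,
# diffuse subtype and late onset adverse); intercept centers the
# marginal split near 50/50 at the default prevalences
ALPHA_DEFAULT = np.array([[-1.33, -0.4, 1.2, 1.1, 1.0]])


def _slope_coefs(total_change: float, spline: SplineConfig) -> np.ndarray:
    """Minimum-norm spline coefficients whose fitted curve changes by
    ``total_change`` between onset and the right boundary knot."""
    s_end = spline_basis(spline.boundary[1], spline)
    return total_change * s_end / float(s_end @ s_end)


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration; defaults emulate the registry subset."""

    n_subjects: int = 289
    L: int = 2
    # fitted 10-year change of each cluster's trend, per biomarker:
    # row l, column k. Cluster 1 declines ~1.2 standardized units in
    # both biomarkers, cluster 2 is flat.
    ten_year_change: tuple[tuple[float, ...], ...] = ((-1.2, -1.2), (0.0, 0.0))
    onset_level: tuple[tuple[float, ...], ...] = ((0.3, 0.3), (0.3, 0.3))
    alpha: np.ndarray = field(default_factory=lambda: ALPHA_DEFAULT.copy())
    cov_names: tuple[str, ...] = COV_NAMES
    cov_prevalence: tuple[float, ...] = COV_PREVALENCE
    g_var: float = 0.5
    g_corr: float = 0.5
    r_var: float = 0.15
    r_corr: float = 0.4
    # visits = 3 + NegBin(shape, mean), capped at max_visits: median ~7
    # with an occasional heavily-followed subject in the high 20s
    visit_mean_extra: float = 4.5
    visit_shape: float = 2.0
    max_visits: int = 28
    window_years: float = 10.0
    first_visit_by: float = 5.0
    spline: SplineConfig = field(default_factory=SplineConfig)

    @property
    def K(self) -> int:
        return len(self.ten_year_change[0])

    def model_spec(self) -> ModelSpec:
        return ModelSpec(k_names=K_NAMES[:self.K], L=self.L,
                         x_names=self.cov_names, w_names=self.cov_names,
                         spline=self.spline)

    def true_params(self) -> ParamDraw:
        K, L, df = self.K, self.L, self.spline.df
        beta_V = np.zeros((L, 1 + df, K))
        for ell in range(L):
            for k in range(K):
                beta_V[ell, 0, k] = self.onset_level[ell][k]
                beta_V[ell, 1:, k] = _slope_coefs(self.ten_year_change[ell][k],
                                                  self.spline)
        beta_U = np.zeros((len(self.cov_names) * (1 + df), K))
        G_one = np.full((K, K), self.g_var * self.g_corr)
        np.fill_diagonal(G_one, self.g_var)
        R = np.full((K, K), self.r_var * self.r_corr)
        np.fill_diagonal(R, self.r_var)
        alpha = np.asarray(self.alpha, float)
        if self.L == 1:
            alpha = np.zeros((0, 1 + len(self.cov_names)))
        return ParamDraw(beta_U=beta_U, beta_V=beta_V, alpha=alpha,
                         G=np.broadcast_to(G_one, (L, K, K)).copy(), R=R)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a generated cohort."""

    cluster: np.ndarray        # (n,) 0-based labels
    b: np.ndarray              # (n, K) random intercepts
    params: ParamDraw

    def to_frame(self, subject_ids) -> pd.DataFrame:
        df = pd.DataFrame({SUBJECT_COL: subject_ids,
                           "true_cluster": self.cluster + 1})
        for k in range(self.b.shape[1]):
            df[f"b_{k + 1}"] = self.b[:, k]
        return df


def _visit_times(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    if cfg.visit_mean_extra <= 0:
        extra = 0
    else:
        p = cfg.visit_shape / (cfg.visit_shape + cfg.visit_mean_extra)
        extra = int(rng.negative_binomial(cfg.visit_shape, p))
    n = 3 + min(extra, cfg.max_visits - 3)
    while True:
        t = np.empty(n)
        t[0] = rng.uniform(0.0, cfg.first_visit_by)
        t[1:] = rng.uniform(0.0, cfg.window_years, n - 1)
        t.sort()
        if np.all(np.diff(t) > 1e-9):  # strict ordering, ties astronomically rare
            return t


def generate(cfg: SimConfig = SimConfig(), seed: int = 0
             ) -> tuple[LongCohort, SimTruth]:
    """Draw a cohort from the generative model.

    The visit process enforces the study inclusion rules by
    construction (>= 3 visits inside the 10-year window, first visit
    within 5 years), so the generated cohort passes
    :func:`mlcmm.longdata.apply_inclusion_criteria` unchanged.
    """
    rng = np.random.default_rng(seed)
    theta = cfg.true_params()
    K, L = cfg.K, cfg.L

    covs = (rng.random((cfg.n_subjects, len(cfg.cov_names)))
            < np.asarray(cfg.cov_prevalence)).astype(float)
    # cluster labels from the logistic membership model
    cluster = np.empty(cfg.n_subjects, dtype=int)
    for i in range(cfg.n_subjects):
        p = membership_prior(covs[i], theta.alpha) if L > 1 else np.ones(1)
        cluster[i] = rng.choice(L, p=p)

    b = np.empty((cfg.n_subjects, K))
    chol_G = [np.linalg.cholesky(theta.G[ell]) for ell in range(L)]
    chol_R = np.linalg.cholesky(theta.R)

    sids, rows = [], []
    for i in range(cfg.n_subjects):
        sid = f"s{i + 1:04d}"
        sids.append(sid)
        ell = cluster[i]
        b[i] = chol_G[ell] @ rng.standard_normal(K)
        t = _visit_times(rng, cfg)
        S = spline_basis(t, cfg.spline)
        mean = (theta.beta_V[ell, 0] + S @ theta.beta_V[ell, 1:]
                + covs[i] @ theta.beta_U[:len(cfg.cov_names)]
                + np.einsum("jd,p->jdp", S, covs[i]).reshape(len(t), -1)
                @ theta.beta_U[len(cfg.cov_names):])
        y = mean + b[i] + rng.standard_normal((len(t), K)) @ chol_R.T
        for j in range(len(t)):
            rows.append((sid, t[j], *y[j]))

    visits = pd.DataFrame(rows, columns=[SUBJECT_COL, TIME_COL,
                                         *K_NAMES[:K]])
    baselines = pd.DataFrame(covs, columns=list(cfg.cov_names))
    baselines.insert(0, SUBJECT_COL, sids)
    cohort = make_cohort(visits, baselines, K_NAMES[:K])
    return cohort, SimTruth(cluster=cluster, b=b, params=theta)


# canonical frozen-seed fixtures -------------------------------------------

FIXTURES = {
    # 6 subjects x exactly 3 visits, for small exact-oracle tests
    "tiny": (replace(SimConfig(), n_subjects=6, visit_mean_extra=0.0,
                     max_visits=3), 20240101),
    # strong separation: progressors start lower and decline steeply,
    # tighter random intercepts; constructed so the Bayes-optimal
    # classifier at the true parameters exceeds 98% accuracy even for
    # subjects with short early follow-up
    "separated": (replace(SimConfig(), n_subjects=150,
                          ten_year_change=((-3.0, -2.6), (0.0, 0.0)),
                          onset_level=((-0.3, -0.3), (0.5, 0.5)),
                          g_var=0.2), 20240102),
    # weak separation for calibration stress tests
    "overlapping": (replace(SimConfig(), n_subjects=150,
                            ten_year_change=((-0.6, -0.5), (0.0, 0.0))),
                    20240103),
    # one-cluster null
    "single_cluster": (replace(SimConfig(), n_subjects=150, L=1,
                               ten_year_change=((-0.5, -0.5),),
                               onset_level=((0.0, 0.0),)), 20240104),
}


def make_fixture(name: str, seed: int | None = None,
                 n_subjects: int | None = None) -> tuple[LongCohort, SimTruth]:
    """Return one of the canonical named fixtures.

    ``seed``/``n_subjects`` override the frozen defaults, for replicate
    studies that reuse a fixture's generative settings.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg, default_seed = FIXTURES[name]
    if n_subjects is not None:
        cfg = replace(cfg, n_subjects=n_subjects)
    return generate(cfg, seed=default_seed if seed is None else seed)
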