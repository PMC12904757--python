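"""Model specification and exact mixture likelihood computations.

The model: subject ``i`` carries a latent cluster label ``C_i`` in
``1..L`` drawn from a multinomial-logistic prior with baseline
covariates ``W_i`` (cluster ``L`` is the reference).  Given
``C_i = l``, the ``K`` biomarkers at visit ``j`` follow

    mu_ijk = beta0_k(l) + b_ik + s_ij . beta1_k(l) + X_i . beta2_k
             + (s_ij x X_i) . beta3_k

with a spline-of-time row ``s_ij``, a per-biomarker random intercept
``b_i ~ MVN(0, G(l))`` correlating biomarkers within subject, and
visit-level residuals ``MVN(0, R)`` correlating biomarkers within a
visit (shared across clusters by default).

Random intercepts are linear-Gaussian, so the cluster-conditional
likelihood of a subject's stacked observations is available in closed
form — a ``J_i * K``-dimensional Gaussian with covariance
``1_J 1_J' (x) G(l) + I_J (x) R`` — and is computed exactly rather than
by simulation.  This exactness is what makes sequential membership
updating cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .basis import SplineConfig, spline_basis
from .longdata import SUBJECT_COL, TIME_COL, LongCohort

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ParamDraw",
    "SubjectDesign",
    "build_design",
    "cluster_marginal_loglik",
    "membership_prior",
    "membership_logits",
    "mixture_loglik",
    "bic",
    "n_free_params",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class NumericalError(RuntimeError):
    """A covariance assembled from parameters failed to factorize."""


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the quantile-normalized scale.

    ``beta_sd`` / ``alpha_sd``: SD of independent zero-mean Gaussian
    priors on all trajectory and membership coefficients.
    ``wishart_dof_extra``: inverse-Wishart degrees of freedom for G and
    R are ``K + wishart_dof_extra`` with identity scale.
    """

    beta_sd: float = 5.0
    alpha_sd: float = 5.0
    wishart_dof_extra: int = 2
    wishart_scale: float = 1.0

    def to_dict(self) -> dict:
        return {"beta_sd": self.beta_sd, "alpha_sd": self.alpha_sd,
                "wishart_dof_extra": self.wishart_dof_extra,
                "wishart_scale": self.wishart_scale}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


@dataclass(frozen=True)
class ModelSpec:
    """Dimensions and design roles of the mixture model.

    ``x_names`` are baseline covariates with shared (cluster-invariant)
    main and spline-interaction effects; ``w_names`` drive the
    cluster-membership logit.  The random-effect design is a per-
    biomarker intercept.
    """

    k_names: tuple[str, ...]
    L: int = 2
    x_names: tuple[str, ...] = ()
    w_names: tuple[str, ...] = ()
    spline: SplineConfig = field(default_factory=SplineConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    shared_R: bool = True

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if len(self.k_names) < 1:
            raise ValueError("need at least one biomarker")
        object.__setattr__(self, "k_names", tuple(self.k_names))
        object.__setattr__(self, "x_names", tuple(self.x_names))
        object.__setattr__(self, "w_names", tuple(self.w_names))

    @property
    def K(self) -> int:
        return len(self.k_names)

    @property
    def df(self) -> int:
        return self.spline.df

    @property
    def q_V(self) -> int:
        """Cluster-specific columns per biomarker: intercept + spline."""
        return 1 + self.df

    @property
    def q_U(self) -> int:
        """Shared columns per biomarker: X main effects + spline:X."""
        return len(self.x_names) * (1 + self.df)

    def to_dict(self) -> dict:
        return {"k_names": list(self.k_names), "L": self.L,
                "x_names": list(self.x_names), "w_names": list(self.w_names),
                "spline": self.spline.to_dict(), "priors": self.priors.to_dict(),
                "shared_R": self.shared_R}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(k_names=tuple(d["k_names"]), L=int(d["L"]),
                   x_names=tuple(d["x_names"]), w_names=tuple(d["w_names"]),
                   spline=SplineConfig.from_dict(d["spline"]),
                   priors=PriorSpec.from_dict(d["priors"]),
                   shared_R=bool(d["shared_R"]))


@dataclass
class ParamDraw:
    """One (draw of the) full parameter vector.

    Shapes: ``beta_U (q_U, K)``, ``beta_V (L, 1+df, K)`` with row 0 the
    cluster intercepts, ``alpha (L-1, 1+p_w)`` with column 0 the
    intercept, ``G (L, K, K)``, ``R (K, K)`` shared or ``(L, K, K)``
    per-cluster.
    """

    beta_U: np.ndarray
    beta_V: np.ndarray
    alpha: np.ndarray
    G: np.ndarray
    R: np.ndarray

    def R_for(self, ell: int) -> np.ndarray:
        return self.R if self.R.ndim == 2 else self.R[ell]

    @property
    def L(self) -> int:
        return self.beta_V.shape[0]

    @property
    def K(self) -> int:
        return self.beta_V.shape[2]

    def copy(self) -> "ParamDraw":
        return ParamDraw(self.beta_U.copy(), self.beta_V.copy(),
                         self.alpha.copy(), self.G.copy(), self.R.copy())


@dataclass(frozen=True)
class SubjectDesign:
    """Per-subject design blocks shared across biomarkers.

    ``V = [1, s]`` multiplies the cluster-specific coefficients,
    ``U = [X, s x X]`` the shared ones; the random-effect design is the
    per-biomarker intercept, so it needs no explicit matrix.
    """

    subject_id: object
    t: np.ndarray          # (J,)
    V: np.ndarray          # (J, 1+df)
    U: np.ndarray          # (J, q_U)
    y: np.ndarray          # (J, K), normalized scale
    w: np.ndarray          # (p_w,)

    @property
    def J(self) -> int:
        return len(self.t)

    def mean(self, theta: ParamDraw, ell: int) -> np.ndarray:
        """Cluster-``ell`` fixed-effect mean, shape (J, K)."""
        m = self.V @ theta.beta_V[ell]
        if self.U.shape[1]:
            m = m + self.U @ theta.beta_U
        return m


def _design_rows(t: np.ndarray, x: np.ndarray, spline: SplineConfig
                 ) -> tuple[np.ndarray, np.ndarray]:
    S = spline_basis(t, spline)
    V = np.column_stack([np.ones(len(t)), S])
    if x.size:
        U = np.column_stack([np.tile(x, (len(t), 1)),
                             np.einsum("jd,p->jdp", S, x).reshape(len(t), -1)])
    else:
        U = np.zeros((len(t), 0))
    return V, U


def build_design(cohort: LongCohort, spec: ModelSpec) -> list[SubjectDesign]:
    """Assemble per-subject design blocks from a (normalized) cohort."""
    for name in (*spec.x_names, *spec.w_names):
        if name not in cohort.baselines.columns:
            raise KeyError(f"covariate {name!r} missing from baseline table")
    for k in spec.k_names:
        if k not in cohort.visits.columns:
            raise KeyError(f"biomarker {k!r} missing from visits table")

    base = cohort.baselines.set_index(SUBJECT_COL)
    designs = []
    for sid, grp in cohort.visits.groupby(SUBJECT_COL, sort=False):
        t = grp[TIME_COL].to_numpy(float)
        x = base.loc[sid, list(spec.x_names)].to_numpy(float) if spec.x_names \
            else np.zeros(0)
        w = base.loc[sid, list(spec.w_names)].to_numpy(float) if spec.w_names \
            else np.zeros(0)
        V, U = _design_rows(t, x, spec.spline)
        y = grp[list(spec.k_names)].to_numpy(float)
        designs.append(SubjectDesign(subject_id=sid, t=t, V=V, U=U, y=y, w=w))
    return designs


def marginal_cov(J: int, G_ell: np.ndarray, R_ell: np.ndarray) -> np.ndarray:
    """Covariance of the stacked (visit-major) J*K observation vector
    with the random intercept integrated out:
    ``1_J 1_J' (x) G + I_J (x) R``."""
    return (np.kron(np.ones((J, J)), G_ell) + np.kron(np.eye(J), R_ell))


def cluster_marginal_loglik(d: SubjectDesign, theta: ParamDraw, ell: int,
                            y: np.ndarray | None = None) -> float:
    """Exact log f(Y_i | C_i = ell, theta), random intercept integrated out.

    ``y`` optionally overrides the design's stored observations (same
    (J, K) shape), which the sequential updater uses for visit prefixes.
    """
    yy = d.y if y is None else y
    J, K = yy.shape
    resid = (yy - d.mean(theta, ell)).reshape(J * K)  # visit-major
    sigma = marginal_cov(J, theta.G[ell], theta.R_for(ell))
    try:
        c = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise NumericalError(
            f"marginal covariance for subject {d.subject_id!r}, cluster "
            f"{ell} is not positive definite") from e
    quad = float(resid @ cho_solve(c, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return -0.5 * (J * K * LOG_2PI + logdet + quad)


def membership_logits(w: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Length-L logit vector; reference cluster L has logit 0."""
    alpha = np.atleast_2d(alpha)
    logits = alpha[:, 0] + (alpha[:, 1:] @ w if alpha.shape[1] > 1 else 0.0)
    return np.append(logits, 0.0)


def membership_prior(w: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """P(C_i = l | W_i) for l = 1..L (softmax, reference last)."""
    logits = membership_logits(np.asarray(w, float), alpha)
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


def mixture_loglik(designs: list[SubjectDesign], theta: ParamDraw) -> float:
    """Observed-data log likelihood: sum_i log sum_l pi_il f_l(Y_i)."""
    total = 0.0
    for d in designs:
        logp = np.log(membership_prior(d.w, theta.alpha))
        ll = np.array([cluster_marginal_loglik(d, theta, ell)
                       for ell in range(theta.L)])
        total += float(logsumexp(logp + ll))
    return total


def bic(loglik_hat: float, n_params: int, n_subjects: int) -> float:
    """Bayesian information criterion with subjects as the independent
    units: ``-2 loglik + n_params log(n_subjects)``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik_hat + n_params * float(np.log(n_subjects))


def n_free_params(spec: ModelSpec) -> int:
    """Count of free parameters entering the BIC penalty."""
    K, L = spec.K, spec.L
    cov_terms = K * (K + 1) // 2
    n = spec.q_U * K                    # shared fixed effects
    n += L * spec.q_V * K               # cluster trends
    n += (L - 1) * (1 + len(spec.w_names))  # membership coefficients
    n += L * cov_terms                  # G(l)
    n += cov_terms if spec.shared_R else L * cov_terms
    return n
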