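"""End-to-end workflows: fit, model selection over L, and reports.

These functions are the library surface behind the command-line
interface; they wire together preprocessing, design construction, the
sampler, relabeling, diagnostics and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dynamics, preprocess
from .likelihood import (ModelSpec, bic, build_design, mixture_loglik,
                         n_free_params)
from .longdata import SUBJECT_COL, TIME_COL, LongCohort
from .sampler import (PosteriorSet, multivariate_psrf, posterior_mean_params,
                      relabel, run_mcmc)

__all__ = ["FitResult", "fit_model", "select_num_clusters", "psrf_report",
           "membership_bin_table", "reference_trajectories", "PROB_BINS"]

# probability intervals used for the membership flow report
PROB_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0 + 1e-12)


@dataclass
class FitResult:
    """A fitted model: frozen normalization maps, relabeled posterior,
    and the spec/cohort it came from."""

    spec: ModelSpec
    posterior: PosteriorSet
    maps: dict | None
    cohort: LongCohort          # normalized scale
    designs: list

    def bic(self) -> float:
        theta = posterior_mean_params(self.posterior)
        ll = mixture_loglik(self.designs, theta)
        return bic(ll, n_free_params(self.spec), len(self.designs))


def fit_model(cohort: LongCohort, spec: ModelSpec, n_chains: int = 4,
              n_burn: int = 2000, n_post: int = 3000, seed: int = 0,
              quantile_normalize: bool = True) -> FitResult:
    """Normalize, build designs, sample, and relabel.

    Set ``quantile_normalize=False`` when the input biomarkers are
    already on the standardized scale (e.g., synthetic cohorts drawn
    directly from the model).
    """
    if n_post < 1:
        raise ValueError("no posterior draws requested (n_post must be >= 1)")
    maps = None
    if quantile_normalize:
        maps = preprocess.fit_all_maps(cohort)
        cohort = preprocess.transform_cohort(cohort, maps)
    designs = build_design(cohort, spec)
    ps = run_mcmc(designs, spec, n_chains=n_chains, n_burn=n_burn,
                  n_post=n_post, seed=seed)
    if spec.L > 1:
        ps = relabel(ps, spec)
    return FitResult(spec=spec, posterior=ps, maps=maps, cohort=cohort,
                     designs=designs)


def select_num_clusters(cohort: LongCohort, spec: ModelSpec,
                        candidates=(1, 2, 3), seed: int = 0,
                        **fit_kwargs) -> tuple[pd.DataFrame, int, dict]:
    """Fit each candidate number of clusters and pick the lowest BIC.

    Ties break toward the smaller L.  Returns (table, chosen_L, fits).
    """
    if not candidates:
        raise ValueError("need at least one candidate L")
    rows, fits = [], {}
    for i, L in enumerate(sorted(candidates)):
        spec_L = replace(spec, L=int(L))
        fr = fit_model(cohort, spec_L, seed=seed + i, **fit_kwargs)
        fits[int(L)] = fr
        rows.append({"L": int(L), "bic": fr.bic(),
                     "n_params": n_free_params(spec_L)})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["bic"].idxmin(), "L"])
    return table, chosen, fits


# --------------------------------------------------------------------------
# diagnostics and reports

def _flat_group_traces(ps: PosteriorSet) -> dict[str, np.ndarray]:
    """Per-chain vector traces for the four reported parameter groups:
    trend coefficients, random-intercept covariances, residual
    covariance, and membership coefficients."""
    m, n = ps.n_chains, ps.n_post
    K = ps.spec.K
    iu = np.triu_indices(K)

    def tri(a):  # (m, n, ..., K, K) -> unique entries
        return a[..., iu[0], iu[1]].reshape(m, n, -1)

    groups = {
        "trend_coefficients": np.concatenate(
            [ps.beta_U.reshape(m, n, -1), ps.beta_V.reshape(m, n, -1)],
            axis=2),
        "random_intercept_cov": tri(ps.G),
        "residual_cov": tri(ps.R),
    }
    if ps.spec.L > 1:
        groups["membership_coefficients"] = ps.alpha.reshape(m, n, -1)
    return groups


def psrf_report(ps: PosteriorSet) -> pd.DataFrame:
    """Multivariate PSRF per reported parameter group."""
    rows = [{"group": name, "dim": tr.shape[2],
             "multivariate_psrf": multivariate_psrf(tr)}
            for name, tr in _flat_group_traces(ps).items()]
    return pd.DataFrame(rows)


def membership_summary(fr: FitResult) -> pd.DataFrame:
    """Posterior membership probabilities and modal cluster per
    training subject."""
    p = fr.posterior.pooled_member_prob()
    df = pd.DataFrame(p, columns=[f"prob_cluster_{i + 1}"
                                  for i in range(p.shape[1])])
    df.insert(0, SUBJECT_COL, list(fr.posterior.subject_ids))
    df["modal_cluster"] = p.argmax(axis=1) + 1
    return df


def subject_traces(fr: FitResult, thin: int = 10) -> list:
    """Sequential membership traces for every training subject,
    computed from a thinned posterior to keep the cost linear."""
    ps = thin_posterior(fr.posterior, thin)
    base = fr.cohort.baselines.set_index(SUBJECT_COL)
    out = []
    for sid, grp in fr.cohort.visits.groupby(SUBJECT_COL, sort=False):
        cov = base.loc[sid].to_dict()
        tr = dynamics.membership_trace(
            ps, fr.spec, grp[TIME_COL].to_numpy(float),
            grp[list(fr.spec.k_names)].to_numpy(float), cov, subject_id=sid)
        out.append(tr)
    return out


def thin_posterior(ps: PosteriorSet, step: int) -> PosteriorSet:
    if step <= 1:
        return ps
    sl = slice(None, None, step)
    return PosteriorSet(spec=ps.spec, beta_U=ps.beta_U[:, sl],
                        beta_V=ps.beta_V[:, sl], alpha=ps.alpha[:, sl],
                        G=ps.G[:, sl], R=ps.R[:, sl],
                        member_prob=ps.member_prob[:, sl],
                        loglik=ps.loglik[:, sl], n_burn=ps.n_burn,
                        seed=ps.seed, relabeled=ps.relabeled,
                        subject_ids=ps.subject_ids,
                        accept_alpha=ps.accept_alpha)


def membership_bin_table(traces, cluster: int = 0) -> pd.DataFrame:
    """Counts of subjects per probability interval at each visit index
    (index 0 = baseline, prior-only), for the flow-style report of the
    probability of the fastest-progressing cluster."""
    max_len = max(len(tr.times) for tr in traces)
    rows = []
    for idx in range(max_len):
        probs = [tr.probs[idx, cluster] for tr in traces
                 if len(tr.times) > idx]
        counts, _ = np.histogram(probs, bins=PROB_BINS)
        rows.append({"visit_index": idx, "n_subjects": len(probs),
                     **{f"bin_{i + 1}": int(c)
                        for i, c in enumerate(counts)}})
    return pd.DataFrame(rows)


def reference_trajectories(ps: PosteriorSet, times=None) -> pd.DataFrame:
    """Posterior mean and 95% credible band of each cluster's mean
    trajectory for the reference covariate profile (all covariates 0),
    on the standardized scale."""
    from .basis import spline_basis

    spec = ps.spec
    if times is None:
        times = np.linspace(spec.spline.boundary[0],
                            spec.spline.boundary[1], 41)
    times = np.asarray(times, float)
    V = np.column_stack([np.ones(len(times)),
                         spline_basis(times, spec.spline)])
    D = ps.n_draws
    beta_V = ps.beta_V.reshape(D, spec.L, spec.q_V, spec.K)
    curves = np.einsum("tq,dlqk->dltk", V, beta_V)
    rows = []
    for ell in range(spec.L):
        for k, name in enumerate(spec.k_names):
            c = curves[:, ell, :, k]
            for j, t in enumerate(times):
                rows.append({"cluster": ell + 1, "biomarker": name,
                             "time": float(t),
                             "mean": float(c[:, j].mean()),
                             "lower95": float(np.quantile(c[:, j], 0.025)),
                             "upper95": float(np.quantile(c[:, j], 0.975))})
    return pd.DataFrame(rows)
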