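# mlcmm

Bayesian **multivariate latent class mixture models** for longitudinal
biomarkers: joint trajectory clustering of correlated outcomes, MCMC
posterior inference, BIC-based choice of the number of clusters, and
real-time sequential updating of a patient's cluster-membership
probability and trajectory forecasts as visits accumulate.

The package is aimed at biostatisticians and clinical modelers working
with registry-style longitudinal data — the motivating case is joint
modeling of percent-predicted FVC and DLCO in scleroderma patients,
where "fast progressor" and "stable" subgroups matter for care — but
the number of biomarkers, clusters and covariates is configurable.

## Model

Subject *i* carries one latent cluster label `C_i ∈ {1..L}` shared by
all K of their biomarkers. Conditional on `C_i = ℓ`, biomarker *k* at
time `t_ij` (years since disease onset) follows

    y_ijk = β₀k^(ℓ) + b_ik + s(t_ij)·β₁k^(ℓ) + x_i·β₂k + (s(t_ij)⊗x_i)·β₃k + ε_ijk

with a natural cubic spline `s(t)` in time (default: 2 columns, knot
at 5 years, boundary knots at 0 and 10), correlated per-biomarker
random intercepts `b_i ~ MVN(0, G^(ℓ))`, and correlated within-visit
residuals `ε_ij ~ MVN(0, R)`. Membership is multinomial-logistic in
baseline covariates: `logit P(C_i = ℓ | w_i) = α₀ℓ + w_i·α_Wℓ`.
Biomarkers are quantile-normalized (`Φ⁻¹ ∘ Ĝ_k`) before fitting.

Because the random effects are linear-Gaussian they are integrated out
analytically everywhere — the likelihood, the Gibbs sampler's label
updates, and the sequential updater all use the exact marginal
Gaussian. After fitting, the posterior probability that a (possibly
new) patient belongs to each cluster,
`p_it = P(C_i = ℓ | y_{i,1:t})`, is recomputed after every visit, and
cluster-conditional trajectory forecasts are drawn from the posterior
predictive given the patient's history. See `docs/methods.md` for the
full account.

## Worked example

Simulate a registry-like two-cluster cohort, fit, select the number of
clusters, and sequentially update one subject:

```python
import dataclasses
from mlcmm import synthcohort
from mlcmm.pipeline import fit_model, psrf_report, select_num_clusters

cohort, truth = synthcohort.make_fixture("separated", n_subjects=150)
spec = dataclasses.replace(synthcohort.SimConfig().model_spec(), L=2)
fit = fit_model(cohort, spec, n_chains=2, n_burn=1000, n_post=1000,
                seed=1, quantile_normalize=False)

probs = fit.posterior.pooled_member_prob()
print("modal-cluster accuracy:",
      (probs.argmax(1) == truth.cluster).mean())
print(psrf_report(fit.posterior).to_string(index=False))
```

prints

```
modal-cluster accuracy: 1.0
                  group  dim  multivariate_psrf
     trend_coefficients   36           1.010370
   random_intercept_cov    6           1.003138
           residual_cov    3           1.000224
membership_coefficients    5           1.015332
```

i.e., every subject's modal posterior cluster matches the simulated
truth, and all four parameter groups' multivariate potential scale
reduction factors are within 0.016 of 1 — the chains have converged.
BIC-based selection over candidate cluster counts:

```python
table, chosen, _ = select_num_clusters(
    cohort, spec, candidates=(1, 2, 3), seed=2,
    n_chains=1, n_burn=300, n_post=300, quantile_normalize=False)
print(table.to_string(index=False), "\nchosen L =", chosen)
```

```
 L         bic  n_params
 1 3691.327844        36
 2 2879.552531        50
 3 4728.092907        64
chosen L = 2
```

The two-cluster model has the lowest BIC, matching the generative
truth. Sequentially updating the first subject (a true fast
progressor) shows the membership probability sharpening from the
covariate-only baseline toward certainty as visits accrue:

```python
from mlcmm.dynamics import membership_trace
from mlcmm.longdata import SUBJECT_COL, TIME_COL

sid = cohort.subject_ids[0]
visits = cohort.subject_visits(sid)
covs = cohort.baselines.set_index(SUBJECT_COL).loc[sid].to_dict()
trace = membership_trace(fit.posterior, spec,
                         visits[TIME_COL].to_numpy(),
                         visits[list(spec.k_names)].to_numpy(), covs,
                         subject_id=sid)
print(trace.to_frame().round(3).to_string(index=False))
```

```
 time  prob_cluster_1  prob_cluster_2
0.000           0.892           0.108
1.253           0.961           0.039
1.489           0.975           0.025
2.750           0.991           0.009
3.849           0.997           0.003
4.822           0.999           0.001
5.753           1.000           0.000
8.083           1.000           0.000
9.639           1.000           0.000
```

(some rows elided)  Row one is the baseline probability of being in
the fast-progressing cluster 1, computed from covariates alone; this
subject's covariate profile already leans toward the progressor
cluster, and each visit's lung-function readings push the updated
probability further toward certainty.

The same workflow is available from the shell via the `mlcmm` CLI
(`simulate`, `fit`, `select`, `diagnose`, `update`, `forecast`,
`report`), driven by a YAML config; outputs are plain CSV/YAML.

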