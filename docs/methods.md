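# Methods

`mlcmm` implements a Bayesian multivariate latent class mixture model
(MLCMM) for longitudinal biomarkers: a finite mixture of multivariate
linear mixed models in which each subject carries a single latent
cluster label shared by all of their biomarker trajectories. The
motivating application is joint clustering of percent-predicted FVC and
DLCO trajectories in scleroderma patients at high risk of interstitial
lung disease, where clinicians distinguish "fast progressors" from
"stable" patients; the machinery is generic in the number of
biomarkers, clusters and covariates.

## Model

For subject *i* with visits *j = 1..J_i* at times *t_ij* (years since
disease onset) and *K* biomarkers, conditional on cluster *C_i = ℓ*:

    y_ijk = β₀k^(ℓ) + b_ik + s(t_ij)·β₁k^(ℓ) + x_i·β₂k + (s(t_ij)⊗x_i)·β₃k + ε_ijk

- `s(t)` is a natural cubic spline basis in time (default: 2 columns,
  interior knot at 5 years, boundary knots at 0 and 10 years). Each
  column is zero at onset, so `β₀k^(ℓ)` is the cluster's mean biomarker
  level at disease onset. Columns are rescaled by the knot range so
  their values are O(1) over the window; individual coefficients are
  convention-dependent, fitted curves are not, and all trend
  comparisons in tests are made through fitted curves or the 10-year
  fitted change.
- `b_i = (b_i1..b_iK) ~ MVN(0, G^(ℓ))` are per-biomarker random
  intercepts, correlated across biomarkers within subject.
- `ε_ij ~ MVN(0, R)` are visit-level residuals, correlated across
  biomarkers within a visit and independent across visits; `R` is
  shared across clusters by default (a cluster-specific `R^(ℓ)` is
  supported via `ModelSpec(shared_R=False)`).
- Membership follows multinomial logistic regression on baseline
  covariates `w_i`: `logit P(C_i = ℓ | w_i) = α₀ℓ + w_i·α_Wℓ` for
  `ℓ = 1..L−1`, with cluster `L` the reference.

Biomarkers are quantile-normalized before fitting: `z = Φ⁻¹(Ĝ_k(y))`
with `Ĝ_k` the pooled empirical CDF of biomarker *k* over all training
visits. Conventions: ECDF levels `rank/(n+1)` (finite at the extremes),
mid-ranks for ties, linear ECDF interpolation for unseen values, and
clamping outside the training range. The map is frozen after training;
new patients' sequential updates reuse it, and forecasts are
back-transformed through its inverse for original-unit reporting.

Because the random-intercept structure is linear-Gaussian, the
cluster-conditional likelihood of a subject's stacked observations is
an exact `J_i·K`-dimensional Gaussian with covariance
`1 1' ⊗ G^(ℓ) + I ⊗ R`. All likelihood evaluations use this closed
form — via the Woodbury identity and the matrix determinant lemma, so
the per-subject algebra is K×K regardless of visit count — rather than
conditioning on sampled random effects.

## Priors

Defaults are weakly informative on the quantile-normalized scale:
independent `N(0, 5²)` on every trajectory and membership coefficient,
and inverse-Wishart with `K+2` degrees of freedom and identity scale
on each `G^(ℓ)` and on `R`. On a scale where biomarkers are standard
normal and spline columns are O(1), an SD of 5 is far wider than any
plausible effect, and `K+2` degrees of freedom is the weakest proper
inverse-Wishart with a finite mean. All are overridable through
`PriorSpec`.

## Posterior computation

`run_mcmc` is Metropolis-within-Gibbs, exploiting conditional
conjugacy:

1. `C_i` from its categorical full conditional using the marginalized
   (random-intercepts-integrated) likelihood;
2. all trajectory coefficients jointly from a Gaussian full
   conditional **with the random intercepts still integrated out** (a
   partially collapsed update; conditioning on `b` leaves a very slow
   ridge between cluster intercepts and `G` that can inflate `G`
   without bound on finite runs);
3. `b_i` from its Gaussian full conditional;
4. `G^(ℓ)` and `R` from inverse-Wishart full conditionals;
5. `α` by random-walk Metropolis with 10 sub-steps per scan, step size
   adapted toward 0.3 acceptance during burn-in only (the target is a
   small logistic-regression posterior; Pólya-Gamma augmentation would
   be the conjugate alternative and is not implemented).

Initialization: per-subject OLS intercept/slope summaries per
biomarker, winsorized at the 5%/95% quantiles (per-subject slopes are
heavy-tailed when visit times cluster), standardized, then k-means for
the initial labels; per-cluster least squares for the coefficients;
chain-specific Gaussian jitter overdisperses starting points. Defaults
are 2000 burn-in iterations, 3000 kept draws and 4 chains. Everything
is reproducible bitwise from one integer seed. Empty clusters are allowed during sampling; their parameters
then update from the prior (no artificial repopulation).

Label switching is resolved after sampling: within every draw,
clusters are sorted by the fitted 10-year change of the first
biomarker's cluster trend (most negative — fastest progressing —
first), with `α` re-expressed against the permuted reference cluster.
Relabeling is an exact model symmetry; the mixture likelihood of each
draw is unchanged.

## Model selection and diagnostics

The number of clusters is chosen by BIC,
`−2·loglik + n_params·log(n_subjects)`, with the observed-data mixture
log likelihood evaluated at the relabeled posterior mean and subjects
(the independent units) as the sample size — both documented choices
where the convention is ambiguous.

Convergence is monitored with the Gelman–Rubin PSRF,
`R̂ = sqrt(((n−1)/n·W + B/n)/W)`, and the Brooks–Gelman multivariate
PSRF computed for four parameter groups (trend coefficients; the
`G^(ℓ)`; `R`; `α`). The multivariate statistic is implemented without
the `(m+1)/m` finite-chain factor so that its one-dimensional case
reduces exactly to the scalar definition; it still bounds the scalar
PSRF of every linear projection from above.

## Sequential updating and forecasting

The cluster label is a fixed latent trait; belief about it evolves.
For each stored posterior draw θ, the probability vector
`p(C_i | y_{1:t}, θ)` combines the covariate prior with the exact
marginal likelihood of the visit prefix; `p_it` is the average over
draws (Rao-Blackwellized — no label resampling, lower variance, same
expectation). With no biomarker history this reduces exactly to the
posterior-averaged covariate prior. Updates are defined at visit
prefixes; an update at an arbitrary time t uses all visits with time
≤ t.

Cluster-conditional forecasts sample, per posterior draw, the horizon
values from their Gaussian conditional given the observed history
(history and future are jointly Gaussian under a draw), giving exactly
one predictive sample per draw. Mixture forecasts (used for
calibration checks) first sample a label from that draw's membership
posterior. Horizon times beyond the spline boundary use the basis's
natural linear continuation and should be kept moderate.

## Synthetic cohorts

`synthcohort.generate` draws cohorts from the model's own generative
process, emulating the structure of the motivating registry subset:
289 subjects by default; four Bernoulli baseline covariates with
prevalences 0.163 (male), 0.225 (Black race), 0.571 (diffuse subtype),
0.5 (late onset); membership logits mirroring the known risk
directions with intercept −1.33, centering the marginal split near
50/50; visit counts `3 + NegBin(2, mean 4.5)` capped at 28 (range
3–28, median ≈ 7); visit times uniform on [0, 10] with the first
forced ≤ 5 years, so the study inclusion rules hold by construction;
cluster 1 declining 1.2 standardized units over 10 years in both
biomarkers and cluster 2 flat; `G` with variances 0.5 and
cross-biomarker correlation 0.5; `R` with variances 0.15 and
correlation 0.4.

Generated biomarkers live directly on the standardized scale (pipelines
fitting them set `quantile_normalize=False`); the generator does not
emulate measurement-scale artifacts, informative visit timing, dropout,
missingness or treatment effects, so passing tests demonstrate
correctness of the inferential machinery under the model's own
assumptions, not robustness to real-data violations of them.

Named frozen fixtures: `tiny` (6 subjects × 3 visits, for exact-oracle
tests), `separated` (steeper decline, −2.6/−2.2 over 10 years,
`g_var = 0.3` — strong enough that k-means initialization alone
recovers ≥ 90% of labels), `overlapping` (decline −0.6/−0.5, for
calibration stress), `single_cluster` (L = 1 null).

## Verification harness sizes

The statistical acceptance suite uses: 20 replicates of 150-subject
separated cohorts at 2 chains × 1000 burn-in / 1000 draws for CI
coverage and cluster recovery; 5 dedicated replicates with every
subject's final visit held out (2 × 500/500; 1500 predictions) for
predictive-band calibration — final visits are each subject's most
informative observation, so holdout fits are kept separate from the
recovery fits; and 10 + 10 replicates of 100 subjects at 1 chain ×
300/300 per candidate L for BIC selection recovery. These sizes are
the package's verification defaults; the thresholds they are checked
against (85% per-effect coverage, ≥95% modal accuracy per replicate,
≥80% selection recovery, predictive coverage within [0.90, 0.98]) are
stated in the tests.

## Numerical notes and limitations

- Covariances are factorized with Cholesky; a non-positive-definite
  assembly raises a contextual error rather than propagating NaNs.
- `membership_prior` subtracts the max logit before exponentiating;
  mixture log likelihoods use log-sum-exp.
- Duplicate (subject, time) rows are rejected at load: same-day repeat
  tests would break the strictly-increasing-time invariant the prefix
  updater relies on, and the right aggregation is a data-cleaning
  decision, not the model's.
- BIC at the posterior mean is a plug-in approximation; with heavy
  label switching before relabeling it could degrade, which is why
  relabeling precedes it.
- The α block is Metropolis, so its effective sample size per draw is
  lower than the conjugate blocks'; the multivariate PSRF report makes
  this visible per group.
- Forecast draw count equals the stored posterior draw count by
  design; thinning the posterior thins forecasts correspondingly.
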