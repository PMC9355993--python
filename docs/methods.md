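# Methods

This note documents the models, the sampler, the synthetic-data
generators, the numerical choices, and the limits of what the test suite
demonstrates.

## Normative model and w-values

For each region the CU arm is modelled as
`y = beta0 + beta_age * age + u_cohort + u_subject + e`, with independent
Gaussian random intercepts for cohort and subject and a fixed linear age
effect over the supported span of 50–90 years. The marginal likelihood is
maximised directly: the fixed effects are profiled out by GLS inside the
objective and the three variance components are optimised on the log-SD
scale with L-BFGS-B (bounds `exp(-8)` to `exp(6)` on the SD scale; 200
iterations; moment-based start). ML is the default; REML is a switch
(`method="reml"`). Per-cohort covariance blocks keep the cost linear in
the number of cohorts. Cohort offsets for cohorts seen in training are
empirical-Bayes (BLUP) predictions.

The w-transform divides the residual `y - prediction` by an SD that
matches what was subtracted (default `sd_components="match"`):

* known cohort: prediction includes the cohort offset, SD =
  sqrt(subject + residual variance);
* population mode (unseen cohorts): prediction is the population mean,
  SD = sqrt(cohort + subject + residual variance).

With this pairing, CU-like data standardise to mean 0, SD 1 in *both*
modes. Forcing the full marginal SD everywhere (`sd_components="all"`)
deflates known-cohort w-SDs to about
`sqrt((v_s+v_e)/(v_c+v_s+v_e))` (≈0.89 at the default simulation
variances) and is kept only as a sensitivity option. The subject random
intercept is never subtracted when transforming patients — they are not
normative-training subjects — so it stays in the SD.

## The mixture of multivariate linear mixed models

Observation model (region-major random-effect layout, d = R·(T+1)):

```
w_irj = x_ij' beta_r + b_ir0 + b_ir1 t_ij (+ b_ir2 t_ij^2) + e_irj
e_irj ~ N(0, sigma2_r),   b_i | z_i=k ~ N(mu_k, Sigma_k),   z_i ~ Cat(pi)
```

`t` is disease duration in years (visits before recorded onset are
rejected at ingest). Fixed effects are shared across clusters: a 3T
indicator and eTIV z-scored over the fitting set, both *centred* —
uncentred codes are exactly collinear with the cluster-mean intercept
direction and cripple mixing. `MixtureModel.encode_covariates` maps raw
values into the fitted coding; fitted maps and concordance reports default
to the population-average covariate point (coded zeros).

### Priors

All exposed in `MixturePriors`; defaults are weakly informative on the
w-scale: Dirichlet(1) on `pi`; `mu_k ~ N(0, 10^2 I)`;
`sigma2_r ~ InvGamma(0.01, 0.01)`; `beta ~ N(0, 100)` per coefficient;
`Sigma_k ~ InvWishart(nu0, Psi0)` with `nu0 = d+2`. The scale matrix is
empirical by default: `Psi0 = (nu0 - d - 1) * diag(v0)` where `v0` is the
within-cluster variance diagonal of the initial allocation, so the prior
mean sits on the data's own scale. This matters: intercepts (~0.1–1 w²)
and per-year slopes (~0.01 w²/yr²) live on very different scales, and a
unit isotropic scale matrix overwhelms the slope blocks and merges
clusters. A scalar `psi0` restores `Psi0 = psi0 * I` for sensitivity
checks.

### Sampler

A fixed-scan, partially-collapsed Gibbs sampler:

1. `beta` | z, mu, Sigma, sigma2 — Gaussian, with the random effects
   integrated out analytically;
2. `mu_k` | beta, z, Sigma, sigma2 — Gaussian, also collapsed over b;
3. `b_i` | everything — Gaussian (the per-subject precision
   `Sigma_k^{-1} + Z_i' D^{-1} Z_i` is shared with the collapsed steps);
4. `z_i | b` — categorical on `pi_k N(b_i; mu_k, Sigma_k)`;
5. `Sigma_k | b, z, mu` — inverse-Wishart;
6. `pi | z` — Dirichlet; 7. `sigma2_r | b, beta` — inverse-Gamma.

The collapsed steps are the load-bearing design choice: conditioning
`beta` and `mu` on sampled `b` random-walks along the ridge between
subject-constant covariates (scanner field strength never changes within
a subject) and the subject intercepts — measured lag-1 autocorrelations
around 0.9 versus ≈0 after collapsing. Because `b` is redrawn immediately
after the collapsed draws and before anything else conditions on it, the
scan is an exact blocked Gibbs sampler for the stated posterior (the
collapsed conditionals were verified against dense brute-force
computations to 1e-14). All within-sweep linear algebra runs batched in
the d-dimensional random-effect space via the matrix-determinant and
Woodbury identities; the observed-data deviance
`-2 sum_i log sum_k pi_k N(y_i; X_i beta + Z_i mu_k, Z_i Sigma_k Z_i' + D_i)`
is evaluated at every retained draw and is comparable across K and trend
orders.

Randomness comes from counter-based Philox streams keyed by
`(seed, sweep, update block)`: chains are bit-reproducible, and because
datasets are kept in canonical order (subject id, then age), permuting
input rows cannot change a fit. Empty clusters draw `(mu_k, Sigma_k)`
from the prior; a cluster empty in more than half the sweeps triggers a
degenerate-cluster warning.

### Initialisation and restarts

Gibbs samplers for mixtures merge clusters easily but essentially never
split them, so the starting allocation decides which mode the chain
explores. The start is built from low-noise subject summaries: per-region
mean w minus a pooled slope times mean duration (raw per-subject OLS
intercepts extrapolate back to onset and are uselessly noisy for subjects
first seen late), plus OLS slopes shrunk toward the pooled slope with an
empirical-Bayes weight. Ward clustering of the intercept summaries is
refined by a few rounds of cluster-specific slope re-adjustment and
nearest-centroid reassignment (undoing the pooled-slope bias that smears
fast-progressing clusters along duration). On top of that, `gibbs_fit`
runs short pilot chains (default 8 restarts × 200 sweeps) from the Ward
start and from seeded k-means++ allocations and continues the mode with
the lowest mean observed-data deviance — the same quantity used for
model comparison. Restarts are deterministic under the fit's seed and can
be disabled (`n_restarts=0`).

### Label switching

Retained draws are relabeled by greedy matching of each draw's cluster
means to a running posterior-mean reference (optimal assignment per
draw), then clusters are reported in decreasing-weight order. This is a
pragmatic convention, not a full relabeling algorithm; with separated
clusters the permutation is almost always the identity after burn-in.

### Stepwise quadratic refinement

`fit_stepwise_quadratic` runs the linear model to completion, then builds
a quadratic spec whose cluster means gain zero-mean quadratic terms, with
the linear posterior means embedded exactly and small initial quadratic
variances (`quad_init_var = 0.01`); allocations start at the linear
posterior mode. This captures the atrophy plateau at long disease
duration without optimising all trend parameters from a cold start. The
initialisation is recorded in `MCMCSamples.init_record`.

## Diagnostics and model ranking

Quality of a fit is summarised by mean observed-data deviance and by the
fraction of scalar parameter chains (elements of pi, mu, diag Sigma,
beta, sigma2) whose lag-1 autocorrelation exceeds
`median + 3 * 1.4826 * MAD` over all chains — a robust, scale-free
reading of "higher autocorrelation than the majority", with the
multiplier and lag configurable. Constant chains are flagged by
definition. `rank_models` returns the Pareto front over (deviance ↓,
flag fraction ↓) and refuses to auto-select when the front has more than
one member: conflicting criteria are an analyst's decision.

## Classification, concordance and cluster matching

Classification of new subjects uses pi-weighted closed-form marginal
likelihoods at the posterior-mean state (draw-averaged responsibilities
are an option). Single-visit subjects are handled naturally — one visit
still constrains the intercepts. eTIV standardisation and covariate
centring reuse the constants stored in the fitted model, never
re-estimated on new data. An ambiguity flag marks subjects with max
probability < 0.5 and runner-up > 0.3 (both configurable). Validation
concordance compares per-cluster median observed w-maps against fitted
values at the cluster's median disease duration. Clusters of two
independent fits are matched by exact optimal assignment on Euclidean
distances between concatenated (intercept, slope) posterior means.

## Post hoc analyses

Fitted maps are posterior medians of the cluster trend polynomial on a
0–8-year grid; "smoothing" is the posterior-median summarisation only (a
3-point temporal moving average exists, default off — any spatial
smoothing would need geometry the model does not carry). Atrophy masks
use -1.6 (conservative) and -0.5 (liberal) w-thresholds. Pathway
dendrograms are Ward/Euclidean agglomerations of the K×R intercept and
slope mean matrices with a 2-group cut. Nodal strength converts the
intercept or slope block of `Sigma_k` to a correlation matrix and sums
absolute off-diagonal correlations per region (`signed=False` default —
"sum of correlations" is ambiguous under negative correlations). Network
comparisons are posterior credible intervals of per-region strength
differences over the retained `Sigma` draws (positive = reference
stronger), rather than any external permutation machinery.

## Synthetic data

The generators emulate the structure of multi-cohort aging/AD studies,
not any real cohort's values:

* CU arm: linear decline with age 50–90 (default slope -0.02 units/yr,
  baseline 2.5), cohort offsets (SD 0.2), subject intercepts (SD 0.3),
  visit noise (SD 0.25), 3–9 visits ~1 year apart, log-normal eTIV around
  1.5e6 mm³, per-subject scanner field strength.
* AD arm (in w-units): per subject a latent cluster, a random-effect
  vector from that cluster's Gaussian, onset age ~ N(72, 7²), first visit
  uniform in 0–8 years of duration, later visits at 0.4–1.1-year gaps,
  plus field-strength and eTIV fixed effects.
* `preset_three_patterns`: minimal / limbic-predominant /
  cortical-predominant archetypes with pairwise Mahalanobis separations
  ≈7–9 — the regime where recovery should be near-exact.
* `preset_five_patterns`: MA / LPA / LPA+ / DA / HS archetypes with the
  qualitative orderings of the atrophy-subtyping literature (MA least
  atrophic at onset; HS most cortical, least mediotemporal; LPA+ faster
  than LPA; slope geometry separating {MA, LPA, LPA+} from {DA, HS}),
  weights 0.50/0.28/0.10/0.05/0.07 — dominance of the minimal and limbic
  patterns while keeping every cluster identifiable at n=400. Pairwise
  Mahalanobis separations are ≥4.7 (Bayes-optimal ARI on the true latent
  vectors ≈0.99); the shapes are qualitative stand-ins, not estimates of
  any fitted clusters.
* `preset_plateau`: single archetype with a positive quadratic term
  (steep early decline that flattens), or a purely linear control.

What passing tests do *not* show about real data: the generators draw
truly Gaussian clusters with shared covariance shape, complete
measurement vectors, exact onset ages and well-separated archetypes. Real
cohorts have non-Gaussian heterogeneity, onset-age recall error,
missingness correlated with severity, and overlapping subtypes; recovery
rates here are upper bounds of a different regime, and the package's
value on real data rests on the model's assumptions, not on these tests.

## Experiment scales

The suite and `scripts/acceptance.py` run: normative recovery at n=300
CU subjects over 12 cohorts × 4 regions (many small cohorts so the cohort
variance component is estimable; the pooled age slope is the tested
estimand, per-region slopes having SEs near the tolerance); K=1
sampler-vs-ML equivalence at n=100 × 3 regions × 2000 sweeps with
random-effect scales the data identify (intercept SD 0.5, slope SD 0.2,
4–7 visits — with unidentified variance components the posterior mean and
the ML point estimate legitimately disagree at this n); three-pattern
recovery at n=150 × 6 regions × 4000 sweeps; the stepwise check at n=80;
the five-pattern demonstration at n=400 × 8 regions × 2500 sweeps.
Posterior weights and credible-interval coverage are compared against the
*realised* (finite-sample) cluster frequencies and latent means — the
estimands the data actually carry — rather than the generative constants.

## Known limitations

* Gaussian response only; no non-Gaussian families, infinite mixtures or
  tempering.
* Single-chain design; no cross-chain R-hat (the autocorrelation flag
  fraction is the mixing diagnostic).
* Greedy relabeling can mislabel draws when clusters genuinely overlap.
* Covariance estimation needs cluster sizes comfortably above d = R(T+1);
  `dim_cap` warns at d > 60.
* The deviance-guided restarts reduce, but cannot eliminate, the risk of
  settling in a merged mode when clusters are weakly separated.
* Linear aging in the normative model; no heteroscedastic (age-varying)
  normative SDs.
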