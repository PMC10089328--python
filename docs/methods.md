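# Methods

## Outcome construction (CIAF)

Each child record carries three anthropometric z-scores relative to the WHO
2006 growth-standard medians: height-for-age (HAZ), weight-for-height
(WHZ) and weight-for-age (WAZ). A record is valid when HAZ ∈ [−6, 6],
WHZ ∈ [−5, 5] and WAZ ∈ [−6, 5] (the standard DHS/WHO flagging windows,
inclusive); invalid records are dropped with a logged count. Failure is
strict: stunted ⇔ HAZ < −2, wasted ⇔ WHZ < −2, underweight ⇔ WAZ < −2, so a
z-score of exactly −2 is not failure. The eight flag combinations map to
the conventional groups A–G plus a label H for the combination (stunted and
wasted, not underweight) that the convention omits; H is physiologically
rare and is counted as failure, since the CIAF is defined as *any* failure.
A warning is logged when H occurs.

Prevalence intervals are unweighted Wald intervals,
p̂ ± z·√(p̂(1−p̂)/n), clipped to [0, 1]. Survey-design weighting is out of
scope. In the prevalence table the "Stunting Only" / "Wasting Only" /
"Underweight only" rows report the *marginal* simple indices (any stunting,
any wasting, any underweight), while the combination rows report the
exclusive CIAF groups — the mixed convention customary in CIAF reporting.

## Model

For child *i* in region *s*:

    logit P(y_i = 1) = v_i'β + Σ_r f_r(x_ir) + f_str(s_i) + f_unstr(s_i)

- **Fixed effects.** Reference-coded categorical covariates with proper
  diffuse priors β_j ~ N(0, 10⁸) (a numerically safe stand-in for flat
  priors; at survey sample sizes the prior contribution is negligible).
  Continuous covariates appearing linearly (in the reduced models, below)
  are standardised to mean 0, SD 1 so that linear and smooth versions of
  the same covariate produce comparable predictors.
- **Smooths.** Bayesian P-splines: a cubic B-spline basis on 20
  equidistant segments of the observed covariate range (23 basis
  functions; both counts are configuration knobs), with a Gaussian
  random-walk prior on adjacent coefficients expressed as the difference
  penalty K = DᵀD of order 2 by default (order 1 available). Knots are
  equidistant, not quantile-based, matching standard P-spline practice.
- **Structured spatial effect.** Intrinsic GMRF over the region graph:
  the prior precision is the graph Laplacian (diagonal = neighbour count
  N_s, off-diagonal −1 for adjacent pairs), so each region's full
  conditional is Gaussian with mean the neighbour average and variance
  γ²_str/N_s.
- **Unstructured spatial effect.** iid N(0, γ²_unstr) per region,
  capturing non-spatial regional heterogeneity.
- **Variance components.** Every penalised block's variance γ² carries an
  IG(a, b) prior, default a = b = 0.001; the alternative standard choice
  (1, 0.005) is available for sensitivity analysis.

**Identifiability.** The penalties of the smooth and spatial blocks have
non-trivial null spaces containing the constant vector, which is
confounded with the intercept. Each smooth block is reparameterised so its
fitted values sum to zero over the observations; each spatial block so its
regional effects sum to zero. The reparameterisation is exact: an
orthonormal basis Z of the constraint's null space replaces the block
matrix X by XZ and the penalty K by ZᵀKZ, dropping exactly one column and
leaving the fitted predictor unchanged in the presence of a free
intercept. The RW2 smooth penalty retains a one-dimensional (linear-trend)
null space after the constraint; it is unpenalised and identified by the
data.

## Posterior computation

Sampling uses Pólya-Gamma augmentation: introducing ω_i ~ PG(1, η_i) makes
the Bernoulli-logit likelihood Gaussian in η, so each sweep performs

1. ω_i ~ PG(1, η_i) for all records;
2. one exact multivariate-normal draw per coefficient block (order:
   fixed → smooths → structured → unstructured), with posterior precision
   XᵀΩX + K/γ² (plus the diffuse 10⁻⁸ ridge) and mean solved by Cholesky;
3. conjugate variance updates γ² ~ IG(a + rank(K)/2, b + βᵀKβ/2). The
   rank, not the block dimension, enters the shape because the penalty's
   null space carries no information about γ².

The PG(1, z) sampler is the exact Devroye alternating-series rejection
method (truncated inverse-Gaussian body, exponential tail, partial-sums
squeeze), vectorised over the whole record vector; its per-round
acceptance is ≈0.9998, so a full sweep costs a few numpy passes. Moments
are verified against the closed forms E[PG(1,z)] = tanh(z/2)/(2z) and
Var[PG(1,0)] = 1/24 in the test suite.

Default chain schedule: 12,000 iterations, 2,000 burn-in, thinning 10
(1,000 stored draws). Stored-draw count is exactly
⌊(iterations − burnin)/thin⌋. Chains are pure functions of the seed.
Coefficient blocks start at zero and variance components at 0.1; the
Gibbs sampler forgets these within a few hundred sweeps at the sample
sizes considered here. Deviance is clamped via p ∈ [10⁻¹², 1 − 10⁻¹²] to
stay finite under saturation. Quasi-complete separation in a fixed effect
is detected by a constant-outcome cell check and reported as a warning
only — the proper priors keep the posterior well defined.

## Model selection

The nested hierarchy is M0 (linear fixed effects only, continuous
covariates linear), M1 (+ P-spline smooths), M2 (linear + spatial), M3
(full). For each fit, D̄ is the mean of the stored deviance trace and
D̂ the deviance at the posterior means of all coefficient blocks (the
classical plug-in definition), giving pD = D̄ − D̂ and DIC = D̄ + pD =
D̂ + 2·pD; the internal identity is enforced to 10⁻⁹. The smallest-DIC
model is selected.

## Reporting conventions

Fixed effects: posterior odds ratios with central 95% credible intervals;
the point estimate is the mean of the exponentiated draws (not the
exponentiated mean — both are derivable from stored draws, and the
convention is recorded in the table metadata); significant ⇔ the interval
excludes 1. Smooths: pointwise posterior mean and 2.5/97.5% quantiles of
the centred curve on a user grid (grid points outside the knot range are
an error). Spatial effects: per region, the draws of the structured, the
unstructured, or the total (sum) effect are summarised and coded +1 when
the 95% interval lies above zero, −1 below, 0 otherwise; classification
defaults to the total effect, and the structured-only map is also
available since that is what choropleth displays conventionally show.

## Synthetic data

The generator emulates a national household-survey child dataset on an
R-region graph (rook lattices stand in for an administrative map):

- ages uniform on their supports (child 0–59 months, mother 15–49 years);
- categorical covariates drawn independently from survey-like marginals;
- fixed-effect truth defaulting to posterior odds ratios reported by a
  national-scale analysis of this outcome (e.g. male 1.315, diarrhoea
  1.256, media exposure 0.858);
- a child-age effect that rises to ≈30 months, dips to 48 and rises again
  (piecewise quadratic — the shape, not the formula, is the documented
  phenomenon), and a small negative linear mother-age effect, both centred
  over the sampled values;
- a structured field drawn from the intrinsic GMRF via the spectral
  decomposition of the Laplacian with the null eigenvector removed (so the
  sum-to-zero constraint is exact and the draw covariance is γ²K⁺), with
  default γ²_str = 0.323; iid unstructured effects with default
  γ²_unstr = 0.009;
- Bernoulli outcomes through the logistic link of the assembled predictor.

Z-score triplets for the classification pipeline are trivariate normal
with unit variances and correlations (HAZ,WAZ) = 0.6, (WHZ,WAZ) = 0.65,
(HAZ,WHZ) = −0.1, shifted by a common mean μ calibrated so the implied
CIAF prevalence hits a target (default 41.3%). The calibration equation
P(min_k z_k < −2) = p is solved exactly on the sample's empirical law by
the order-statistic quantile μ = −2 − Q_p(min_k e_k), so the achieved
prevalence is within 1/n of the target. These records deliberately are
*not* linked record-by-record to the regression outcome: the two pipelines
exercise different modules.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real survey data: two-stage cluster sampling and
sampling weights, covariate dependence (real wealth, education and
residence are strongly associated), item-missingness mechanisms, irregular
administrative adjacency structures, and measurement error in
anthropometry beyond the plausibility windows.

## Problem sizes used in validation

The automated checks run at deliberately moderate scale chosen to make the
full suite convenient on a single CPU while keeping every check
well-powered: recovery and specificity experiments use n = 3,000–4,000
children on a 12-region lattice with chains of ~1,000–1,100 iterations
(300 burn-in, thin 2), credible-interval coverage uses 20 independent
replicates, and the large-sample comparison against the maximum-likelihood
logistic fit uses n = 20,000. The Pólya-Gamma Gibbs sampler mixes quickly
for this model class, which is what makes these short chains adequate;
production analyses should use the 12,000-iteration default.

## Known limitations

- Logit link only; no probit or multinomial outcomes.
- No tensor-product or varying-coefficient smooths.
- Structured and unstructured spatial components are only weakly
  separately identified (the standard convolution-model caveat); their sum
  is the well-identified quantity, which is why significance coding
  defaults to the total effect.
- DIC is the only model-comparison criterion (no WAIC or cross-validation).
- Complete-case handling of missing data; no imputation.
- Maps are rendered only as lattice heat-grids for visual checks; real
  administrative boundary rendering is out of scope.
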