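# Methods

This note records the modelling assumptions, the numerical choices, and
the design decisions behind `mrdjoint`, in the spirit of a model
reference page. The README states the model; here we explain why each
piece looks the way it does and what the synthetic benchmark does and
does not demonstrate.

## Observation model and censoring

Log10 MRD (percent scale) at days 15 and 42 is modelled as normal with
a detection limit at `z_low = log10(0.01) = −2`. A censored observation
enters the likelihood through the normal CDF mass below `z_low`; inside
the Gibbs sampler the same information is carried by data augmentation
— a draw from the normal truncated above at `z_low`. Both routes
describe the same posterior; the test suite checks the CDF terms
against numerical quadrature (to 1e−8) and checks that alternating
truncated imputation with allocation draws reproduces the closed-form
allocation probabilities obtained by integrating the censored values
out.

The day-42 mean contains the autoregressive and covariate block only
when day-15 MRD is detected (`δ^(1) = 1`). For day-15-censored patients
the day-42 mean is the bare intercept `β0^(2)`: their (almost always
censored) day-42 values say nothing about covariate effects, and
forcing dependence through imputed day-15 values would bias both the
temporal and the covariate coefficients. A consequence worth knowing:
`β0^(2)` is identified mainly through a one-sided constraint (it must
sit far enough below `z_low` to keep the censored group censored), so
`β0^(2)` and `ρ0` are individually soft; their sum, which is what the
day-42 regression among detected patients pins down, is well
identified.

## Priors

* `β^(t)`, `γ^(t)`: horseshoe, i.e. `β_j ~ N(0, λ_j² τ²)` with
  independent half-Cauchy(0,1) local scales `λ_j` and one global scale
  `τ` per block (four blocks: day-15/day-42 × covariates/cluster
  contrasts). The sampler uses the inverse-gamma auxiliary
  representation, which makes every scale update conjugate.
* `ρ0, ρ ~ N(0, 1)`; all variances `~ Inv-Gamma(3, 2)` (mean 1);
  mixture weights `~ Dirichlet(1/3, 1/3, 1/3)`; component means
  `~ N_5(0, I)` on the standardized LC50 scale.
* Intercepts `β0^(t) ~ N(0, 10²)` — weakly informative on the
  log10-percent scale, where plausible values span roughly (−8, 2).

## Mixture covariance

The mixture over 5-dimensional LC50 vectors supports two diagonal
covariance readings behind `cov_mode`:

* `"diag_shared"` (default): one variance per drug, shared across
  components, `Σ = diag(σ_1², …, σ_5²)`.
* `"isotropic"`: one variance per component, `Σ_j = σ_j² I_5`.

The default is `diag_shared` because the mixture is fit on per-drug
standardized columns, whose within-component variances genuinely differ
by drug: a drug that separates the profiles strongly ends up with small
within-component variance after standardization, while a
non-separating drug ends up near 1. An isotropic likelihood weights
all drugs equally and demonstrably degrades allocation recovery on the
synthetic benchmark (Binder-partition ARI ≈ 0.88 vs ≈ 0.94, where the
anisotropic information ceiling of the imputed data is ≈ 0.93). Both
modes are first-class and tested.

## Multiple imputation and completion selection

Missing LC50 entries (MCAR per drug in the generator; rates 19–40%) are
completed by chained equations: each incomplete column is regressed on
all other current-state columns with a Bayesian normal linear model
(vague prior), and missing entries are replaced by posterior-predictive
draws — so completions carry parameter uncertainty, not only residual
noise. Ten sweeps per completion; m = 100 completions by default.
K-means (k-means++, multi-restart, best WSS kept) on each completion
over k = 1…10 gives WSS curves whose average locates the elbow at
k = 3; the completion with the lowest WSS at k = 3 is carried into the
joint model. Pre-imputation is a deliberate simplification: it
understates LC50 uncertainty in the joint posterior, which is the price
of keeping the mixture block conjugate on a fixed complete matrix.

## Sampler

One sweep updates, in order: censored MRD values (truncated normals),
allocations (categorical full conditional combining `w_j`, the
component density of `Y_i`, and the patient's MRD likelihood under each
candidate cluster, in log space), mixture parameters (Dirichlet /
normal / inverse-gamma conjugate draws; empty components draw from the
prior), the two regression blocks (joint multivariate-normal draws —
day-42 on the gated design `[1, δ1, δ1·z1, δ1·X, δ1·C]`, so imputed
day-15 values never leak into the day-42 block), observation variances
(`Inv-Gamma(3 + n/2, 2 + RSS/2)`), and horseshoe scales. Defaults:
15000 iterations, 5000 burn-in, thinning 2 (5000 retained draws),
single chain, fully seed-deterministic.

Numerical safeguards: squared horseshoe scales are clipped to
[1e−16, 1e16]; the conditional precision Cholesky gets escalating
jitter if (pathologically) non-positive-definite; truncated-normal
draws use inverse-CDF in the bulk and a Robert-style exponential
rejection sampler when the standardized bound is below −30; allocation
probabilities are normalized in log space.

Initialisation: ridge regression on threshold-imputed responses,
k-means labels for the allocations, horseshoe scales at 1. Label
switching is left alone: partition inference goes through the
label-invariant posterior similarity matrix, and cluster-specific
summaries are computed on the Binder point partition.

Correctness is enforced by a Geweke-style joint-distribution test (500
independent short chains alternating data regeneration with full
sweeps must leave the prior marginals of ρ, σ²^(1) and w exactly
invariant — a deliberately corrupted conditional fails it), plus
conditional-by-conditional oracles (OLS limit under flat scales, prior
recovery with no data, conjugate-algebra checks, brute-force
allocation probabilities).

## Partition point estimate

Binder's loss with equal misclassification costs,
`L(c) = Σ_{i<j} |1[c_i = c_j] − psm_ij|`, minimized over the sampled
allocation draws followed by greedy single-element reassignment sweeps
from the ten best candidates (moves to any existing cluster or a fresh
singleton) until no move improves the loss. On small problems the
result matches exhaustive enumeration over all set partitions; by
construction it dominates every sampled draw. Credible-interval
summaries use 95% equal-tailed empirical quantiles with linear
(type-7) interpolation.

## Synthetic cohort: what it emulates, and its calibration

The generator is the package's study population. Defaults were fixed
analytically from typical trial summary tables before any fitting:

* n = 788 patients; protocol arms in proportions 192:428:168; 54.8%
  male; lognormal age (median ≈ 5.4 y, mean ≈ 6.9 y); log10-normal WBC
  (median ≈ 16.6, mean ≈ 51.5).
* Twelve subtype categories with skewed frequencies (hyperdiploid 25%,
  ETV6-RUNX1 22%, down to 2%), matching the practice of pooling
  subtypes with fewer than 10 patients into an "Other" level.
* Day-15 model: `β0^(1) = −2.1`, `σ²^(1) = 1.2`, nonzero effects
  log10 WBC +0.6, hyperdiploid +1.0, protocol Total_XV −0.8, cluster
  contrasts `γ^(1) = (−0.8, +0.8)`; normal-tail algebra puts the
  day-15 censored fraction at ≈ 33%.
* Day-42 model: pure autoregression (`ρ = 1`, `β^(2) = γ^(2) = 0`) with
  `β0^(2) = −3.6`, `ρ0 = 1.41`, `σ²^(2) = 0.25`; this yields ≈ 85%
  day-42 censoring overall and makes day-15 censoring carry to day 42
  with probability ≈ 0.9993 per patient — monotonicity emerges from
  the intercept sitting 3.2 residual sd below the detection limit
  rather than from a structural constraint (a `strict_monotone` flag
  resamples the rare violators when exact monotonicity is needed).
* Mixture truth: three components along a global sensitivity axis
  dominated by prednisone and asparaginase,
  `μ = 0, ∓(2, 2, 1.2, 0.5, 0.5)`, within-component variance 0.2,
  weights (0.40, 0.35, 0.25); per-drug missing rates
  (20, 25, 30, 35, 39)%. Every drug carries some signal, so a patient
  missing the two most informative drugs remains classifiable — at
  these missing rates a mixture separated in only two coordinates
  would make a few percent of patients information-theoretically
  unclassifiable.

What passing tests on this cohort do **not** show about real data: the
generator's covariates are mutually independent (no subtype–WBC or
subtype–cluster association), missingness is MCAR, LC50 vectors are
exactly Gaussian within profile, and the day-42 block is exactly
autoregressive. Recovery results quantify the estimator under the
model's own assumptions, not robustness to their violation.

## Problem sizes used in checks

The recovery study runs 5 replicates at n = 800 with 3000 iterations
(1000 burn-in, thinning 2) and m = 100 imputations — sizes at which
credible-interval coverage of ρ, σ²^(t) and the nonzero effects, and
Binder-partition ARI ≈ 0.94, are stable; the full 15000-iteration
default is the recommended setting for a single analysis. One known
limitation surfaces here: with p = 16 covariates at n = 800 and
residual variance 1.2, a truly-zero coefficient's least-squares
estimate occasionally flukes to 2–3 standard errors (0.2–0.4 for rare
subtype dummies), and the horseshoe — whose heavy tails deliberately
protect signals of that size — passes such flukes through. Posterior
medians of null coefficients are therefore typically ≈ 0.03 but not
uniformly below 0.1 in every replicate; distinguishing a rare-subtype
fluke from a small true effect at this design is a property of the
data, not of the prior.

## Known limitations

* Pre-imputation of LC50 (see above) understates drug-sensitivity
  uncertainty.
* k = 3 is fixed by the elbow analysis, not inferred in-model.
* LC50 values estimated at the edge of the assayed concentration range
  are treated as exact, not censored.
* Rare subtypes are pooled rather than modelled hierarchically.
* Single-chain defaults; diagnostics (split-R-hat, Geyer ESS) accept
  multi-chain input for users who want between-chain evidence.
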