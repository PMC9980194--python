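# mrdjoint

Joint Bayesian modelling of serial minimal-residual-disease (MRD)
measurements and *ex vivo* drug-sensitivity profiles in pediatric acute
lymphoblastic leukemia (ALL).

## The problem

During induction chemotherapy for childhood ALL, MRD — the fraction of
residual leukemic cells in bone marrow — is measured on day 15 and at
the end of induction (day 42). Flow cytometry cannot quantify MRD below
0.01%, so roughly a third of day-15 values and most day-42 values are
*left-censored* at the detection limit. Alongside, each patient's
leukemic blasts are assayed *ex vivo* against a 5-drug panel
(asparaginase, prednisone, vincristine, 6-thioguanine,
6-mercaptopurine), yielding log10 LC50 sensitivity vectors with 20–40%
missing entries per drug.

`mrdjoint` is for biostatisticians who want to relate treatment response
(the censored MRD pair) to baseline covariates and to *latent
drug-sensitivity profiles* — clusters of patients with similar LC50
patterns — within one coherent posterior. Because patient-level trial
data of this kind are generally not public, the package ships a
first-class synthetic-cohort generator that reproduces the statistical
structure of such a trial (skewed subtype frequencies, three protocol
arms, censoring rates, missingness) with known ground truth, so every
part of the machinery is testable end to end.

## The model

Let `Z_i = (Z_i^(1), Z_i^(2))` be log10 MRD (percent scale) at days 15
and 42, censored at `z_low = log10(0.01) = −2` with detection indicators
`δ_i^(t)`. Each observed value contributes a normal density, each
censored value the normal mass below `z_low`:

    L = ∏_t ∏_i f(z_i^(t))^{δ_i^(t)} · F^(t)(z_low)^{1 − δ_i^(t)}

with a conditionally autoregressive mean structure gated on day-15
detection:

    Z_i^(t) ~ N(μ_i^(t), σ²^(t)),   t = 1, 2
    μ_i^(1) = β0^(1) + β^(1)·X_i + γ^(1)·c_i
    μ_i^(2) = β0^(2) + δ_i^(1) (ρ0 + ρ Z_i^(1) + β^(2)·X_i + γ^(2)·c_i)

`X_i` collects age, gender, log10 WBC, 11 subtype dummies (reference
ETV6-RUNX1) and 2 protocol dummies (p = 16). Patients censored on day 15
are almost surely censored on day 42; the gate makes the two timepoints
conditionally independent for exactly those patients, so the
autoregressive and covariate effects at day 42 are estimated only from
patients with detectable day-15 disease.

The coefficient blocks `β^(t)`, `γ^(t)` carry horseshoe priors
(local–global half-Cauchy scales) for continuous variable selection;
`ρ0, ρ ~ N(0,1)`; all variances are Inv-Gamma(3, 2).

`c_i ∈ {1,2,3}` is the patient's latent drug-sensitivity profile, dummy
coded into the regression, and modelled by a finite Gaussian mixture
over the (standardized, imputed) LC50 vectors:

    Ỹ_i ~ Σ_j w_j N_5(μ_j, Σ_j),   w ~ Dir(1/3, 1/3, 1/3),
    μ_j ~ N_5(0, I)

Both blocks are estimated **jointly** by a native Gibbs sampler:
censored MRD values are imputed within the chain from truncated
normals, and the allocation update for `c_i` combines the mixture
responsibility with the patient's MRD likelihood. Missing LC50 entries
are handled before the fit by chained-equation multiple imputation
(m = 100 completions), a k-means elbow over the completions confirms
k = 3, and the completion with the lowest within-cluster sum of squares
at k = 3 is carried into the model. Clustering point estimates minimize
Binder's loss against the posterior similarity matrix.

## Worked example

`examples/fit_joint_model.py` simulates a 400-patient cohort, imputes
the LC50 panel, and runs a short chain:

```
rho (day-15 -> day-42 autoregression): median 1.00, IQR 0.94-1.04
   (simulated truth: 1.0)
sigma2 day 15: 1.08 (truth 1.2)
sigma2 day 42: 0.22 (truth 0.25)

day-15 effects whose 95% credible interval excludes zero:
                 parameter    median    ci_low   ci_high
           beta1_log10_wbc  0.672234  0.504903  0.844067
beta1_subtype_Hyperdiploid  1.087096  0.847846  1.357423
   beta1_protocol_Total_XV -0.634552 -0.913343 -0.337762
           gamma1_Cluster2 -0.860127 -1.113134 -0.586138
           gamma1_Cluster3  0.822881  0.544900  1.130721

worst split-R-hat across 65 scalar parameters: 1.012
```

The posterior median of ρ near 1 says day-42 log MRD tracks day-15 log
MRD one-for-one among patients with detectable day-15 disease. The
credible-interval selection recovers exactly the covariates simulated
with nonzero effects — higher white-cell count, the hyperdiploid
subtype and one protocol arm shift day-15 MRD — plus the two
drug-sensitivity cluster contrasts (cluster 2 lower, cluster 3 higher
day-15 MRD than the reference cluster). The other examples cover cohort
simulation (`simulate_cohort.py`), the imputation/elbow analysis
(`impute_and_elbow.py`), and Binder partitioning with per-cluster
profiles (`cluster_partition.py`).

The full pipeline — simulate or load a cohort CSV, impute, select,
fit, summarize, with all artifacts written to disk — is one call:

```python
from mrdjoint import RunConfig, SimConfig, MCMCConfig, run_pipeline
run_pipeline(RunConfig(outdir="out", sim=SimConfig(seed=1),
                       mcmc=MCMCConfig(n_iter=15000, burn_in=5000, thin=2)))
```

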