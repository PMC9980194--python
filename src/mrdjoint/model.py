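"""Exact log-density computations for the joint model.

Three building blocks:

* the left-censored two-timepoint MRD likelihood — an observed value
  contributes a normal density term, a censored value the normal CDF
  mass below the detection limit ``z_low``;
* the finite Gaussian mixture likelihood over completed LC50 vectors,
  in both allocated (conditional on labels) and collapsed
  (label-marginalized) form;
* the joint prior: horseshoe hierarchy on the regression blocks,
  standard-normal priors on the autoregressive coefficients,
  Inv-Gamma(3, 2) on all variances, N(0, 10^2) on intercepts,
  Dirichlet(1/3, 1/3, 1/3) on the weights and N_5(0, I) on the
  component means.

All functions are pure and vectorized over patients; they are the single
source of truth that the Gibbs sampler's full conditionals are tested
against.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, log_ndtr

from .datatypes import (
    CLUSTER_DUMMY,
    N_CLUSTERS,
    N_DRUGS,
    Allocations,
    CovariateTable,
    HorseshoeState,
    MixtureParams,
    MRDObservations,
    RegressionParams,
)

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: prior standard deviation of the intercepts b0^(t)
INTERCEPT_PRIOR_SD = 10.0
#: Inv-Gamma shape/rate shared by all variance priors
IG_SHAPE, IG_RATE = 3.0, 2.0


def mean_mrd(
    params: RegressionParams,
    X_i: np.ndarray,
    c_i: int,
    z1_i: float | None,
    delta1_i: int,
    t: int,
) -> float:
    """Conditional mean of the log10 MRD value for one patient at time t.

    For ``t = 2`` the autoregressive/regression block is gated by the
    day-15 detection indicator: if ``delta1_i = 0`` the mean is exactly
    the day-42 intercept, independent of covariates, cluster and rho.
    ``z1_i`` must be the current (possibly MCMC-imputed) day-15 value
    when ``t = 2`` and ``delta1_i = 1``.
    """
    c_dummy = CLUSTER_DUMMY[int(c_i) - 1]
    if t == 1:
        return float(params.b0_1 + X_i @ params.beta1 + c_dummy @ params.gamma1)
    if t == 2:
        if delta1_i == 0:
            return float(params.b0_2)
        return float(
            params.b0_2
            + params.rho0
            + params.rho * z1_i
            + X_i @ params.beta2
            + c_dummy @ params.gamma2
        )
    raise ValueError("t must be 1 or 2")


def mean_vectors(
    params: RegressionParams,
    X: np.ndarray,
    C: np.ndarray,
    z1: np.ndarray,
    delta1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (mu1, mu2) for a whole cohort.

    ``C`` is the n x 2 cluster dummy matrix and ``z1`` the current
    day-15 values (observed or imputed; the gate zeroes the imputed ones
    out of mu2 anyway).
    """
    mu1 = params.b0_1 + X @ params.beta1 + C @ params.gamma1
    ar = params.rho0 + params.rho * z1 + X @ params.beta2 + C @ params.gamma2
    mu2 = params.b0_2 + delta1 * ar
    return mu1, mu2


def _censored_normal_loglik(
    z: np.ndarray, delta: np.ndarray, mu: np.ndarray, sigma2: float, z_low: float
) -> float:
    """Sum of delta * log phi + (1 - delta) * log Phi terms for one timepoint."""
    if sigma2 <= 0:
        raise ValueError("observation variance must be positive")
    sd = np.sqrt(sigma2)
    dens = -LOG_SQRT_2PI - np.log(sd) - 0.5 * ((z - mu) / sd) ** 2
    cens = log_ndtr((z_low - mu) / sd)
    return float(np.sum(delta * dens + (1 - delta) * cens))


def loglik_mrd(
    params: RegressionParams,
    covariates: CovariateTable,
    mrd: MRDObservations,
    alloc: Allocations,
) -> float:
    """Censored log-likelihood of the MRD pair, summed over patients and times.

    Observed entries (delta = 1) contribute normal log-densities at the
    stored value; censored entries contribute log Phi((z_low - mu)/sigma).
    The day-42 mean uses the *observed* day-15 value inside the gate,
    which is only active for delta1 = 1 patients.
    """
    X = covariates.design_matrix()
    C = alloc.dummies()
    mu1, mu2 = mean_vectors(params, X, C, mrd.z1, mrd.delta1)
    out = _censored_normal_loglik(mrd.z1, mrd.delta1, mu1, params.sigma2_1, mrd.z_low)
    out += _censored_normal_loglik(mrd.z2, mrd.delta2, mu2, params.sigma2_2, mrd.z_low)
    return out


def _component_logpdfs(mix: MixtureParams, Y: np.ndarray) -> np.ndarray:
    """n x 3 matrix of log N_5(Y_i; mu_j, Sigma_j) values."""
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[1] != N_DRUGS:
        raise ValueError(f"Y must be n x {N_DRUGS}")
    sd = mix.component_sd_matrix()  # 3 x 5
    diff = Y[:, None, :] - mix.mu[None, :, :]  # n x 3 x 5
    quad = ((diff / sd[None, :, :]) ** 2).sum(axis=2)
    logdet = np.log(sd).sum(axis=1) * 2.0
    return -N_DRUGS * LOG_SQRT_2PI - 0.5 * logdet[None, :] - 0.5 * quad


def loglik_mixture(mix: MixtureParams, alloc: Allocations, Y: np.ndarray) -> float:
    """Allocated mixture log-likelihood: sum_i log w_{c_i} + log N_5(Y_i; ...).

    Returns ``-inf`` when an occupied component has zero weight.
    """
    logpdf = _component_logpdfs(mix, Y)
    with np.errstate(divide="ignore"):
        logw = np.log(mix.w)
    terms = logw[alloc.labels - 1] + logpdf[np.arange(len(Y)), alloc.labels - 1]
    return float(np.sum(terms))


def loglik_mixture_collapsed(mix: MixtureParams, Y: np.ndarray) -> float:
    """Label-marginalized mixture log-likelihood via per-row log-sum-exp."""
    logpdf = _component_logpdfs(mix, Y)
    with np.errstate(divide="ignore"):
        logw = np.log(mix.w)
    a = logw[None, :] + logpdf
    m = a.max(axis=1)
    return float(np.sum(m + np.log(np.exp(a - m[:, None]).sum(axis=1))))


def log_invgamma(x: float | np.ndarray, a: float = IG_SHAPE, b: float = IG_RATE) -> np.ndarray:
    """Inv-Gamma(a, b) log-density, b the rate (mean b/(a-1))."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("Inv-Gamma support is x > 0")
    return a * np.log(b) - gammaln(a) - (a + 1) * np.log(x) - b / x


def log_half_cauchy(x: float | np.ndarray) -> np.ndarray:
    """half-Cauchy(0, 1) log-density on x > 0: log(2/pi) - log(1 + x^2)."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("half-Cauchy support is x > 0")
    return np.log(2.0 / np.pi) - np.log1p(x**2)


def _log_normal(x: np.ndarray, sd: np.ndarray | float) -> np.ndarray:
    return -LOG_SQRT_2PI - np.log(sd) - 0.5 * (np.asarray(x, float) / sd) ** 2


def log_prior(params: RegressionParams, hs: HorseshoeState, mix: MixtureParams) -> float:
    """Joint log-prior over regression, horseshoe and mixture parameters.

    The horseshoe contributes, per block: N(0, lambda_j^2 tau^2) on each
    coefficient, half-Cauchy(0,1) on each local scale and on the global
    scale.  (The inverse-gamma auxiliaries used by the sampler are a
    reparameterization of the same hierarchy and do not appear here.)
    """
    out = 0.0
    coef_blocks = {
        "beta1": params.beta1,
        "gamma1": params.gamma1,
        "beta2": params.beta2,
        "gamma2": params.gamma2,
    }
    for name, block in hs.blocks().items():
        coef = coef_blocks[name]
        out += float(np.sum(_log_normal(coef, block.lam * block.tau)))
        out += float(np.sum(log_half_cauchy(block.lam)))
        out += float(log_half_cauchy(block.tau))
    out += float(_log_normal(np.array(params.rho0), 1.0))
    out += float(_log_normal(np.array(params.rho), 1.0))
    out += float(_log_normal(np.array(params.b0_1), INTERCEPT_PRIOR_SD))
    out += float(_log_normal(np.array(params.b0_2), INTERCEPT_PRIOR_SD))
    out += float(log_invgamma(params.sigma2_1) + log_invgamma(params.sigma2_2))
    # mixture block
    a = mix.alpha
    out += float(gammaln(a.sum()) - gammaln(a).sum() + np.sum((a - 1) * np.log(mix.w)))
    out += float(np.sum(_log_normal(mix.mu, 1.0)))
    out += float(np.sum(log_invgamma(mix.sigma2)))
    return out


def log_joint(
    params: RegressionParams,
    hs: HorseshoeState,
    mix: MixtureParams,
    alloc: Allocations,
    covariates: CovariateTable,
    mrd: MRDObservations,
    Y: np.ndarray,
) -> float:
    """Unnormalized log posterior: MRD likelihood + mixture likelihood + prior."""
    return (
        loglik_mrd(params, covariates, mrd, alloc)
        + loglik_mixture(mix, alloc, Y)
        + log_prior(params, hs, mix)
    )
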