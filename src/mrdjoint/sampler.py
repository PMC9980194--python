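"""Native Gibbs sampler for the joint MRD / drug-sensitivity posterior.

After two augmentations the model is fully conjugate, so every update is
an exact draw from its full conditional:

* censored MRD values are imputed from normals truncated above at the
  detection limit ``z_low`` (data augmentation for the CDF terms of the
  likelihood);
* horseshoe scales use the inverse-gamma auxiliary representation of the
  half-Cauchy hierarchy, making local and global scale updates
  inverse-gamma draws.

Each sweep updates, in order: censored values, allocations (jointly
informed by the mixture and both MRD timepoints), mixture parameters,
regression coefficients (two blockwise multivariate-normal draws),
observation variances, and horseshoe scales.  The sampler is a pure
function of (data, config): two runs with the same seed produce
identical retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri
from sklearn.cluster import KMeans

from .datatypes import (
    CLUSTER_DUMMY,
    N_CLUSTERS,
    N_DRUGS,
    Allocations,
    CovariateTable,
    HorseshoeBlock,
    HorseshoeState,
    MixtureParams,
    MRDObservations,
    RegressionParams,
)
from .model import (
    IG_RATE,
    IG_SHAPE,
    INTERCEPT_PRIOR_SD,
    LOG_SQRT_2PI,
    _component_logpdfs,
    log_joint,
    mean_vectors,
)

_SCALE2_MIN, _SCALE2_MAX = 1e-16, 1e16  # numerical bounds for squared HS scales


@dataclass
class MCMCConfig:
    """Chain length and bookkeeping.

    Defaults: 15000 iterations, the first 5000 discarded as burn-in,
    thinning every two, which retains (15000 - 5000) / 2 = 5000 draws.
    """

    n_iter: int = 15000
    burn_in: int = 5000
    thin: int = 2
    seed: int = 0
    init: str = "kmeans-ridge"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")

    @property
    def n_retained(self) -> int:
        return int(np.ceil((self.n_iter - self.burn_in) / self.thin))


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of every parameter plus imputed values."""

    config: MCMCConfig
    coef_names: list[str]
    b0_1: np.ndarray
    b0_2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    gamma1: np.ndarray
    gamma2: np.ndarray
    rho0: np.ndarray
    rho: np.ndarray
    sigma2_1: np.ndarray
    sigma2_2: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    mix_sigma2: np.ndarray
    alloc: np.ndarray
    z1_imputed: np.ndarray  # draws x n_censored_day15
    z2_imputed: np.ndarray
    cens1_idx: np.ndarray
    cens2_idx: np.ndarray
    draw_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_draws(self) -> int:
        return len(self.rho)

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a named draw vector."""
        out = {
            "b0_1": self.b0_1,
            "b0_2": self.b0_2,
            "rho0": self.rho0,
            "rho": self.rho,
            "sigma2_1": self.sigma2_1,
            "sigma2_2": self.sigma2_2,
        }
        for j, name in enumerate(self.coef_names):
            out[f"beta1_{name}"] = self.beta1[:, j]
            out[f"beta2_{name}"] = self.beta2[:, j]
        for j, cl in enumerate(("Cluster2", "Cluster3")):
            out[f"gamma1_{cl}"] = self.gamma1[:, j]
            out[f"gamma2_{cl}"] = self.gamma2[:, j]
        for j in range(N_CLUSTERS):
            out[f"w_{j + 1}"] = self.w[:, j]
        for j in range(self.mix_sigma2.shape[1]):
            out[f"mix_sigma2_{j + 1}"] = self.mix_sigma2[:, j]
        for j in range(N_CLUSTERS):
            for d in range(N_DRUGS):
                out[f"mu_{j + 1}_{d + 1}"] = self.mu[:, j, d]
        return out

    def to_long_dataframe(self):
        """Long-format (draw, parameter, value) table of the scalar draws."""
        import pandas as pd

        frames = []
        for name, vals in self.scalar_draws().items():
            frames.append(
                pd.DataFrame(
                    {"draw": np.arange(len(vals)), "parameter": name, "value": vals}
                )
            )
        return pd.concat(frames, ignore_index=True)


def truncated_normal_below(
    rng: np.random.Generator,
    mu: np.ndarray,
    sd: np.ndarray | float,
    upper: float,
) -> np.ndarray:
    """Draws from N(mu, sd^2) truncated to (-inf, upper].

    Inverse-CDF in the bulk; for extreme bounds (standardized bound
    below -30, where the CDF underflows) a Robert-style exponential
    rejection sampler on the tail.
    """
    mu = np.asarray(mu, float)
    sd = np.broadcast_to(np.asarray(sd, float), mu.shape)
    alpha = (upper - mu) / sd
    out = np.empty_like(mu)
    bulk = alpha > -30.0
    if np.any(bulk):
        u = rng.random(bulk.sum())
        p = ndtr(alpha[bulk])
        out[bulk] = mu[bulk] + sd[bulk] * ndtri(u * p)
    tail = ~bulk
    if np.any(tail):
        t = -alpha[tail]  # large positive
        x = np.empty(t.shape)
        todo = np.ones(t.shape, bool)
        while np.any(todo):
            k = todo.sum()
            prop = t[todo] - np.log(rng.random(k)) / t[todo]
            acc = rng.random(k) < np.exp(-0.5 * (prop - t[todo]) ** 2)
            idx = np.where(todo)[0][acc]
            x[idx] = prop[acc]
            todo[idx] = False
        out[tail] = mu[tail] - sd[tail] * x
    return np.minimum(out, upper)


def update_censored(
    rng: np.random.Generator,
    params: RegressionParams,
    X: np.ndarray,
    C: np.ndarray,
    mrd: MRDObservations,
    z1_cur: np.ndarray,
    z2_cur: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute censored MRD values from their truncated-normal conditionals.

    Day-15 imputed values never feed the day-42 mean: the delta1 = 0
    gate zeroes the autoregressive block for exactly those patients, so
    their day-42 conditional mean is the bare intercept.
    """
    z1 = z1_cur.copy()
    z2 = z2_cur.copy()
    mu1, mu2 = mean_vectors(params, X, C, z1, mrd.delta1)
    c1 = mrd.delta1 == 0
    if np.any(c1):
        z1[c1] = truncated_normal_below(
            rng, mu1[c1], np.sqrt(params.sigma2_1), mrd.z_low
        )
    c2 = mrd.delta2 == 0
    if np.any(c2):
        z2[c2] = truncated_normal_below(
            rng, mu2[c2], np.sqrt(params.sigma2_2), mrd.z_low
        )
    return z1, z2


def allocation_log_conditional(
    params: RegressionParams,
    mix: MixtureParams,
    X: np.ndarray,
    mrd: MRDObservations,
    z1_cur: np.ndarray,
    z2_cur: np.ndarray,
    Y: np.ndarray,
) -> np.ndarray:
    """n x 3 unnormalized log full-conditional of each allocation.

    Combines the mixture responsibility (log w_j + log N_5) with the MRD
    likelihood evaluated at the current (imputed-complete) values under
    each candidate cluster; the day-42 factor is gated by delta1.
    """
    n = len(z1_cur)
    with np.errstate(divide="ignore"):
        logw = np.log(mix.w)
    logits = logw[None, :] + _component_logpdfs(mix, Y)
    sd1 = np.sqrt(params.sigma2_1)
    sd2 = np.sqrt(params.sigma2_2)
    base1 = params.b0_1 + X @ params.beta1
    ar_base = params.rho0 + params.rho * z1_cur + X @ params.beta2
    for j in range(N_CLUSTERS):
        cd = CLUSTER_DUMMY[j]
        mu1 = base1 + cd @ params.gamma1
        mu2 = params.b0_2 + mrd.delta1 * (ar_base + cd @ params.gamma2)
        logits[:, j] += -LOG_SQRT_2PI - np.log(sd1) - 0.5 * ((z1_cur - mu1) / sd1) ** 2
        logits[:, j] += -LOG_SQRT_2PI - np.log(sd2) - 0.5 * ((z2_cur - mu2) / sd2) ** 2
    return logits


def update_allocations(
    rng: np.random.Generator,
    params: RegressionParams,
    mix: MixtureParams,
    X: np.ndarray,
    mrd: MRDObservations,
    z1_cur: np.ndarray,
    z2_cur: np.ndarray,
    Y: np.ndarray,
) -> Allocations:
    """Sample every c_i from its categorical full conditional (log-space)."""
    logits = allocation_log_conditional(params, mix, X, mrd, z1_cur, z2_cur, Y)
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random((len(probs), 1))
    labels = 1 + (u > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    return Allocations(labels=labels)


def _draw_invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def update_mixture(
    rng: np.random.Generator, mix: MixtureParams, alloc: Allocations, Y: np.ndarray
) -> MixtureParams:
    """Conjugate draws of (w, mu_j, sigma_j^2) given allocations.

    Empty components draw their parameters from the prior.  In
    ``diag_shared`` mode the five per-drug variances pool residuals
    across components.
    """
    labels = alloc.labels
    counts = alloc.counts().astype(float)
    w = rng.dirichlet(mix.alpha + counts)

    mu = np.empty_like(mix.mu)
    if mix.cov_mode == "isotropic":
        for j in range(N_CLUSTERS):
            members = labels == j + 1
            nj = counts[j]
            if nj > 0:
                prec = 1.0 + nj / mix.sigma2[j]
                mean = Y[members].sum(axis=0) / mix.sigma2[j] / prec
            else:
                prec, mean = 1.0, np.zeros(N_DRUGS)
            mu[j] = mean + rng.standard_normal(N_DRUGS) / np.sqrt(prec)
        sigma2 = np.empty(N_CLUSTERS)
        for j in range(N_CLUSTERS):
            members = labels == j + 1
            nj = counts[j]
            ss = float(((Y[members] - mu[j]) ** 2).sum()) if nj > 0 else 0.0
            sigma2[j] = _draw_invgamma(
                rng, IG_SHAPE + nj * N_DRUGS / 2.0, IG_RATE + 0.5 * ss
            )
    else:  # diag_shared
        for j in range(N_CLUSTERS):
            members = labels == j + 1
            nj = counts[j]
            if nj > 0:
                prec = 1.0 + nj / mix.sigma2
                mean = Y[members].sum(axis=0) / mix.sigma2 / prec
            else:
                prec, mean = np.ones(N_DRUGS), np.zeros(N_DRUGS)
            mu[j] = mean + rng.standard_normal(N_DRUGS) / np.sqrt(prec)
        resid2 = (Y - mu[labels - 1]) ** 2
        sigma2 = np.array(
            [
                _draw_invgamma(rng, IG_SHAPE + len(Y) / 2.0, IG_RATE + 0.5 * resid2[:, d].sum())
                for d in range(N_DRUGS)
            ]
        )
    return MixtureParams(w=w, mu=mu, sigma2=sigma2, alpha=mix.alpha, cov_mode=mix.cov_mode)


def _draw_mvn_coefficients(
    rng: np.random.Generator,
    D: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    prior_prec: np.ndarray,
) -> np.ndarray:
    """Draw from N((D'D/s2 + P)^-1 D'y/s2, (D'D/s2 + P)^-1), jittering if singular."""
    A = D.T @ D / sigma2 + np.diag(prior_prec)
    b = D.T @ y / sigma2
    jitter = 0.0
    for _ in range(6):
        try:
            cf = cho_factor(A + jitter * np.eye(len(A)), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
    else:  # pragma: no cover - pathological conditioning
        raise np.linalg.LinAlgError("conditional precision not positive definite")
    mean = cho_solve(cf, b)
    z = rng.standard_normal(len(A))
    return mean + solve_triangular(cf[0], z, lower=True, trans="T")


def update_regression(
    rng: np.random.Generator,
    params: RegressionParams,
    hs: HorseshoeState,
    X: np.ndarray,
    C: np.ndarray,
    mrd: MRDObservations,
    z1_cur: np.ndarray,
    z2_cur: np.ndarray,
) -> RegressionParams:
    """Blockwise conjugate draws of all regression parameters.

    Day-15 block: (b0_1, beta1, gamma1) jointly multivariate normal on
    the imputed-complete responses.  Day-42 block: (b0_2, rho0, rho,
    beta2, gamma2) jointly, on the gated design [1, d1, d1*z1, d1*X,
    d1*C] — censored-at-day-15 rows inform only the intercept.  Each
    variance then draws from Inv-Gamma(3 + n/2, 2 + RSS/2).
    """
    p = X.shape[1]
    n = len(z1_cur)
    one = np.ones((n, 1))

    D1 = np.hstack([one, X, C])
    prior1 = np.concatenate(
        [
            [1.0 / INTERCEPT_PRIOR_SD**2],
            1.0 / np.clip((hs.beta1.lam * hs.beta1.tau) ** 2, _SCALE2_MIN, _SCALE2_MAX),
            1.0 / np.clip((hs.gamma1.lam * hs.gamma1.tau) ** 2, _SCALE2_MIN, _SCALE2_MAX),
        ]
    )
    th1 = _draw_mvn_coefficients(rng, D1, z1_cur, params.sigma2_1, prior1)
    b0_1, beta1, gamma1 = th1[0], th1[1 : 1 + p], th1[1 + p :]
    rss1 = float(np.sum((z1_cur - D1 @ th1) ** 2))
    sigma2_1 = _draw_invgamma(rng, IG_SHAPE + n / 2.0, IG_RATE + 0.5 * rss1)

    d1 = mrd.delta1.astype(float)[:, None]
    # day-15 values feeding the AR term are the observed ones; gated rows
    # carry zeros so imputed day-15 draws never leak into the day-42 block
    D2 = np.hstack([one, d1, d1 * z1_cur[:, None], d1 * X, d1 * C])
    prior2 = np.concatenate(
        [
            [1.0 / INTERCEPT_PRIOR_SD**2],
            [1.0, 1.0],  # rho0, rho ~ N(0, 1)
            1.0 / np.clip((hs.beta2.lam * hs.beta2.tau) ** 2, _SCALE2_MIN, _SCALE2_MAX),
            1.0 / np.clip((hs.gamma2.lam * hs.gamma2.tau) ** 2, _SCALE2_MIN, _SCALE2_MAX),
        ]
    )
    th2 = _draw_mvn_coefficients(rng, D2, z2_cur, params.sigma2_2, prior2)
    b0_2, rho0, rho = th2[0], th2[1], th2[2]
    beta2, gamma2 = th2[3 : 3 + p], th2[3 + p :]
    rss2 = float(np.sum((z2_cur - D2 @ th2) ** 2))
    sigma2_2 = _draw_invgamma(rng, IG_SHAPE + n / 2.0, IG_RATE + 0.5 * rss2)

    return RegressionParams(
        b0_1=float(b0_1),
        b0_2=float(b0_2),
        beta1=beta1,
        beta2=beta2,
        gamma1=gamma1,
        gamma2=gamma2,
        rho0=float(rho0),
        rho=float(rho),
        sigma2_1=sigma2_1,
        sigma2_2=sigma2_2,
    )


def _update_hs_block(
    rng: np.random.Generator, block: HorseshoeBlock, coef: np.ndarray
) -> HorseshoeBlock:
    """Inverse-gamma auxiliary sweep for one horseshoe block."""
    p = len(coef)
    tau2 = float(np.clip(block.tau**2, _SCALE2_MIN, _SCALE2_MAX))
    nu = block.nu
    lam2 = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / nu + coef**2 / (2.0 * tau2)))
    lam2 = np.clip(lam2, _SCALE2_MIN, _SCALE2_MAX)
    nu = 1.0 / rng.gamma(1.0, 1.0 / (1.0 + 1.0 / lam2))
    tau2 = 1.0 / rng.gamma(
        (p + 1) / 2.0, 1.0 / (1.0 / block.xi + float(np.sum(coef**2 / lam2)) / 2.0)
    )
    tau2 = float(np.clip(tau2, _SCALE2_MIN, _SCALE2_MAX))
    xi = float(1.0 / rng.gamma(1.0, 1.0 / (1.0 + 1.0 / tau2)))
    return HorseshoeBlock(lam=np.sqrt(lam2), tau=float(np.sqrt(tau2)), nu=nu, xi=xi)


def update_horseshoe(
    rng: np.random.Generator, hs: HorseshoeState, params: RegressionParams
) -> HorseshoeState:
    """Update the four shrinkage blocks given their current coefficients."""
    return HorseshoeState(
        beta1=_update_hs_block(rng, hs.beta1, params.beta1),
        gamma1=_update_hs_block(rng, hs.gamma1, params.gamma1),
        beta2=_update_hs_block(rng, hs.beta2, params.beta2),
        gamma2=_update_hs_block(rng, hs.gamma2, params.gamma2),
    )


def _ridge_fit(D: np.ndarray, y: np.ndarray, penalty: float = 1.0) -> np.ndarray:
    return np.linalg.solve(D.T @ D + penalty * np.eye(D.shape[1]), D.T @ y)


def initialize_state(
    covariates: CovariateTable,
    mrd: MRDObservations,
    Y: np.ndarray,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
    cov_mode: str = "diag_shared",
) -> tuple[RegressionParams, HorseshoeState, MixtureParams, Allocations]:
    """Warm start: ridge regression on threshold-imputed data, k-means labels.

    Censored responses are set at the detection limit for the ridge fit;
    allocations come from k-means on the completed LC50 matrix unless
    explicit labels are supplied; horseshoe scales start at 1.
    """
    X = covariates.design_matrix()
    n, p = X.shape
    if init_labels is None:
        km = KMeans(n_clusters=N_CLUSTERS, n_init=10, random_state=seed % (2**31)).fit(Y)
        labels = km.labels_ + 1
    else:
        labels = np.asarray(init_labels, int)
    alloc = Allocations(labels=labels)
    C = alloc.dummies()

    one = np.ones((n, 1))
    D1 = np.hstack([one, X, C])
    th1 = _ridge_fit(D1, mrd.z1)
    s2_1 = max(float(np.var(mrd.z1 - D1 @ th1)), 1e-3)
    d1 = mrd.delta1.astype(float)[:, None]
    D2 = np.hstack([one, d1, d1 * mrd.z1[:, None], d1 * X, d1 * C])
    th2 = _ridge_fit(D2, mrd.z2)
    s2_2 = max(float(np.var(mrd.z2 - D2 @ th2)), 1e-3)
    params = RegressionParams(
        b0_1=float(th1[0]),
        b0_2=float(th2[0]),
        beta1=th1[1 : 1 + p],
        beta2=th2[3 : 3 + p],
        gamma1=th1[1 + p :],
        gamma2=th2[3 + p :],
        rho0=float(th2[1]),
        rho=float(th2[2]),
        sigma2_1=s2_1,
        sigma2_2=s2_2,
    )

    counts = alloc.counts().astype(float)
    w = counts / counts.sum()
    mu = np.vstack([
        Y[labels == j + 1].mean(axis=0) if counts[j] else np.zeros(N_DRUGS)
        for j in range(N_CLUSTERS)
    ])
    resid2 = (Y - mu[labels - 1]) ** 2
    if cov_mode == "isotropic":
        sigma2 = np.array(
            [
                max(float(resid2[labels == j + 1].mean()), 1e-3) if counts[j] else 1.0
                for j in range(N_CLUSTERS)
            ]
        )
    else:
        sigma2 = np.maximum(resid2.mean(axis=0), 1e-3)
    mix = MixtureParams(w=w, mu=mu, sigma2=sigma2, cov_mode=cov_mode)
    return params, HorseshoeState.ones(p), mix, alloc


def run_mcmc(
    covariates: CovariateTable,
    mrd: MRDObservations,
    Y: np.ndarray,
    config: MCMCConfig | None = None,
    init_labels: np.ndarray | None = None,
    cov_mode: str = "diag_shared",
) -> PosteriorSamples:
    """Run the Gibbs sampler and return thinned post-burn-in draws.

    ``Y`` must be a complete (imputed, typically standardized) n x 5
    LC50 matrix.  Raises ``RuntimeError`` if the joint log-density is
    non-finite at any retained draw.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    X = covariates.design_matrix()
    Y = np.asarray(Y, float)
    n, p = X.shape
    if Y.shape != (n, N_DRUGS) or np.any(~np.isfinite(Y)):
        raise ValueError(f"Y must be a complete {n} x {N_DRUGS} matrix")

    params, hs, mix, alloc = initialize_state(
        covariates, mrd, Y, seed=config.seed, init_labels=init_labels, cov_mode=cov_mode
    )
    z1 = mrd.z1.copy()
    z2 = mrd.z2.copy()
    cens1 = np.where(mrd.delta1 == 0)[0]
    cens2 = np.where(mrd.delta2 == 0)[0]

    n_keep = config.n_retained
    coef_names = covariates.design_columns
    n_mix_var = N_CLUSTERS if cov_mode == "isotropic" else N_DRUGS
    store = PosteriorSamples(
        config=config,
        coef_names=coef_names,
        b0_1=np.empty(n_keep),
        b0_2=np.empty(n_keep),
        beta1=np.empty((n_keep, p)),
        beta2=np.empty((n_keep, p)),
        gamma1=np.empty((n_keep, N_CLUSTERS - 1)),
        gamma2=np.empty((n_keep, N_CLUSTERS - 1)),
        rho0=np.empty(n_keep),
        rho=np.empty(n_keep),
        sigma2_1=np.empty(n_keep),
        sigma2_2=np.empty(n_keep),
        w=np.empty((n_keep, N_CLUSTERS)),
        mu=np.empty((n_keep, N_CLUSTERS, N_DRUGS)),
        mix_sigma2=np.empty((n_keep, n_mix_var)),
        alloc=np.empty((n_keep, n), np.int8),
        z1_imputed=np.empty((n_keep, len(cens1))),
        z2_imputed=np.empty((n_keep, len(cens2))),
        cens1_idx=cens1,
        cens2_idx=cens2,
        draw_index=np.empty(n_keep, int),
    )

    kept = 0
    for it in range(config.n_iter):
        C = alloc.dummies()
        z1, z2 = update_censored(rng, params, X, C, mrd, z1, z2)
        alloc = update_allocations(rng, params, mix, X, mrd, z1, z2, Y)
        C = alloc.dummies()
        mix = update_mixture(rng, mix, alloc, Y)
        params = update_regression(rng, params, hs, X, C, mrd, z1, z2)
        hs = update_horseshoe(rng, hs, params)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            lj = log_joint(params, hs, mix, alloc, covariates, mrd, Y)
            if not np.isfinite(lj):
                raise RuntimeError(
                    f"non-finite log joint at iteration {it}: "
                    f"sigma2=({params.sigma2_1}, {params.sigma2_2}), w={mix.w}"
                )
            store.b0_1[kept] = params.b0_1
            store.b0_2[kept] = params.b0_2
            store.beta1[kept] = params.beta1
            store.beta2[kept] = params.beta2
            store.gamma1[kept] = params.gamma1
            store.gamma2[kept] = params.gamma2
            store.rho0[kept] = params.rho0
            store.rho[kept] = params.rho
            store.sigma2_1[kept] = params.sigma2_1
            store.sigma2_2[kept] = params.sigma2_2
            store.w[kept] = mix.w
            store.mu[kept] = mix.mu
            store.mix_sigma2[kept] = mix.sigma2
            store.alloc[kept] = alloc.labels
            store.z1_imputed[kept] = z1[cens1]
            store.z2_imputed[kept] = z2[cens2]
            store.draw_index[kept] = it
            kept += 1
    return store
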