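"""Multiple imputation of the LC50 matrix and k-means elbow analysis.

The drug-sensitivity panel has per-drug missing rates around 20-40%, so
the analysis proceeds on multiply-imputed completions: chained equations
with a Bayesian normal linear regression per column (coefficients and
residual variance drawn from their posterior under a vague prior, so
imputations carry parameter uncertainty, not just residual noise).
Each completed matrix is clustered with k-means over a grid of k; the
within-cluster sum of squares (WSS) curves, averaged over imputations,
locate the elbow, and the completion with the lowest WSS at the chosen k
is selected for the joint model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import DrugSensitivityMatrix


@dataclass
class ImputationSet:
    """M completed copies of one partially observed matrix."""

    completed: list[np.ndarray]
    method: str
    seed: int

    @property
    def m(self) -> int:
        return len(self.completed)


@dataclass
class WSSCurve:
    """Within-cluster sum-of-squares curves per imputation, plus their mean."""

    k_values: np.ndarray
    per_imputation_wss: np.ndarray  # M x len(k_values)
    mean_wss: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, int)
        self.per_imputation_wss = np.asarray(self.per_imputation_wss, float)
        self.mean_wss = np.asarray(self.mean_wss, float)


def _draw_regression_imputation(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One posterior-predictive draw for the missing entries of a column.

    Bayesian normal linear regression with the vague prior
    p(beta, sigma^2) ~ 1/sigma^2: draw sigma^2 from its scaled
    inverse-chi^2 posterior, beta from N(beta_hat, sigma^2 (X'X)^-1),
    then the missing values from the predictive normal.  A small ridge
    keeps the cross-product invertible for collinear columns.
    """
    n, q = X_obs.shape
    ridge = 1e-8 * np.eye(q)
    xtx = X_obs.T @ X_obs + ridge
    beta_hat = np.linalg.solve(xtx, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    df = max(n - q, 1)
    s2 = float(resid @ resid) / df
    sigma2 = df * s2 / rng.chisquare(df)
    sigma2 = max(sigma2, 1e-12)
    cov_chol = np.linalg.cholesky(np.linalg.inv(xtx) * sigma2)
    beta = beta_hat + cov_chol @ rng.standard_normal(q)
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))


def impute_chained(
    matrix: DrugSensitivityMatrix, m: int = 100, seed: int = 0, n_sweeps: int = 10
) -> ImputationSet:
    """Multiple imputation by chained equations (normal-regression flavour).

    For each of ``m`` independent completions: initialise missing entries
    at observed column means, then for ``n_sweeps`` sweeps regress each
    incomplete column on all other (current-state) columns and replace
    its missing entries with posterior-predictive draws.  Observed
    entries are never touched.

    Raises ``ValueError`` naming the offending row/column when a row is
    fully missing or a column has fewer than two observed entries.
    """
    values, mask = matrix.values, matrix.mask
    n, d = values.shape
    full_rows = np.where(mask.all(axis=1))[0]
    if full_rows.size:
        raise ValueError(f"rows fully missing: {full_rows.tolist()}")
    thin_cols = np.where((~mask).sum(axis=0) < 2)[0]
    if thin_cols.size:
        names = [matrix.drug_names[c] for c in thin_cols]
        raise ValueError(f"columns with fewer than two observed entries: {names}")
    if m < 1:
        raise ValueError("m must be at least 1")

    col_means = np.array([values[~mask[:, j], j].mean() for j in range(d)])
    incomplete = [j for j in range(d) if mask[:, j].any()]
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(m)]

    completed = []
    for rng in rngs:
        work = np.where(mask, col_means, values)
        for _ in range(n_sweeps if incomplete else 0):
            for j in incomplete:
                mis = mask[:, j]
                others = np.delete(work, j, axis=1)
                X_obs = np.column_stack([np.ones((~mis).sum()), others[~mis]])
                X_mis = np.column_stack([np.ones(mis.sum()), others[mis]])
                work[mis, j] = _draw_regression_imputation(
                    X_obs, values[~mis, j], X_mis, rng
                )
        completed.append(work)
    return ImputationSet(completed=completed, method="chained-normal", seed=seed)


def wss_curve(
    imps: ImputationSet,
    k_values: np.ndarray | list[int] = tuple(range(1, 11)),
    seed: int = 0,
    n_restarts: int = 10,
) -> WSSCurve:
    """k-means WSS (inertia) per imputation and k, plus the mean curve.

    k-means++ initialisation with ``n_restarts`` restarts, keeping the
    best WSS, so the curves are non-increasing in k up to local-optimum
    noise.
    """
    k_values = np.asarray(sorted(k_values), int)
    n = imps.completed[0].shape[0]
    if k_values.min() < 1 or k_values.max() > n:
        raise ValueError(f"k values must lie in [1, {n}]")
    seeds = np.random.SeedSequence(seed).generate_state(imps.m)
    wss = np.empty((imps.m, len(k_values)))
    for i, Y in enumerate(imps.completed):
        for a, k in enumerate(k_values):
            km = KMeans(
                n_clusters=int(k),
                n_init=n_restarts,
                random_state=int(seeds[i] % (2**31)),
            ).fit(Y)
            wss[i, a] = km.inertia_
    return WSSCurve(k_values=k_values, per_imputation_wss=wss, mean_wss=wss.mean(axis=0))


def select_dataset(imps: ImputationSet, wss: WSSCurve, k: int = 3) -> int:
    """Index (0-based) of the completion with the lowest WSS at the given k.

    Ties break toward the lowest index.
    """
    matches = np.where(wss.k_values == k)[0]
    if matches.size == 0:
        raise ValueError(f"k={k} not among the evaluated k values {wss.k_values.tolist()}")
    return int(np.argmin(wss.per_imputation_wss[:, matches[0]]))


def standardize(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column z-scoring; returns (standardized, means, sds)."""
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Y - mean) / sd, mean, sd
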