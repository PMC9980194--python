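"""Core data containers for the joint MRD / drug-sensitivity model.

The model couples two observation blocks per patient:

* a pair of minimal-residual-disease (MRD) measurements taken on day 15
  and day 42 of induction therapy, recorded on the log10-percent scale
  and left-censored at the flow-cytometry detection limit of 0.01%
  (``z_low = log10(0.01) = -2``), and
* a 5-dimensional vector of log10 LC50 drug-sensitivity values measured
  ex vivo, with substantial missingness, modelled as a 3-component
  Gaussian mixture whose latent component label enters the MRD
  regression as a covariate.

Everything downstream (simulation, likelihoods, the Gibbs sampler,
summaries) operates on the containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

Z_LOW: float = float(np.log10(0.01))
"""Detection limit on the log10-percent scale: MRD < 0.01% is censored."""

N_CLUSTERS: int = 3
N_DRUGS: int = 5

DRUGS: tuple[str, ...] = ("asparaginase", "prednisone", "vincristine", "6TG", "6MP")

SUBTYPE_LEVELS: tuple[str, ...] = (
    "BCR-ABL1",
    "DUX4",
    "ETV6-RUNX1",
    "Hyperdiploid",
    "Hypodiploid",
    "KMT2A",
    "Other",
    "PAX5alt",
    "Ph-like",
    "T-ALL",
    "TCF3-PBX1",
    "iAMP21",
)
REFERENCE_SUBTYPE: str = "ETV6-RUNX1"

PROTOCOL_LEVELS: tuple[str, ...] = ("Total_XV", "Total_XVI", "Total_XVII")
REFERENCE_PROTOCOL: str = "Total_XVI"


def dummy_columns(levels: Sequence[str], reference: str) -> list[str]:
    """Non-reference levels in fixed lexical order (the dummy-column order)."""
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among levels")
    return sorted(l for l in levels if l != reference)


@dataclass
class CovariateTable:
    """Per-patient baseline covariates.

    The design vector for patient ``i`` has ``p = 3 + (S-1) + (P-1)``
    entries in the fixed order: age (years), male indicator, log10 WBC,
    subtype dummies (reference ``ETV6-RUNX1`` omitted, lexical order),
    protocol dummies (reference ``Total_XVI`` omitted).  With the default
    12 subtypes and 3 protocols, ``p = 16``.  At most one subtype dummy
    and one protocol dummy equal 1 per patient.
    """

    age: np.ndarray
    male: np.ndarray
    log10_wbc: np.ndarray
    subtype: np.ndarray
    protocol: np.ndarray
    patient_id: np.ndarray | None = None
    subtype_levels: tuple[str, ...] = SUBTYPE_LEVELS
    protocol_levels: tuple[str, ...] = PROTOCOL_LEVELS
    reference_subtype: str = REFERENCE_SUBTYPE
    reference_protocol: str = REFERENCE_PROTOCOL

    def __post_init__(self) -> None:
        n = len(self.age)
        for name in ("male", "log10_wbc", "subtype", "protocol"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"covariate column {name!r} has inconsistent length")
        if self.patient_id is None:
            self.patient_id = np.arange(1, n + 1)
        bad = set(np.unique(self.subtype)) - set(self.subtype_levels)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        bad = set(np.unique(self.protocol)) - set(self.protocol_levels)
        if bad:
            raise ValueError(f"unknown protocol labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.age)

    @property
    def design_columns(self) -> list[str]:
        sub = dummy_columns(self.subtype_levels, self.reference_subtype)
        pro = dummy_columns(self.protocol_levels, self.reference_protocol)
        return (
            ["age", "male", "log10_wbc"]
            + [f"subtype_{s}" for s in sub]
            + [f"protocol_{p}" for p in pro]
        )

    @property
    def p(self) -> int:
        return len(self.design_columns)

    def design_matrix(self) -> np.ndarray:
        """The n x p real design matrix X (no intercept column)."""
        sub = dummy_columns(self.subtype_levels, self.reference_subtype)
        pro = dummy_columns(self.protocol_levels, self.reference_protocol)
        cols = [
            np.asarray(self.age, float),
            np.asarray(self.male, float),
            np.asarray(self.log10_wbc, float),
        ]
        cols += [(self.subtype == s).astype(float) for s in sub]
        cols += [(self.protocol == p).astype(float) for p in pro]
        return np.column_stack(cols)


@dataclass
class MRDObservations:
    """Left-censored MRD pair on the log10-percent scale.

    ``delta[t] = 1`` marks an observed value (``z > z_low``); censored
    entries store the bound ``z_low`` itself, never the latent value.
    """

    z1: np.ndarray
    z2: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    z_low: float = Z_LOW

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, float)
        self.z2 = np.asarray(self.z2, float)
        self.delta1 = np.asarray(self.delta1, int)
        self.delta2 = np.asarray(self.delta2, int)
        n = len(self.z1)
        if not (len(self.z2) == len(self.delta1) == len(self.delta2) == n):
            raise ValueError("MRD blocks have inconsistent lengths")
        for z, d, name in ((self.z1, self.delta1, "day15"), (self.z2, self.delta2, "day42")):
            if np.any((d == 1) & ~(z > self.z_low)):
                raise ValueError(f"{name}: observed entries must exceed z_low")
            if np.any((d == 0) & (z != self.z_low)):
                raise ValueError(f"{name}: censored entries must store z_low")

    @property
    def n(self) -> int:
        return len(self.z1)


@dataclass
class DrugSensitivityMatrix:
    """N x 5 matrix of log10 LC50 values with an explicit missingness mask.

    ``mask[i, d] = True`` flags a missing entry; ``values`` at masked
    positions are undefined (stored as NaN), never sentinel-coded.
    """

    values: np.ndarray
    mask: np.ndarray
    drug_names: tuple[str, ...] = DRUGS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.ndim != 2 or self.values.shape[1] != N_DRUGS:
            raise ValueError(f"LC50 matrix must have exactly {N_DRUGS} columns")
        if self.values.shape[0] < 2:
            raise ValueError("LC50 matrix needs at least two rows")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def missing_rates(self) -> np.ndarray:
        return self.mask.mean(axis=0)


@dataclass
class RegressionParams:
    """All regression-block parameters of the two-timepoint MRD model.

    Day-15 mean:  mu1_i = b0_1 + beta1 . X_i + gamma1 . c_i
    Day-42 mean:  mu2_i = b0_2 + delta1_i * (rho0 + rho * z1_i
                                             + beta2 . X_i + gamma2 . c_i)

    where ``c_i`` is the 2-vector dummy coding of the mixture component
    (cluster 1 -> (0,0), 2 -> (1,0), 3 -> (0,1)).  The day-42 regression
    block is gated off entirely when day-15 MRD is censored.
    """

    b0_1: float
    b0_2: float
    beta1: np.ndarray
    beta2: np.ndarray
    gamma1: np.ndarray
    gamma2: np.ndarray
    rho0: float
    rho: float
    sigma2_1: float
    sigma2_2: float

    def __post_init__(self) -> None:
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, float))
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, float))
        self.gamma1 = np.atleast_1d(np.asarray(self.gamma1, float))
        self.gamma2 = np.atleast_1d(np.asarray(self.gamma2, float))
        if self.beta1.shape != self.beta2.shape:
            raise ValueError("beta1 and beta2 must have equal length")
        if self.gamma1.shape != (N_CLUSTERS - 1,) or self.gamma2.shape != (N_CLUSTERS - 1,):
            raise ValueError(f"gamma vectors must have length {N_CLUSTERS - 1}")
        if self.sigma2_1 <= 0 or self.sigma2_2 <= 0:
            raise ValueError("observation variances must be positive")

    @property
    def p(self) -> int:
        return len(self.beta1)

    @classmethod
    def zeros(cls, p: int, sigma2_1: float = 1.0, sigma2_2: float = 1.0) -> "RegressionParams":
        return cls(
            b0_1=0.0, b0_2=0.0,
            beta1=np.zeros(p), beta2=np.zeros(p),
            gamma1=np.zeros(N_CLUSTERS - 1), gamma2=np.zeros(N_CLUSTERS - 1),
            rho0=0.0, rho=0.0, sigma2_1=sigma2_1, sigma2_2=sigma2_2,
        )


@dataclass
class HorseshoeBlock:
    """Local-global horseshoe scales for one coefficient block.

    beta_j | lambda_j, tau ~ N(0, lambda_j^2 tau^2);
    lambda_j, tau ~ half-Cauchy(0, 1).  ``nu`` and ``xi`` are the
    inverse-gamma auxiliaries that make the scale updates conjugate.
    """

    lam: np.ndarray
    tau: float
    nu: np.ndarray | None = None
    xi: float = 1.0

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, float))
        if np.any(self.lam <= 0) or self.tau <= 0:
            raise ValueError("horseshoe scales must be strictly positive")
        if self.nu is None:
            self.nu = np.ones_like(self.lam)

    @classmethod
    def ones(cls, p: int) -> "HorseshoeBlock":
        return cls(lam=np.ones(p), tau=1.0)


@dataclass
class HorseshoeState:
    """Horseshoe scales for the four shrunk blocks (beta1, gamma1, beta2, gamma2)."""

    beta1: HorseshoeBlock
    gamma1: HorseshoeBlock
    beta2: HorseshoeBlock
    gamma2: HorseshoeBlock

    @classmethod
    def ones(cls, p: int) -> "HorseshoeState":
        return cls(
            beta1=HorseshoeBlock.ones(p),
            gamma1=HorseshoeBlock.ones(N_CLUSTERS - 1),
            beta2=HorseshoeBlock.ones(p),
            gamma2=HorseshoeBlock.ones(N_CLUSTERS - 1),
        )

    def blocks(self) -> dict[str, HorseshoeBlock]:
        return {"beta1": self.beta1, "gamma1": self.gamma1,
                "beta2": self.beta2, "gamma2": self.gamma2}


@dataclass
class MixtureParams:
    """Finite Gaussian mixture over the 5-dimensional log10 LC50 vectors.

    ``cov_mode`` selects the covariance reading: ``"isotropic"`` (default)
    gives each component the covariance ``sigma2[j] * I_5``; ``"diag_shared"``
    gives every component the same diagonal ``diag(sigma2)`` with one
    variance per drug.  Mixture weights carry a Dirichlet(1/3, 1/3, 1/3)
    prior; component means are a priori N_5(0, I).
    """

    w: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    alpha: np.ndarray = field(default_factory=lambda: np.full(N_CLUSTERS, 1.0 / N_CLUSTERS))
    cov_mode: str = "isotropic"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        self.mu = np.asarray(self.mu, float)
        self.sigma2 = np.asarray(self.sigma2, float)
        self.alpha = np.asarray(self.alpha, float)
        if self.w.shape != (N_CLUSTERS,):
            raise ValueError(f"w must have length {N_CLUSTERS}")
        if abs(self.w.sum() - 1.0) > 1e-8 or np.any(self.w < 0):
            raise ValueError("mixture weights must be a probability vector")
        if self.mu.shape != (N_CLUSTERS, N_DRUGS):
            raise ValueError(f"mu must be {N_CLUSTERS} x {N_DRUGS}")
        if self.cov_mode == "isotropic":
            if self.sigma2.shape != (N_CLUSTERS,):
                raise ValueError("isotropic mode needs one variance per component")
        elif self.cov_mode == "diag_shared":
            if self.sigma2.shape != (N_DRUGS,):
                raise ValueError("diag_shared mode needs one variance per drug")
        else:
            raise ValueError(f"unknown cov_mode {self.cov_mode!r}")
        if np.any(self.sigma2 <= 0):
            raise ValueError("component variances must be positive")

    def component_sd_matrix(self) -> np.ndarray:
        """Per-(component, drug) standard deviations as a 3 x 5 matrix."""
        if self.cov_mode == "isotropic":
            return np.sqrt(self.sigma2)[:, None] * np.ones((1, N_DRUGS))
        return np.ones((N_CLUSTERS, 1)) * np.sqrt(self.sigma2)[None, :]


#: dummy coding of cluster membership: cluster 1 is the reference level.
CLUSTER_DUMMY = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


@dataclass
class Allocations:
    """Latent mixture-component labels c_i in {1, 2, 3}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if np.any((self.labels < 1) | (self.labels > N_CLUSTERS)):
            raise ValueError("allocations must lie in {1, 2, 3}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def dummies(self) -> np.ndarray:
        """n x 2 dummy coding: 1 -> (0,0), 2 -> (1,0), 3 -> (0,1)."""
        return CLUSTER_DUMMY[self.labels - 1]

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_CLUSTERS + 1)[1:]


@dataclass
class CohortData:
    """A complete cohort: covariates, censored MRD pair, LC50 block."""

    covariates: CovariateTable
    mrd: MRDObservations
    lc50: DrugSensitivityMatrix

    def __post_init__(self) -> None:
        n = self.covariates.n
        if self.mrd.n != n or self.lc50.n != n:
            raise ValueError("cohort blocks have inconsistent patient counts")

    @property
    def n(self) -> int:
        return self.covariates.n


def regression_params_to_dict(params: RegressionParams) -> dict:
    d = asdict(params)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d


def regression_params_from_dict(d: dict) -> RegressionParams:
    return RegressionParams(**d)
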