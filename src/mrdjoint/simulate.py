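"""Synthetic-cohort generator.

Emulates the statistical structure of a pediatric ALL induction cohort:
baseline covariates with realistically skewed marginals, a 3-component
Gaussian mixture over 5-dimensional log10 LC50 drug-sensitivity vectors
with per-drug missingness, and a left-censored, conditionally
autoregressive MRD pair generated from the observation model itself.

Default parameter values are calibrated so that a default cohort
reproduces the field-typical summary pattern: ~55% male, about one third
of patients censored (< 0.01%) at day 15 and ~85% censored at day 42,
with day-15 censoring (near-)implying day-42 censoring.  Monotone
censoring is not forced structurally; it emerges from a day-42 intercept
far below the detection limit, matching the generative model.  A strict
flag that resamples the rare violators is available for tests that need
exact monotonicity.

The full generator is a seed-deterministic pure function of its config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import (
    CLUSTER_DUMMY,
    N_CLUSTERS,
    N_DRUGS,
    PROTOCOL_LEVELS,
    SUBTYPE_LEVELS,
    Z_LOW,
    dummy_columns,
    Allocations,
    CohortData,
    CovariateTable,
    DrugSensitivityMatrix,
    MixtureParams,
    MRDObservations,
    RegressionParams,
    regression_params_to_dict,
)

# Skewed 12-level subtype frequency table; hyperdiploid and ETV6-RUNX1
# dominate, as in childhood ALL.
DEFAULT_SUBTYPE_FREQS: dict[str, float] = {
    "ETV6-RUNX1": 0.22,
    "Hyperdiploid": 0.25,
    "T-ALL": 0.10,
    "Ph-like": 0.08,
    "DUX4": 0.07,
    "TCF3-PBX1": 0.06,
    "PAX5alt": 0.05,
    "KMT2A": 0.05,
    "BCR-ABL1": 0.04,
    "Hypodiploid": 0.03,
    "iAMP21": 0.03,
    "Other": 0.02,
}

# Trial-arm sizes 192 : 428 : 168.
DEFAULT_PROTOCOL_FREQS: dict[str, float] = {
    "Total_XV": 192 / 788,
    "Total_XVI": 428 / 788,
    "Total_XVII": 168 / 788,
}


def default_mixture_truth() -> MixtureParams:
    """Well-separated 3-component truth on the (roughly standardized) LC50 scale.

    The separating axis is sensitivity to prednisone and asparaginase:
    component 2 is sensitive (low LC50), component 3 resistant, component
    1 intermediate; vincristine separates weakly and the thiopurines not
    at all.
    """
    mu = np.array(
        [
            [0.0, 0.0, 0.0, 0.0, 0.0],
            [-2.0, -2.0, -1.2, -0.5, -0.5],
            [2.0, 2.0, 1.2, 0.5, 0.5],
        ]
    )
    return MixtureParams(w=np.array([0.40, 0.35, 0.25]), mu=mu, sigma2=np.full(3, 0.2))


def default_regression_truth(p: int = 16) -> RegressionParams:
    """Default regression truth, calibrated to the target censoring pattern.

    Sparse day-15 effects (log10 WBC, the hyperdiploid subtype, the
    Total_XV protocol arm) plus opposite-signed cluster effects; the
    day-42 block is pure autoregression (rho = 1) on top of an intercept
    far below the detection limit, which makes day-15 censoring carry
    over to day 42 almost surely.
    """
    beta1 = np.zeros(p)
    beta2 = np.zeros(p)
    sub = dummy_columns(SUBTYPE_LEVELS, "ETV6-RUNX1")
    pro = dummy_columns(PROTOCOL_LEVELS, "Total_XVI")
    cols = ["age", "male", "log10_wbc"] + [f"subtype_{s}" for s in sub] + [
        f"protocol_{q}" for q in pro
    ]
    beta1[cols.index("log10_wbc")] = 0.6
    beta1[cols.index("subtype_Hyperdiploid")] = 1.0
    beta1[cols.index("protocol_Total_XV")] = -0.8
    return RegressionParams(
        b0_1=-2.1,
        b0_2=-3.6,
        beta1=beta1,
        beta2=beta2,
        gamma1=np.array([-0.8, 0.8]),
        gamma2=np.zeros(2),
        rho0=1.41,
        rho=1.0,
        sigma2_1=1.2,
        sigma2_2=0.25,
    )


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Frequencies must be probability vectors; ages are lognormal in years,
    WBC is log10-normal.  ``censor_threshold`` is the detection limit on
    the log10-percent scale (default log10(0.01) = -2).
    """

    n_patients: int = 788
    subtype_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_FREQS))
    protocol_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROTOCOL_FREQS))
    male_prob: float = 0.548
    age_log_mean: float = 1.69
    age_log_sd: float = 0.70
    wbc_log10_mean: float = 1.22
    wbc_log10_sd: float = 0.65
    mixture_truth: MixtureParams = field(default_factory=default_mixture_truth)
    missing_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.20, 0.25, 0.30, 0.35, 0.39])
    )
    regression_truth: RegressionParams = field(default_factory=default_regression_truth)
    censor_threshold: float = Z_LOW
    strict_monotone: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        for name, freqs, levels in (
            ("subtype_freqs", self.subtype_freqs, SUBTYPE_LEVELS),
            ("protocol_freqs", self.protocol_freqs, PROTOCOL_LEVELS),
        ):
            if set(freqs) != set(levels):
                raise ValueError(f"{name} must assign a frequency to each of {levels}")
            vals = np.array(list(freqs.values()), float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.male_prob <= 1.0:
            raise ValueError("male_prob must lie in [0, 1]")
        self.missing_rates = np.asarray(self.missing_rates, float)
        if self.missing_rates.shape != (N_DRUGS,):
            raise ValueError(f"missing_rates must have length {N_DRUGS}")
        if np.any((self.missing_rates < 0) | (self.missing_rates > 1)):
            raise ValueError("missing_rates must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort, for recovery tests."""

    allocations: np.ndarray
    uncensored_z1: np.ndarray
    uncensored_z2: np.ndarray
    params: RegressionParams
    mixture: MixtureParams
    n_non_monotone: int = 0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "allocations": self.allocations.tolist(),
            "uncensored_z1": self.uncensored_z1.tolist(),
            "uncensored_z2": self.uncensored_z2.tolist(),
            "params": regression_params_to_dict(self.params),
            "mixture": {
                "w": self.mixture.w.tolist(),
                "mu": self.mixture.mu.tolist(),
                "sigma2": self.mixture.sigma2.tolist(),
                "cov_mode": self.mixture.cov_mode,
            },
            "n_non_monotone": int(self.n_non_monotone),
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[stream])


def generate_covariates(config: SimConfig) -> CovariateTable:
    """Draw the baseline covariate table (age, gender, WBC, subtype, protocol)."""
    rng = _rng_for(config, 0)
    n = config.n_patients
    age = np.exp(rng.normal(config.age_log_mean, config.age_log_sd, size=n))
    male = (rng.random(n) < config.male_prob).astype(int)
    log10_wbc = rng.normal(config.wbc_log10_mean, config.wbc_log10_sd, size=n)
    sub_levels = list(config.subtype_freqs)
    sub_p = np.array([config.subtype_freqs[s] for s in sub_levels])
    subtype = np.array(sub_levels, object)[rng.choice(len(sub_levels), size=n, p=sub_p)]
    pro_levels = list(config.protocol_freqs)
    pro_p = np.array([config.protocol_freqs[s] for s in pro_levels])
    protocol = np.array(pro_levels, object)[rng.choice(len(pro_levels), size=n, p=pro_p)]
    return CovariateTable(
        age=age, male=male, log10_wbc=log10_wbc, subtype=subtype, protocol=protocol
    )


def generate_lc50(config: SimConfig) -> tuple[DrugSensitivityMatrix, np.ndarray]:
    """Draw allocations and the LC50 matrix, then mask entries MCAR per drug.

    Returns the matrix together with the true component labels (1-based).
    """
    rng = _rng_for(config, 1)
    mix = config.mixture_truth
    n = config.n_patients
    labels = rng.choice(N_CLUSTERS, size=n, p=mix.w) + 1
    sd = mix.component_sd_matrix()
    values = mix.mu[labels - 1] + rng.standard_normal((n, N_DRUGS)) * sd[labels - 1]
    mask = rng.random((n, N_DRUGS)) < config.missing_rates
    # a patient with no assay at all would not be in the panel: redraw
    # the (rare) fully-missing rows
    bad = mask.all(axis=1)
    while np.any(bad):
        mask[bad] = rng.random((bad.sum(), N_DRUGS)) < config.missing_rates
        bad = mask.all(axis=1)
    return DrugSensitivityMatrix(values=values, mask=mask), labels


def generate_mrd(
    covariates: CovariateTable,
    allocations: np.ndarray,
    params: RegressionParams,
    config: SimConfig,
) -> tuple[MRDObservations, SimTruth]:
    """Draw the censored MRD pair from the conditional AR observation model.

    Day-15 values come from the baseline regression; the day-42 mean
    includes the autoregressive block only when day-15 MRD is detected
    (delta1 = 1), otherwise it collapses to the day-42 intercept.  Both
    latent (uncensored) values are recorded in the returned truth, along
    with the count of non-monotone patients (censored at day 15 but
    detected at day 42).
    """
    rng = _rng_for(config, 2)
    X = covariates.design_matrix()
    if params.p != X.shape[1]:
        raise ValueError(
            f"regression truth has p={params.p} but design matrix has {X.shape[1]} columns"
        )
    if len(allocations) != covariates.n:
        raise ValueError("allocations length must equal the number of patients")
    C = CLUSTER_DUMMY[np.asarray(allocations, int) - 1]
    z_low = config.censor_threshold

    mu1 = params.b0_1 + X @ params.beta1 + C @ params.gamma1
    z1 = rng.normal(mu1, np.sqrt(params.sigma2_1))
    d1 = (z1 > z_low).astype(int)
    ar = params.rho0 + params.rho * z1 + X @ params.beta2 + C @ params.gamma2
    mu2 = params.b0_2 + d1 * ar
    z2 = rng.normal(mu2, np.sqrt(params.sigma2_2))
    d2 = (z2 > z_low).astype(int)

    if config.strict_monotone:
        # resample day-42 draws for the rare (delta1=0, delta2=1) violators
        bad = (d1 == 0) & (d2 == 1)
        while np.any(bad):
            z2[bad] = rng.normal(params.b0_2, np.sqrt(params.sigma2_2), size=bad.sum())
            d2 = (z2 > z_low).astype(int)
            bad = (d1 == 0) & (d2 == 1)

    n_non_monotone = int(np.sum((d1 == 0) & (d2 == 1)))
    truth = SimTruth(
        allocations=np.asarray(allocations, int),
        uncensored_z1=z1.copy(),
        uncensored_z2=z2.copy(),
        params=params,
        mixture=config.mixture_truth,
        n_non_monotone=n_non_monotone,
    )
    obs = MRDObservations(
        z1=np.where(d1 == 1, z1, z_low),
        z2=np.where(d2 == 1, z2, z_low),
        delta1=d1,
        delta2=d2,
        z_low=z_low,
    )
    return obs, truth


def generate_cohort(config: SimConfig) -> tuple[CohortData, SimTruth]:
    """Generate a full cohort (covariates + LC50 + MRD) with its ground truth."""
    covariates = generate_covariates(config)
    lc50, labels = generate_lc50(config)
    mrd, truth = generate_mrd(covariates, labels, config.regression_truth, config)
    return CohortData(covariates=covariates, mrd=mrd, lc50=lc50), truth
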