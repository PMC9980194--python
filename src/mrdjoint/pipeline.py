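"""End-to-end orchestration: simulate/load -> impute -> elbow -> fit -> summarize.

``run_pipeline`` executes the whole analysis with every source of
randomness derived from one master seed, writes all artifacts (CSV/JSON)
into the output directory, and is idempotent: re-running with the same
config and seed reproduces the summary files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .datatypes import CohortData
from .diagnostics import diagnostics
from .imputation import impute_chained, select_dataset, standardize, wss_curve
from .io import read_cohort, write_cohort
from .sampler import MCMCConfig, run_mcmc
from .simulate import SimConfig, generate_cohort
from .summaries import (
    binder_partition,
    censored_posterior_means,
    cluster_profiles,
    posterior_similarity,
    summarize_coefficients,
)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``sim`` (synthetic cohort) or ``cohort_path`` (CSV on
    disk) must be provided.  ``seed`` is the master seed from which all
    stage seeds are derived.
    """

    outdir: str | Path
    sim: SimConfig | None = None
    cohort_path: str | Path | None = None
    m_imputations: int = 100
    k_range: tuple[int, ...] = tuple(range(1, 11))
    k: int = 3
    n_kmeans_restarts: int = 10
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    cov_mode: str = "diag_shared"
    seed: int = 0
    merge_rare: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.cohort_path is None):
            raise ValueError("provide exactly one of sim or cohort_path")
        if self.k not in self.k_range:
            raise ValueError("k must be contained in k_range")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be at least 1")

    def digest(self) -> str:
        payload = {
            "m": self.m_imputations,
            "k_range": list(self.k_range),
            "k": self.k,
            "mcmc": [self.mcmc.n_iter, self.mcmc.burn_in, self.mcmc.thin],
            "cov_mode": self.cov_mode,
            "seed": self.seed,
            "sim_n": None if self.sim is None else self.sim.n_patients,
            "cohort": None if self.cohort_path is None else str(self.cohort_path),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"[{name}] {e}") from e

        return wrapped

    return deco


@_stage("load")
def _load(config: RunConfig, seeds) -> tuple[CohortData, object]:
    if config.sim is not None:
        sim = SimConfig(**{**config.sim.__dict__})
        sim.seed = int(seeds[0])
        return generate_cohort(sim)
    return read_cohort(config.cohort_path, merge_rare=config.merge_rare), None


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the artifact directory.

    Artifacts: ``cohort.csv`` (and ``truth.json`` when simulated),
    ``wss_curve.csv``, ``selection.json``, ``coefficients.csv``,
    ``diagnostics.csv``, ``partition.csv``, ``cluster_profiles_drugs.csv``,
    ``cluster_profiles_subtypes.csv``, ``censored_means.csv``,
    ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    cohort, truth = _load(config, seeds)
    write_cohort(cohort, outdir / "cohort.csv")
    if truth is not None:
        truth.to_json(outdir / "truth.json")

    imps, curve, sel = _impute_stage(config, cohort, seeds)
    _write_wss(curve, sel, config.k, outdir)

    samples, Y_sel = _fit_stage(config, cohort, imps, sel, seeds)
    _summarize_stage(config, cohort, samples, Y_sel, outdir)

    manifest = {
        "seed": int(config.seed),
        "stage_seeds": [int(s) for s in seeds],
        "config_hash": config.digest(),
        "n_patients": int(cohort.n),
        "m_imputations": int(config.m_imputations),
        "k": int(config.k),
        "mcmc": {
            "n_iter": config.mcmc.n_iter,
            "burn_in": config.mcmc.burn_in,
            "thin": config.mcmc.thin,
            "n_retained": config.mcmc.n_retained,
        },
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


@_stage("impute")
def _impute_stage(config: RunConfig, cohort: CohortData, seeds):
    imps = impute_chained(cohort.lc50, m=config.m_imputations, seed=int(seeds[1]))
    curve = wss_curve(
        imps, k_values=config.k_range, seed=int(seeds[2]), n_restarts=config.n_kmeans_restarts
    )
    sel = select_dataset(imps, curve, k=config.k)
    return imps, curve, sel


def _write_wss(curve, sel: int, k: int, outdir: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        curve.per_imputation_wss, columns=[f"k{kv}" for kv in curve.k_values]
    )
    df.insert(0, "imputation", np.arange(len(df)))
    df.to_csv(outdir / "wss_curve.csv", index=False)
    (outdir / "selection.json").write_text(
        json.dumps(
            {
                "selected_imputation": int(sel),
                "k": int(k),
                "mean_wss": dict(zip(map(str, curve.k_values.tolist()), curve.mean_wss.tolist())),
            },
            indent=1,
        )
    )


@_stage("fit")
def _fit_stage(config: RunConfig, cohort: CohortData, imps, sel: int, seeds):
    Y_sel = imps.completed[sel]
    Y_std, _, _ = standardize(Y_sel)
    mcfg = MCMCConfig(
        n_iter=config.mcmc.n_iter,
        burn_in=config.mcmc.burn_in,
        thin=config.mcmc.thin,
        seed=int(seeds[3]),
        init=config.mcmc.init,
    )
    samples = run_mcmc(cohort.covariates, cohort.mrd, Y_std, mcfg, cov_mode=config.cov_mode)
    return samples, Y_sel


@_stage("summarize")
def _summarize_stage(config: RunConfig, cohort: CohortData, samples, Y_sel, outdir: Path):
    import pandas as pd

    summarize_coefficients(samples).to_csv(outdir / "coefficients.csv", index=False)
    diagnostics(samples).to_csv(outdir / "diagnostics.csv", index=False)
    psm = posterior_similarity(samples.alloc)
    part = binder_partition(psm, samples.alloc)
    pd.DataFrame(
        {"patient_id": cohort.covariates.patient_id, "cluster": part.labels}
    ).to_csv(outdir / "partition.csv", index=False)
    drugs, subs = cluster_profiles(
        part, Y_sel, cohort.covariates.subtype, cohort.lc50.drug_names
    )
    drugs.to_csv(outdir / "cluster_profiles_drugs.csv", index=False)
    subs.to_csv(outdir / "cluster_profiles_subtypes.csv", index=False)
    censored_posterior_means(samples, cohort.mrd).to_csv(
        outdir / "censored_means.csv", index=False
    )


def _versions() -> dict[str, str]:
    import pandas
    import scipy
    import sklearn

    return {
        "mrdjoint": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
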