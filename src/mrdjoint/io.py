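"""Cohort file schema: reading and writing patient-level CSV tables.

One row per patient with columns::

    patient_id, age, gender, wbc, subtype, protocol,
    mrd_day15, mrd_day42, lc50_<drug> (five columns)

MRD is stored on the percent scale, as in clinical reporting; values
below the 0.01% detection limit may be written either as the literal
token ``"<0.01"`` or as a numeric value below 0.01 (including 0).  On
load, MRD is log10-transformed and the censoring indicators are derived
(threshold 0.01% corresponds to ``z_low = -2``).  WBC is stored as a
raw count and log10-transformed on load.  Missing LC50 entries are
blank cells.

Rare subtypes can be pooled on load: Ph-like variants are merged into a
single ``Ph-like`` level first, then any subtype with fewer than
``min_subtype_count`` patients (default 10) is merged into ``Other``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DRUGS,
    Z_LOW,
    CohortData,
    CovariateTable,
    DrugSensitivityMatrix,
    MRDObservations,
)

CENSOR_TOKEN = "<0.01"
MRD_THRESHOLD_PCT = 0.01

_BASE_COLUMNS = [
    "patient_id", "age", "gender", "wbc", "subtype", "protocol",
    "mrd_day15", "mrd_day42",
]


def lc50_column(drug: str) -> str:
    return f"lc50_{drug}"


def _parse_mrd_column(col: pd.Series, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Percent-scale MRD column -> (z log10 values, delta indicators)."""
    z = np.empty(len(col))
    delta = np.empty(len(col), int)
    for i, raw in enumerate(col):
        if isinstance(raw, str) and raw.strip() == CENSOR_TOKEN:
            z[i], delta[i] = Z_LOW, 0
            continue
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric MRD value {raw!r} in column {name!r}, row {i}")
        if val < 0:
            raise ValueError(f"negative MRD value {val} in column {name!r}, row {i}")
        if val < MRD_THRESHOLD_PCT:
            z[i], delta[i] = Z_LOW, 0
        else:
            z[i], delta[i] = np.log10(val), 1
    return z, delta


def merge_rare_subtypes(
    subtype: np.ndarray, min_count: int = 10, other_label: str = "Other"
) -> np.ndarray:
    """Pool Ph-like variants, then subtypes with fewer than ``min_count`` patients."""
    out = np.array(
        [s if not str(s).startswith("Ph-like") else "Ph-like" for s in subtype], object
    )
    labels, counts = np.unique(out, return_counts=True)
    rare = {l for l, c in zip(labels, counts) if c < min_count}
    return np.array([other_label if s in rare else s for s in out], object)


def read_cohort(
    path: str | Path,
    merge_rare: bool = True,
    min_subtype_count: int = 10,
    subtype_vocabulary: list[str] | None = None,
) -> CohortData:
    """Load and validate a cohort CSV.

    ``subtype_vocabulary``, when given, declares the admissible raw
    subtype labels; anything outside it raises.  Validation errors name
    the offending row and column.
    """
    df = pd.read_csv(path, dtype={"mrd_day15": object, "mrd_day42": object})
    missing = [c for c in _BASE_COLUMNS + [lc50_column(d) for d in DRUGS] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing columns: {missing}")

    wbc = pd.to_numeric(df["wbc"], errors="coerce").to_numpy(float)
    if np.any(np.isnan(wbc)):
        row = int(np.where(np.isnan(wbc))[0][0])
        raise ValueError(f"non-numeric WBC in column 'wbc', row {row}")
    if np.any(wbc <= 0):
        row = int(np.where(wbc <= 0)[0][0])
        raise ValueError(f"non-positive WBC in column 'wbc', row {row}")

    gender = df["gender"].astype(str).str.strip()
    bad = ~gender.isin(["Male", "Female"])
    if bad.any():
        row = int(np.where(bad)[0][0])
        raise ValueError(f"unknown gender label {gender.iloc[row]!r} in row {row}")

    subtype = df["subtype"].astype(str).to_numpy(object)
    if subtype_vocabulary is not None:
        unknown = sorted(set(subtype) - set(subtype_vocabulary))
        if unknown:
            raise ValueError(f"unknown subtype labels in column 'subtype': {unknown}")
    if merge_rare:
        subtype = merge_rare_subtypes(subtype, min_count=min_subtype_count)

    z1, d1 = _parse_mrd_column(df["mrd_day15"], "mrd_day15")
    z2, d2 = _parse_mrd_column(df["mrd_day42"], "mrd_day42")

    protocol = df["protocol"].astype(str).to_numpy(object)
    subtype_levels = tuple(sorted(np.unique(subtype)))
    protocol_levels = tuple(sorted(np.unique(protocol)))
    ref_sub = "ETV6-RUNX1" if "ETV6-RUNX1" in subtype_levels else subtype_levels[0]
    ref_pro = "Total_XVI" if "Total_XVI" in protocol_levels else protocol_levels[0]

    covariates = CovariateTable(
        age=pd.to_numeric(df["age"]).to_numpy(float),
        male=(gender == "Male").astype(int).to_numpy(),
        log10_wbc=np.log10(wbc),
        subtype=subtype,
        protocol=protocol,
        patient_id=df["patient_id"].to_numpy(),
        subtype_levels=subtype_levels,
        protocol_levels=protocol_levels,
        reference_subtype=ref_sub,
        reference_protocol=ref_pro,
    )
    mrd = MRDObservations(z1=z1, z2=z2, delta1=d1, delta2=d2)
    lc = df[[lc50_column(d) for d in DRUGS]].to_numpy(float)
    lc50 = DrugSensitivityMatrix(values=lc, mask=np.isnan(lc))
    return CohortData(covariates=covariates, mrd=mrd, lc50=lc50)


def write_cohort(cohort: CohortData, path: str | Path) -> None:
    """Write a cohort back to the CSV schema (inverse of :func:`read_cohort`).

    Censored MRD entries are emitted as the canonical ``"<0.01"`` token;
    observed entries as percent values ``10**z``.
    """
    cov, mrd, lc50 = cohort.covariates, cohort.mrd, cohort.lc50

    def mrd_col(z: np.ndarray, delta: np.ndarray) -> list[str | float]:
        return [CENSOR_TOKEN if d == 0 else 10.0**v for v, d in zip(z, delta)]

    df = pd.DataFrame(
        {
            "patient_id": cov.patient_id,
            "age": cov.age,
            "gender": np.where(cov.male == 1, "Male", "Female"),
            "wbc": 10.0**cov.log10_wbc,
            "subtype": cov.subtype,
            "protocol": cov.protocol,
            "mrd_day15": mrd_col(mrd.z1, mrd.delta1),
            "mrd_day42": mrd_col(mrd.z2, mrd.delta2),
        }
    )
    for d, name in enumerate(lc50.drug_names):
        df[lc50_column(name)] = np.where(lc50.mask[:, d], np.nan, lc50.values[:, d])
    df.to_csv(path, index=False)
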