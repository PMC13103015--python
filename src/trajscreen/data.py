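"""Data model and I/O for longitudinal cohort tables.

The single input currency of the pipeline is a :class:`CohortDataset`:
a long-format table of repeated measurements (patient, visit time in
months, variable id, variable type, value) plus a per-patient covariate
table (age in years, sex).  Proteins are measured on a strictly positive
relative-fluorescence scale and are analysed after a natural-log
transform; echocardiographic variables (e.g. indexed atrial volume,
indexed end-diastolic volume in mL/m², ejection fraction in %) are
analysed on their native scale.

Time is coded in months since the index event, with hospital discharge
at 0.  Baseline (t = 0) protein measurements are excluded by design —
the acute-phase inflammatory response makes them unrepresentative of
the chronic remodeling process — via :func:`apply_design_filters`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, SchemaError, StateError

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("patient_id", "time_months", "variable_id", "variable_type", "value")
COVARIATE_COLUMNS = ("patient_id", "age_years", "sex")
VARIABLE_TYPES = ("protein", "echo")
SEX_LEVELS = ("female", "male")

#: Column order of the results table written by :func:`write_results`.
RESULT_COLUMNS = (
    "protein_id",
    "echo_id",
    "structure_protein",
    "structure_echo",
    "lrt_stat",
    "df",
    "p_value",
    "fdr_q",
    "spearman_of_means",
    "converged",
)


@dataclass
class CohortDataset:
    """Long-format repeated measurements plus per-patient covariates.

    Attributes
    ----------
    measurements
        DataFrame with columns ``patient_id, time_months, variable_id,
        variable_type, value``; one row per observation.
    covariates
        DataFrame with columns ``patient_id, age_years, sex``; one row
        per patient.
    protein_log_applied
        Whether protein values have been natural-log transformed.
    n_dropped_missing
        Rows dropped at load time because the value cell was empty.
    """

    measurements: pd.DataFrame
    covariates: pd.DataFrame
    protein_log_applied: bool = False
    n_dropped_missing: int = 0

    def variable_ids(self, variable_type: str | None = None) -> list[str]:
        m = self.measurements
        if variable_type is not None:
            m = m[m["variable_type"] == variable_type]
        return sorted(m["variable_id"].unique())

    def sex_indicator(self) -> pd.Series:
        """0/1 indicator with female = 1, indexed by patient_id."""
        s = self.covariates.set_index("patient_id")["sex"]
        return (s == "female").astype(float)

    def subset_variables(self, variable_ids: Iterable[str]) -> "CohortDataset":
        ids = set(variable_ids)
        m = self.measurements[self.measurements["variable_id"].isin(ids)].reset_index(drop=True)
        return replace(self, measurements=m)


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements table is missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    df["time_months"] = pd.to_numeric(df["time_months"], errors="raise")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad_type = set(df["variable_type"].unique()) - set(VARIABLE_TYPES)
    if bad_type:
        raise SchemaError(f"unknown variable_type value(s): {sorted(bad_type)}")
    if (df["time_months"] < 0).any():
        raise DomainError("time_months must be non-negative")
    if np.isinf(df["time_months"]).any():
        raise DomainError("time_months must be finite")
    return df


def _validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"covariates table is missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(COVARIATE_COLUMNS)].copy()
    df["age_years"] = pd.to_numeric(df["age_years"], errors="raise")
    if (df["age_years"] <= 0).any() or not np.isfinite(df["age_years"]).all():
        raise DomainError("age_years must be positive and finite")
    bad_sex = set(df["sex"].unique()) - set(SEX_LEVELS)
    if bad_sex:
        raise SchemaError(f"sex must be one of {SEX_LEVELS}; got {sorted(bad_sex)}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].unique()
        raise IntegrityError(f"duplicate covariate rows for patient(s): {sorted(map(str, dups))}")
    return df


def make_cohort(
    measurements: pd.DataFrame,
    covariates: pd.DataFrame,
    protein_log_applied: bool = False,
) -> CohortDataset:
    """Validate in-memory tables and assemble a :class:`CohortDataset`.

    Rows whose value is missing (empty cell / NA) are dropped and
    counted; duplicate (patient, time, variable) keys and measured
    patients without a covariate row raise :class:`IntegrityError`.
    """
    meas = _validate_measurements(measurements)
    cov = _validate_covariates(covariates)

    n_before = len(meas)
    meas = meas.dropna(subset=["value"]).reset_index(drop=True)
    n_dropped = n_before - len(meas)
    if n_dropped:
        logger.info("dropped %d measurement rows with missing value", n_dropped)
    if np.isinf(meas["value"]).any():
        raise DomainError("measurement values must be finite")

    key = ["patient_id", "time_months", "variable_id"]
    dup = meas.duplicated(subset=key)
    if dup.any():
        examples = meas.loc[dup, key].head(5).to_dict("records")
        raise IntegrityError(f"duplicate (patient, time, variable) rows, e.g. {examples}")

    measured = set(meas["patient_id"].unique())
    covered = set(cov["patient_id"].unique())
    orphans = sorted(map(str, measured - covered))
    if orphans:
        raise IntegrityError(f"no covariate row for measured patient(s): {orphans}")

    meas = meas.sort_values(key, kind="mergesort").reset_index(drop=True)
    cov = cov.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    return CohortDataset(meas, cov, protein_log_applied, n_dropped)


def load_cohort(measurements_path: str | Path, covariates_path: str | Path) -> CohortDataset:
    """Read and validate the two delimited input tables.

    The delimiter is inferred from the extension (``.tsv``/``.tab``/
    ``.txt`` → tab, otherwise comma).  Empty cells and the token ``NA``
    denote missing values.
    """
    mp, cp = Path(measurements_path), Path(covariates_path)
    for p in (mp, cp):
        if not p.exists():
            raise FileNotFoundError(p)
    meas = pd.read_csv(mp, sep=_delimiter_for(mp), na_values=["NA"], keep_default_na=True)
    cov = pd.read_csv(cp, sep=_delimiter_for(cp), na_values=["NA"], keep_default_na=True)
    return make_cohort(meas, cov)


def log_transform_proteins(ds: CohortDataset) -> CohortDataset:
    """Replace every protein value by its natural logarithm.

    Echo values are untouched.  Raises :class:`StateError` on double
    application and :class:`DomainError` if any protein value is not
    strictly positive (identifying the offending rows).
    """
    if ds.protein_log_applied:
        raise StateError("protein log-transform already applied")
    meas = ds.measurements.copy()
    is_protein = meas["variable_type"] == "protein"
    vals = meas.loc[is_protein, "value"]
    bad = vals <= 0
    if bad.any():
        rows = meas.loc[is_protein].loc[bad, ["patient_id", "time_months", "variable_id", "value"]]
        raise DomainError(
            "non-positive protein value(s); cannot log-transform: "
            f"{rows.head(5).to_dict('records')}"
        )
    meas.loc[is_protein, "value"] = np.log(vals)
    return replace(ds, measurements=meas, protein_log_applied=True)


def apply_design_filters(ds: CohortDataset) -> CohortDataset:
    """Remove protein measurements at t = 0 (acute-phase exclusion).

    Echo measurements at discharge (t = 0) are retained.  Idempotent.
    """
    meas = ds.measurements
    drop = (meas["variable_type"] == "protein") & (meas["time_months"] == 0)
    n = int(drop.sum())
    if n:
        logger.info("design filter removed %d baseline protein measurement rows", n)
        meas = meas[~drop].reset_index(drop=True)
    return replace(ds, measurements=meas)


def results_to_frame(results) -> pd.DataFrame:
    """Convert a collection of PairTestResult objects into the results table."""
    rows = []
    for r in results:
        rows.append(
            {
                "protein_id": r.protein_id,
                "echo_id": r.echo_id,
                "structure_protein": r.structure_protein,
                "structure_echo": r.structure_echo,
                "lrt_stat": r.lrt.statistic if r.lrt is not None else np.nan,
                "df": r.lrt.df if r.lrt is not None else np.nan,
                "p_value": r.lrt.p_value if r.lrt is not None else np.nan,
                "fdr_q": r.fdr_q if r.fdr_q is not None else np.nan,
                "spearman_of_means": r.spearman_of_means if r.spearman_of_means is not None else np.nan,
                "converged": bool(r.converged),
            }
        )
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df = df.sort_values(
        ["fdr_q", "p_value", "protein_id", "echo_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return df


def write_results(results, path: str | Path) -> None:
    """Write screened pairs as TSV, sorted by FDR q then p.

    Non-converged pairs (no likelihood-ratio test) render their test
    columns as the ``NA`` token.
    """
    results = list(results)
    if not results:
        raise DomainError("write_results requires a non-empty result collection")
    df = results_to_frame(results)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
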