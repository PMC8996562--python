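"""Registry data model and I/O.

A registry is a patient-level table from a multicenter acute-stroke
cohort: one row per patient with the treating hospital, a binary
treatment flag (e.g. intravenous thrombolysis, or general anesthesia
during thrombectomy), a binary functional-outcome flag (modified Rankin
Scale 0-2 at 90 days), and eight case-mix covariates.

The canonical on-disk format is a comma-separated, UTF-8, headered CSV
with '.' as decimal separator and 0/1-coded flags; hospital identifiers
are opaque strings.  Missing values in modelled columns are rejected:
the estimators downstream assume complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Exact column order of the registry CSV.
COLUMNS = [
    "hospital_id",
    "treated",
    "good_outcome",
    "age",
    "male",
    "nihss",
    "onset_to_ed_min",
    "prev_stroke",
    "atrial_fib",
    "hypertension",
    "hypercholesterolemia",
]

#: The eight case-mix covariates used for adjustment in every estimator.
CASE_MIX = [
    "age",
    "male",
    "nihss",
    "onset_to_ed_min",
    "prev_stroke",
    "atrial_fib",
    "hypertension",
    "hypercholesterolemia",
]

BINARY_COLUMNS = [
    "treated",
    "good_outcome",
    "male",
    "prev_stroke",
    "atrial_fib",
    "hypertension",
    "hypercholesterolemia",
]


class SchemaError(ValueError):
    """The table does not have the required columns."""


class ValidationError(ValueError):
    """A column holds a value outside its allowed range."""


def _check_binary(df: pd.DataFrame, col: str) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = ~vals.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise ValidationError(
            f"column '{col}' must be 0/1; offending value "
            f"{df[col].iloc[row - 1]!r} in row {row}"
        )


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals < lo) | (vals > hi)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"column '{col}' must lie in [{lo}, {hi}]; offending value "
            f"{df[col].iloc[row - 1]!r} in row {row}"
        )


@dataclass
class PatientTable:
    """A validated patient-level registry.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; row
    order is preserved.  Construction validates the schema, the 0/1
    coding of flag columns and the plausibility ranges of the
    continuous covariates, and normalises dtypes so that a
    write/read round trip reproduces the table exactly.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = self.df[COLUMNS].reset_index(drop=True).copy()
        if df[COLUMNS].isna().any().any():
            col = df.columns[df.isna().any().to_numpy()][0]
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0]) + 1
            raise ValidationError(f"missing value in column '{col}', row {row}")
        for col in BINARY_COLUMNS:
            _check_binary(df, col)
        _check_range(df, "nihss", 0, 42)
        _check_range(df, "age", 18, 110)
        _check_range(df, "onset_to_ed_min", 0, np.inf)
        df["hospital_id"] = df["hospital_id"].astype(str)
        for col in BINARY_COLUMNS + ["nihss"]:
            df[col] = pd.to_numeric(df[col]).astype(np.int64)
        for col in ("age", "onset_to_ed_min"):
            df[col] = pd.to_numeric(df[col]).astype(np.float64)
        self.df = df

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def n_patients(self) -> int:
        return len(self.df)

    @property
    def hospitals(self) -> list[str]:
        """Hospital identifiers in order of first appearance."""
        return list(dict.fromkeys(self.df["hospital_id"]))

    @property
    def n_hospitals(self) -> int:
        return self.df["hospital_id"].nunique()

    def by_hospital(self):
        """Group rows by hospital, preserving first-appearance order."""
        return self.df.groupby("hospital_id", sort=False)


def read_registry(path) -> PatientTable:
    """Read and validate a registry CSV.

    Raises :class:`SchemaError` if a required column is absent and
    :class:`ValidationError` (citing the 1-based data row) for values
    outside their allowed domain.
    """
    df = pd.read_csv(path, dtype={"hospital_id": str}, float_precision="round_trip")
    return PatientTable(df)


def write_registry(table: PatientTable, path) -> None:
    """Write a registry CSV readable by :func:`read_registry` to an
    identical table."""
    # shortest round-trip repr so write/read reproduces floats bit-exactly
    table.df[COLUMNS].to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def aggregate_by_hospital(table: PatientTable) -> pd.DataFrame:
    """Collapse a registry to one row per hospital.

    Returns a frame with patient count, percent treated, percent good
    outcome (both on the 0-100 scale), the mean of each continuous
    case-mix covariate and the percent with each binary one, ordered by
    descending volume.  These hospital-level records are the inputs of
    the ecological analysis and of the instrument-validity checks.
    """
    g = table.by_hospital()
    out = pd.DataFrame(
        {
            "n_patients": g.size(),
            "pct_treated": g["treated"].sum() * 100.0 / g.size(),
            "pct_good_outcome": g["good_outcome"].sum() * 100.0 / g.size(),
            "mean_age": g["age"].mean(),
            "pct_male": g["male"].mean() * 100.0,
            "mean_nihss": g["nihss"].mean(),
            "mean_onset_to_ed_min": g["onset_to_ed_min"].mean(),
            "pct_prev_stroke": g["prev_stroke"].mean() * 100.0,
            "pct_atrial_fib": g["atrial_fib"].mean() * 100.0,
            "pct_hypertension": g["hypertension"].mean() * 100.0,
            "pct_hypercholesterolemia": g["hypercholesterolemia"].mean() * 100.0,
        }
    )
    out = out.sort_values(["n_patients", "hospital_id"], ascending=[False, True])
    return out.reset_index().rename(columns={"index": "hospital_id"})


#: Hospital-level analogues of the case-mix covariates, in matching order.
HOSPITAL_CASE_MIX = [
    "mean_age",
    "pct_male",
    "mean_nihss",
    "mean_onset_to_ed_min",
    "pct_prev_stroke",
    "pct_atrial_fib",
    "pct_hypertension",
    "pct_hypercholesterolemia",
]
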