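"""Grouped person-year cohort tables.

The unit of analysis is a stratum cell: one combination of city, sex,
age-at-exposure category, attained-age category, calendar period and dose
category, carrying the number of subjects, person-years at risk, the
person-year-weighted mean covariates (age at exposure, attained age, weighted
colon dose) and death counts per endpoint.  All Poisson regression in this
package consumes such tables; no individual-level data are handled.

The on-disk dialect is a plain CSV with a named-column header (see
``REQUIRED_COLUMNS``).  A column-map hook lets users adapt differently named
files, including exports of the original fixed-width grouped LSS summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: Canonical column names of the CSV dialect.
REQUIRED_COLUMNS = (
    "city",
    "sex",
    "agex_cat",
    "age_cat",
    "period",
    "dose_cat",
    "subjects",
    "pyr",
    "mean_agex",
    "mean_age",
    "mean_dose",
    "cases_cevd",
    "cases_heart",
)

#: Columns forming the stratum key (must be unique per row).
KEY_COLUMNS = ("city", "sex", "agex_cat", "age_cat", "period", "dose_cat")

ENDPOINTS = ("cevd", "heart")

#: ICD-9 definitions of the two endpoints (documentation only; endpoint
#: selection is a column choice, not a re-derivation from cause codes).
ICD9_CODES = {
    "cevd": "430-438 (cerebrovascular diseases)",
    "heart": "393-429 excluding 401, 403, 405 (heart diseases)",
}


class GroupedTableError(ValueError):
    """Raised when a grouped table violates its invariants.

    ``violations`` lists human-readable messages, each naming the offending
    1-based data row where applicable.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid grouped table:\n  " + "\n  ".join(self.violations)
        )


def weighted_colon_dose(gamma_dose: float, neutron_dose: float) -> float:
    """Weighted colon dose in Gy: gamma dose plus 10 times the neutron dose.

    The factor 10 is the relative biological effectiveness weight applied to
    the neutron dose component.  Both inputs must be non-negative Gy.
    """
    g = np.asarray(gamma_dose, dtype=float)
    n = np.asarray(neutron_dose, dtype=float)
    if np.any(g < 0) or np.any(n < 0):
        raise ValueError("dose components must be non-negative")
    out = g + 10.0 * n
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StratumCell:
    """One cell of the grouped table for a single endpoint."""

    city: str
    sex: str
    agex_cat: str
    age_cat: str
    period: str
    dose_cat: str
    n_subjects: int
    person_years: float
    mean_agex: float
    mean_age: float
    mean_dose: float
    cases: int


@dataclass
class GroupedTable:
    """A validated grouped cohort table bound to one endpoint.

    Parameters
    ----------
    data:
        DataFrame with all :data:`REQUIRED_COLUMNS`.
    endpoint:
        ``"cevd"`` or ``"heart"``; selects which case column :attr:`cases`
        exposes.
    dose_unit:
        Always Gy for weighted colon dose; kept explicit for auditability.
    """

    data: pd.DataFrame
    endpoint: str = "cevd"
    dose_unit: str = "Gy"

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}; expected one of {ENDPOINTS}")
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def cases(self) -> pd.Series:
        return self.data[f"cases_{self.endpoint}"]

    def __len__(self) -> int:
        return len(self.data)

    def cells(self) -> Iterator[StratumCell]:
        col = f"cases_{self.endpoint}"
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield StratumCell(
                city=d["city"], sex=d["sex"], agex_cat=str(d["agex_cat"]),
                age_cat=str(d["age_cat"]), period=str(d["period"]),
                dose_cat=str(d["dose_cat"]), n_subjects=int(d["subjects"]),
                person_years=float(d["pyr"]), mean_agex=float(d["mean_agex"]),
                mean_age=float(d["mean_age"]), mean_dose=float(d["mean_dose"]),
                cases=int(d[col]),
            )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise GroupedTableError([f"missing column(s): {', '.join(missing)}"])

        violations: list[str] = []
        numeric = ["subjects", "pyr", "mean_agex", "mean_age", "mean_dose",
                   "cases_cevd", "cases_heart"]
        for c in numeric:
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            coerced = pd.to_numeric(df[c], errors="coerce")
            for i in df.index[coerced.isna()]:
                violations.append(f"row {i + 1}: non-numeric value in '{c}'")
        if violations:
            raise GroupedTableError(violations)
        df[numeric] = df[numeric].astype(float)

        def flag(mask, msg):
            for i in df.index[np.asarray(mask)]:
                violations.append(f"row {i + 1}: {msg}")

        flag(df["pyr"] < 0, "person-years < 0")
        flag(df["mean_dose"] < 0, "mean dose < 0")
        flag(df["mean_age"] < df["mean_agex"], "attained age < age at exposure")
        for ep in ENDPOINTS:
            col = f"cases_{ep}"
            flag(df[col] < 0, f"{col} < 0")
            flag(df[col] % 1 != 0, f"{col} not an integer")
            flag((df["pyr"] == 0) & (df[col] > 0), f"{col} > 0 on a zero person-year row")
        if not np.isfinite(df[numeric].to_numpy()).all():
            violations.append("non-finite numeric value present")

        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            first = int(df.index[dup][0]) + 1
            violations.append(f"duplicate stratum key (first at row {first})")

        if violations:
            raise GroupedTableError(violations)


def read_grouped_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    endpoint: str = "cevd",
) -> GroupedTable:
    """Read a grouped cohort table from CSV.

    ``schema`` maps file column names to canonical names (e.g. mapping an
    lsscvd10-style export onto :data:`REQUIRED_COLUMNS`); omit it when the
    file already uses canonical headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    df = df.reset_index(drop=True)
    return GroupedTable(df, endpoint=endpoint)


def write_grouped_table(table: GroupedTable, path: str | Path) -> None:
    """Write a table in the canonical CSV dialect (round-trips exactly)."""
    table.data.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def summarize(table: GroupedTable) -> dict:
    """Cohort-level summary of a grouped table.

    Returns totals plus the person-year-weighted and case-weighted mean
    doses; the former is the scalar conventionally quoted for whole-cohort
    exposure (0.116 Gy in the LSS), the latter for the exposure of the
    deceased.
    """
    df = table.data
    if len(df) == 0:
        raise ValueError("cannot summarize an empty table")
    total_py = float(df["pyr"].sum())
    if total_py == 0:
        raise ValueError("total person-years is zero; weighted mean dose undefined")
    cases = float(table.cases.sum())
    out = {
        "endpoint": table.endpoint,
        "n_cells": int(len(df)),
        "total_subjects": float(df["subjects"].sum()),
        "total_person_years": total_py,
        "total_cases": cases,
        "py_weighted_mean_dose": float((df["pyr"] * df["mean_dose"]).sum() / total_py),
        "case_weighted_mean_dose": (
            float((table.cases * df["mean_dose"]).sum() / cases) if cases > 0 else float("nan")
        ),
    }
    return out
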