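"""Total-hazard composition for grouped Poisson regression.

A hazard model combines

* a parametric log-linear baseline ``h0(city, sex, a, e)``,
* one dose-response family ``err(D)`` / ``ear(D)``, and
* multiplicative dose-effect modifiers (DEMs) ``eps(s, a, e)``

under one of two transfer conventions:

* ERR (excess relative risk):  ``h = h0 * (1 + err(D) * eps)``
* EAR (excess absolute risk):  ``h = h0 + ear(D) * eps``

The baseline is log-linear in an intercept, city and sex contrasts, a
polynomial in ln(a/70), an age-at-exposure trend and a sex-specific age
trend; every non-intercept term can be deactivated, which is what the
baseline-streamlining protocol exploits.  Covariates are centred at attained
age 70 and age at exposure 30, the conventional reporting ages.

DEMs follow standard grouped-cohort practice: a sex factor, a power of
attained age and a log-linear term in age at exposure,
``eps = exp(ts * 1[female]) * (a/70)**ta * exp(te * (e - 30)/10)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dose_response import DoseResponseSpec, evaluate
from .grouped_data import GroupedTable, StratumCell

BASELINE_TERMS = (
    "intercept",
    "city",          # 1 for Nagasaki
    "sex",           # 1 for female
    "log_age",       # ln(a/70)
    "log_age_sq",    # ln(a/70)^2
    "age_at_exposure",  # (e-30)/10
    "sex_log_age",   # female * ln(a/70)
)

DEM_TERMS = ("sex", "attained_age", "age_at_exposure")

TRANSFERS = ("ERR", "EAR")

#: Reporting covariates used for risk curves unless overridden: male,
#: Hiroshima, attained age 70, age at exposure 30.
REFERENCE_COVARIATES = {"city": "hiroshima", "sex": "male",
                        "attained_age": 70.0, "age_at_exposure": 30.0}


class HazardPositivityError(ValueError):
    """ERR transfer evaluated where 1 + ERR <= 0 (negative total hazard)."""


@dataclass(frozen=True)
class CellArrays:
    """Numeric covariate arrays extracted once from a table (or one cell)."""

    nagasaki: np.ndarray
    female: np.ndarray
    attained_age: np.ndarray
    age_at_exposure: np.ndarray
    dose: np.ndarray
    pyr: np.ndarray
    cases: np.ndarray

    @classmethod
    def from_table(cls, table: GroupedTable) -> "CellArrays":
        df = table.data
        city = df["city"].astype(str).str.lower().to_numpy()
        sex = df["sex"].astype(str).str.lower().to_numpy()
        return cls(
            nagasaki=(city == "nagasaki").astype(float),
            female=(sex == "female").astype(float),
            attained_age=df["mean_age"].to_numpy(float),
            age_at_exposure=df["mean_agex"].to_numpy(float),
            dose=df["mean_dose"].to_numpy(float),
            pyr=df["pyr"].to_numpy(float),
            cases=table.cases.to_numpy(float),
        )

    @classmethod
    def from_cell(cls, cell: StratumCell) -> "CellArrays":
        return cls(
            nagasaki=np.array([1.0 if cell.city.lower() == "nagasaki" else 0.0]),
            female=np.array([1.0 if cell.sex.lower() == "female" else 0.0]),
            attained_age=np.array([cell.mean_age]),
            age_at_exposure=np.array([cell.mean_agex]),
            dose=np.array([cell.mean_dose]),
            pyr=np.array([cell.person_years]),
            cases=np.array([float(cell.cases)]),
        )

    @classmethod
    def from_covariates(cls, cov: dict) -> "CellArrays":
        c = {**REFERENCE_COVARIATES, **cov}
        return cls(
            nagasaki=np.array([1.0 if str(c["city"]).lower() == "nagasaki" else 0.0]),
            female=np.array([1.0 if str(c["sex"]).lower() == "female" else 0.0]),
            attained_age=np.array([float(c["attained_age"])]),
            age_at_exposure=np.array([float(c["age_at_exposure"])]),
            dose=np.array([0.0]),
            pyr=np.array([0.0]),
            cases=np.array([0.0]),
        )


def _as_cells(x) -> CellArrays:
    if isinstance(x, CellArrays):
        return x
    if isinstance(x, GroupedTable):
        return CellArrays.from_table(x)
    if isinstance(x, StratumCell):
        return CellArrays.from_cell(x)
    raise TypeError(f"expected CellArrays, GroupedTable or StratumCell, got {type(x)!r}")


@dataclass(frozen=True)
class BaselineParams:
    """Log-linear baseline coefficients with per-term activity flags.

    Inactive terms contribute exactly zero to the linear predictor and are
    not free parameters during fitting.  The intercept is always active.
    """

    values: dict = field(default_factory=dict)
    active: tuple[str, ...] = BASELINE_TERMS

    def __post_init__(self):
        unknown = set(self.values) - set(BASELINE_TERMS)
        if unknown:
            raise ValueError(f"unknown baseline term(s): {sorted(unknown)}")
        act = tuple(t for t in BASELINE_TERMS if t in set(self.active) | {"intercept"})
        object.__setattr__(self, "active", act)
        vals = {t: float(self.values.get(t, 0.0)) for t in BASELINE_TERMS}
        object.__setattr__(self, "values", vals)

    def deactivate(self, term: str) -> "BaselineParams":
        if term == "intercept":
            raise ValueError("the intercept cannot be deactivated")
        return BaselineParams(
            values={**self.values, term: 0.0},
            active=tuple(t for t in self.active if t != term),
        )

    def replace_values(self, **kw) -> "BaselineParams":
        return BaselineParams(values={**self.values, **kw}, active=self.active)


@dataclass(frozen=True)
class DemParams:
    """Dose-effect modifiers; with no active terms eps is identically 1."""

    values: dict = field(default_factory=dict)
    active: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.values) - set(DEM_TERMS)
        if unknown:
            raise ValueError(f"unknown DEM term(s): {sorted(unknown)}")
        act = tuple(t for t in DEM_TERMS if t in self.active)
        object.__setattr__(self, "active", act)
        vals = {t: float(self.values.get(t, 0.0)) for t in DEM_TERMS}
        object.__setattr__(self, "values", vals)

    def activate(self, term: str, value: float = 0.0) -> "DemParams":
        return DemParams(values={**self.values, term: value},
                         active=tuple(self.active) + (term,))

    def replace_values(self, **kw) -> "DemParams":
        return DemParams(values={**self.values, **kw}, active=self.active)


@dataclass(frozen=True)
class HazardModel:
    transfer: str
    baseline: BaselineParams
    dose_response: DoseResponseSpec
    dems: DemParams = field(default_factory=DemParams)

    def __post_init__(self):
        if self.transfer not in TRANSFERS:
            raise ValueError(f"transfer must be one of {TRANSFERS}")

    def replace(self, **kw) -> "HazardModel":
        return dataclasses.replace(self, **kw)


def _linear_predictor(baseline: BaselineParams, cells: CellArrays) -> np.ndarray:
    la = np.log(cells.attained_age / 70.0)
    xe = (cells.age_at_exposure - 30.0) / 10.0
    design = {
        "intercept": 1.0,
        "city": cells.nagasaki,
        "sex": cells.female,
        "log_age": la,
        "log_age_sq": la**2,
        "age_at_exposure": xe,
        "sex_log_age": cells.female * la,
    }
    eta = np.zeros_like(cells.attained_age)
    for term in baseline.active:
        eta = eta + baseline.values[term] * design[term]
    return eta


def baseline_hazard(baseline: BaselineParams, cells) -> np.ndarray:
    """Baseline hazard per person-year; strictly positive, log-linear."""
    cells = _as_cells(cells)
    if not np.isfinite(cells.attained_age).all() or np.any(cells.attained_age <= 0):
        raise ValueError("attained age must be positive and finite")
    return np.exp(_linear_predictor(baseline, cells))


def dem_factor(dems: DemParams, cells) -> np.ndarray:
    cells = _as_cells(cells)
    eps = np.ones_like(cells.attained_age)
    if "sex" in dems.active:
        eps = eps * np.exp(dems.values["sex"] * cells.female)
    if "attained_age" in dems.active:
        eps = eps * (cells.attained_age / 70.0) ** dems.values["attained_age"]
    if "age_at_exposure" in dems.active:
        eps = eps * np.exp(dems.values["age_at_exposure"] * (cells.age_at_exposure - 30.0) / 10.0)
    return eps


def excess_term(model: HazardModel, cells) -> np.ndarray:
    """err(D) * eps  (ERR transfer)  or  ear(D) * eps  (EAR transfer)."""
    cells = _as_cells(cells)
    return evaluate(model.dose_response, cells.dose) * dem_factor(model.dems, cells)


def total_hazard(model: HazardModel, cells, strict: bool = True) -> np.ndarray:
    """Total hazard per person-year; equals the baseline exactly at D = 0.

    Under the ERR transfer, cells where ``1 + err * eps <= 0`` make the
    hazard non-positive; with ``strict`` a :class:`HazardPositivityError` is
    raised, otherwise the offending values are returned for the caller (the
    fitting penalty) to handle.
    """
    cells = _as_cells(cells)
    h0 = baseline_hazard(model.baseline, cells)
    ex = excess_term(model, cells)
    if model.transfer == "ERR":
        h = h0 * (1.0 + ex)
        if strict and np.any(1.0 + ex <= 0):
            raise HazardPositivityError(
                f"1 + ERR <= 0 on {int(np.sum(1.0 + ex <= 0))} cell(s)"
            )
        return h
    return h0 + ex


def expected_cases(model: HazardModel, cells, strict: bool = True) -> np.ndarray:
    """Poisson mean per cell: total hazard times person-years."""
    cells = _as_cells(cells)
    return total_hazard(model, cells, strict=strict) * cells.pyr
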