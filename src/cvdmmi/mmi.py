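"""Information-criterion weighting and multi-model inference (MMI).

Given a set of final non-nested fitted models ("Occam's group"), MMI forms

* per-model information criteria, AIC = dev + 2 * Npar or
  BIC = dev + Npar * ln(n) with n the endpoint death count,
* normalized weights w_i proportional to exp(-0.5 * IC_i), computed from
  criterion differences for numerical stability,
* a weighted central risk curve, and
* a merged uncertainty distribution: each member contributes
  round(w_i * total_draws) multivariate-normal parameter draws (MLE,
  Wald covariance), every draw is converted to a risk curve, and the pooled
  curves yield empirical 2.5/97.5 percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import evaluate
from .fitting import FittedModel, with_free
from .hazard_model import (CellArrays, REFERENCE_COVARIATES, baseline_hazard,
                           dem_factor)

CRITERIA = ("AIC", "BIC")


def information_criterion(dev: float, npar: int, criterion: str = "AIC",
                          n: int | None = None) -> float:
    """AIC or BIC from a deviance and a free-parameter count."""
    if dev < 0:
        raise ValueError("deviance must be non-negative")
    if npar < 1:
        raise ValueError("Npar must be >= 1")
    if criterion == "AIC":
        return float(dev + 2.0 * npar)
    if criterion == "BIC":
        if n is None or n < 2:
            raise ValueError("BIC requires the observation count n >= 2")
        return float(dev + npar * np.log(n))
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")


@dataclass
class WeightedGroup:
    """Members of Occam's group with their criterion values and weights."""

    names: list[str]
    members: list[FittedModel | None]
    dev: np.ndarray
    npar: np.ndarray
    criterion: str
    ic: np.ndarray
    delta_ic: np.ndarray
    weights: np.ndarray
    n: int | None = None

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.names, "dev": self.dev, "npar": self.npar,
            self.criterion: self.ic, f"delta_{self.criterion}": self.delta_ic,
            f"{self.criterion.lower()}_weight": self.weights,
        })


def ic_weights(members, criterion: str = "AIC", n: int | None = None,
               names: list[str] | None = None) -> WeightedGroup:
    """Criterion weights for a model set.

    ``members`` is a list of :class:`FittedModel` or of ``(dev, npar)``
    pairs (the latter lets published deviance tables be weighted directly).
    Weights are ``exp(-0.5 * delta_IC)`` normalized to one; they are
    invariant under adding any constant to all criterion values.
    """
    if len(members) == 0:
        raise ValueError("need at least one member")
    fits: list[FittedModel | None] = []
    dev, npar = [], []
    for m in members:
        if isinstance(m, FittedModel):
            fits.append(m)
            dev.append(m.deviance)
            npar.append(m.npar)
        else:
            d, k = m
            fits.append(None)
            dev.append(float(d))
            npar.append(int(k))
    dev = np.asarray(dev)
    npar = np.asarray(npar)
    ic = np.array([information_criterion(d, k, criterion, n) for d, k in zip(dev, npar)])
    delta = ic - ic.min()
    raw = np.exp(-0.5 * delta)
    w = raw / raw.sum()
    if names is None:
        names = [
            f.model.transfer + "-" + f.model.dose_response.family if f is not None else f"model_{i}"
            for i, f in enumerate(fits)
        ]
    return WeightedGroup(list(names), fits, dev, npar, criterion, ic, delta, w, n)


# ---------------------------------------------------------------------------
# risk curves


def _risk_curve(model, doses: np.ndarray, cov_cells: CellArrays, scale: str) -> np.ndarray:
    """Risk (ERR or EAR scale) versus dose at fixed reporting covariates.

    ERR and EAR are interconverted through the member's own fitted baseline
    at those covariates: EAR = h0 * ERR.
    """
    err_or_ear = evaluate(model.dose_response, doses) * float(dem_factor(model.dems, cov_cells)[0])
    if scale not in ("ERR", "EAR"):
        raise ValueError("scale must be 'ERR' or 'EAR'")
    if model.transfer == scale:
        return np.asarray(err_or_ear, dtype=float)
    h0 = float(baseline_hazard(model.baseline, cov_cells)[0])
    if model.transfer == "ERR":  # requested EAR
        return np.asarray(err_or_ear, dtype=float) * h0
    return np.asarray(err_or_ear, dtype=float) / h0


def member_curve(fit: FittedModel, doses, covariates: dict | None = None,
                 scale: str = "ERR") -> np.ndarray:
    """Central risk curve of one member at its MLE."""
    cov_cells = CellArrays.from_covariates(covariates or {})
    return _risk_curve(fit.model, np.asarray(doses, dtype=float), cov_cells, scale)


def mmi_central(group: WeightedGroup, doses, covariates: dict | None = None,
                scale: str = "ERR") -> np.ndarray:
    """Weight-averaged central risk curve over the group."""
    doses = np.asarray(doses, dtype=float)
    out = np.zeros_like(doses)
    for w, fit in zip(group.weights, group.members):
        if fit is None:
            raise ValueError("mmi_central requires fitted members (with parameters)")
        out = out + w * member_curve(fit, doses, covariates, scale)
    return out


def allocate_draws(weights: np.ndarray, total: int) -> np.ndarray:
    """Per-member sample counts: round(w_i * total), residual to the
    highest-weight member so the pool size equals ``total`` exactly."""
    counts = np.round(np.asarray(weights) * total).astype(int)
    counts[int(np.argmax(weights))] += total - counts.sum()
    return counts


def wald_simulate(fit: FittedModel, doses, covariates: dict | None = None,
                  scale: str = "ERR", n_draws: int = 10_000, seed: int = 0,
                  name: str = "") -> np.ndarray:
    """Monte-Carlo risk curves from the member's Wald covariance.

    Draws parameter vectors from N(MLE, cov) honouring the parameter
    correlations, and evaluates the risk curve per draw.  Deterministic
    given the seed.
    """
    doses = np.asarray(doses, dtype=float)
    cov = np.asarray(fit.cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError(f"member {name or fit.model.dose_response.family}: covariance not finite")
    evals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError(
            f"member {name or fit.model.dose_response.family}: covariance not positive semi-definite"
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.mle, cov, size=n_draws, method="svd")
    cov_cells = CellArrays.from_covariates(covariates or {})
    out = np.empty((n_draws, len(doses)))
    for i in range(n_draws):
        m = with_free(fit.model, fit.param_names, draws[i])
        out[i] = _risk_curve(m, doses, cov_cells, scale)
    return out


@dataclass
class RiskSurface:
    """Central curves and merged percentile bands of risk versus dose."""

    doses: np.ndarray
    central: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    per_model: dict = field(default_factory=dict)
    scale: str = "ERR"
    covariates: dict = field(default_factory=dict)
    n_draws: int = 0
    draw_counts: dict = field(default_factory=dict)
    n_err_below_neg1: int = 0
    pool: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dose": self.doses, "central": self.central,
                           "lo95": self.lo95, "hi95": self.hi95})
        for name, curve in self.per_model.items():
            df[name] = curve
        return df


def simulate_uncertainty(group: WeightedGroup, doses, covariates: dict | None = None,
                         scale: str = "ERR", total_draws: int = 10_000,
                         seed: int = 0, keep_pool: bool = False) -> RiskSurface:
    """Merged MMI uncertainty bands.

    Member i contributes ``round(w_i * total_draws)`` Wald draws simulated
    with seed ``seed + i``; the merged pool's empirical 2.5/97.5 percentiles
    per grid dose form the 95% CI.  Draws whose ERR falls below -1 anywhere
    on the grid (negative total hazard) are retained but counted in
    ``n_err_below_neg1``.
    """
    doses = np.asarray(doses, dtype=float)
    covs = {**REFERENCE_COVARIATES, **(covariates or {})}
    counts = allocate_draws(group.weights, total_draws)
    pools = []
    per_model = {}
    n_bad = 0
    for i, (name, fit, nd) in enumerate(zip(group.names, group.members, counts)):
        if fit is None:
            raise ValueError(f"member {name} has no fitted parameters")
        per_model[name] = member_curve(fit, doses, covs, scale)
        if nd > 0:
            block = wald_simulate(fit, doses, covs, scale, n_draws=int(nd),
                                  seed=seed + i, name=name)
            pools.append(block)
    pool = np.vstack(pools)
    if scale == "ERR":
        n_bad = int(np.sum(pool.min(axis=1) < -1.0))
    lo, hi = np.percentile(pool, [2.5, 97.5], axis=0)
    central = mmi_central(group, doses, covs, scale)
    return RiskSurface(
        doses=doses, central=central, lo95=lo, hi95=hi, per_model=per_model,
        scale=scale, covariates=covs, n_draws=int(pool.shape[0]),
        draw_counts=dict(zip(group.names, map(int, counts))),
        n_err_below_neg1=n_bad, pool=pool if keep_pool else None,
    )
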