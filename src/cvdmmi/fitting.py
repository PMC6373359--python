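"""Poisson-likelihood machinery: deviance, MLE, Wald covariance, LRT.

The grouped Poisson deviance is ``2 * sum[O * ln(O/E) - (O - E)]`` with the
saturated-model convention ``O * ln(O/E) := 0`` when ``O = 0``.  Fits
minimize this deviance with a quasi-Newton optimizer (L-BFGS-B, numerical
derivatives) inside box bounds, with a deterministic multi-start grid over
threshold doses for the non-smooth threshold families, followed by a
simplex polish.  The Wald covariance of the free parameters is twice the
inverse Hessian of the deviance at the MLE.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .dose_response import DOSE_RANGE
from .hazard_model import CellArrays, HazardModel, _as_cells, expected_cases

#: Finite stand-in for the infinite positivity penalty, so line searches can
#: recover from an excursion into 1 + ERR <= 0 territory.
PENALTY_DEV = 1e12

#: Characteristic size of EAR-scale magnitude parameters (hazard per PY per
#: Gy); fitting works in coordinates divided by the parameter scale.
EAR_MAGNITUDE_SCALE = 1e-4

DEFAULT_DTH_GRID = np.linspace(*DOSE_RANGE, 21)

_BASELINE_BOUNDS = {"intercept": (-30.0, 10.0)}
_BASELINE_BOUNDS_OTHER = (-15.0, 15.0)
_DEM_BOUNDS = {"sex": (-5.0, 5.0), "attained_age": (-15.0, 15.0),
               "age_at_exposure": (-5.0, 5.0)}


@dataclass(frozen=True)
class FreeParam:
    name: str          # e.g. "bl:intercept", "dr:beta", "dem:attained_age"
    value: float
    bounds: tuple[float, float]
    scale: float = 1.0


def free_parameters(model: HazardModel) -> list[FreeParam]:
    """Flatten a model into its ordered free-parameter list.

    Order: active baseline terms, dose-response parameters (excluding fixed
    ones such as the pure step's smoothness), active DEM terms.  EAR-scale
    magnitude parameters get a small characteristic scale so the optimizer
    sees O(1) coordinates; bounds stay in natural units.
    """
    out: list[FreeParam] = []
    for term in model.baseline.active:
        out.append(FreeParam(
            f"bl:{term}", model.baseline.values[term],
            _BASELINE_BOUNDS.get(term, _BASELINE_BOUNDS_OTHER),
        ))
    ear = model.transfer == "EAR"
    for pd_ in model.dose_response.param_defs():
        if pd_.fixed:
            continue
        if pd_.kind == "magnitude" and ear:
            lo, hi = (-0.05, 0.05) if pd_.bounds[0] < 0 else (0.0, 0.05)
            out.append(FreeParam(f"dr:{pd_.name}",
                                 model.dose_response.params[pd_.name],
                                 (lo, hi), scale=EAR_MAGNITUDE_SCALE))
        else:
            out.append(FreeParam(f"dr:{pd_.name}",
                                 model.dose_response.params[pd_.name], pd_.bounds))
    for term in model.dems.active:
        out.append(FreeParam(f"dem:{term}", model.dems.values[term], _DEM_BOUNDS[term]))
    return out


def with_free(model: HazardModel, names: list[str], values: np.ndarray) -> HazardModel:
    """Return a copy of the model with the named free parameters set."""
    bl, dr, dem = {}, {}, {}
    for name, v in zip(names, values):
        group, key = name.split(":", 1)
        {"bl": bl, "dr": dr, "dem": dem}[group][key] = float(v)
    m = model
    if bl:
        m = m.replace(baseline=m.baseline.replace_values(**bl))
    if dr:
        m = m.replace(dose_response=m.dose_response.replace(**dr))
    if dem:
        m = m.replace(dems=m.dems.replace_values(**dem))
    return m


def deviance_from_counts(observed, expected) -> float:
    """Closed-form grouped Poisson deviance.

    Infinite when any expected count is non-positive while cases were
    observed (the hazard-positivity penalty during ERR fits).
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if np.any(~np.isfinite(E)) or np.any((E <= 0) & (O > 0)):
        return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(O > 0, O * np.log(np.where(O > 0, O, 1.0) / np.where(E > 0, E, 1.0)), 0.0)
    return float(2.0 * np.sum(term - (O - E)))


def poisson_deviance(model: HazardModel, table) -> float:
    """Deviance of a hazard model against a grouped table."""
    cells = _as_cells(table)
    E = expected_cases(model, cells, strict=False)
    return deviance_from_counts(cells.cases, E)


@dataclass(frozen=True)
class LrtDecision:
    delta_dev: float
    extra_params: int
    cutoff: float
    significant: bool


def lrt_improves(dev_reduced: float, dev_full: float, extra_params: int,
                 alpha: float = 0.05, tol: float = 1e-6) -> LrtDecision:
    """Likelihood-ratio test for a nested model pair.

    The extension is significant when the deviance drops by at least the
    0.95 chi-square quantile for the number of added parameters, stated in
    the protocol at two decimals (3.84 for one parameter, 5.99 for two);
    the boundary counts as significant ("at least").
    """
    if extra_params < 1:
        raise ValueError("extra_params must be >= 1")
    delta = dev_reduced - dev_full
    if delta < -tol:
        raise ValueError(
            f"full model fits worse than its reduction (delta = {delta:.3g}); refit ordering error"
        )
    cutoff = round(float(stats.chi2.ppf(1.0 - alpha, extra_params)), 2)
    return LrtDecision(float(delta), int(extra_params), cutoff, bool(delta >= cutoff))


@dataclass
class FittedModel:
    """A hazard model at its MLE with Wald covariance and fit metadata."""

    model: HazardModel
    param_names: list[str]
    mle: np.ndarray
    cov: np.ndarray
    deviance: float
    npar: int
    converged: bool
    boundary: bool = False          # threshold pinned at the dose-range edge
    cov_reliable: bool = True
    n_iter: int = 0
    message: str = ""
    start: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        d = np.diag(self.cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, map(float, self.mle)))

    def aic(self) -> float:
        return self.deviance + 2.0 * self.npar

    def to_record(self) -> dict:
        return {
            "transfer": self.model.transfer,
            "family": self.model.dose_response.family,
            "param_names": list(self.param_names),
            "mle": [float(v) for v in self.mle],
            "se": [float(v) for v in self.se],
            "cov": [[float(v) for v in row] for row in self.cov],
            "deviance": float(self.deviance),
            "npar": int(self.npar),
            "aic": float(self.aic()),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "cov_reliable": bool(self.cov_reliable),
        }


def _objective(template: HazardModel, names, scales, cells: CellArrays, zbounds):
    zlo = np.array([b[0] for b in zbounds])
    zhi = np.array([b[1] for b in zbounds])

    def dev_z(z):
        # clip: derivative probes and the simplex polish may step just
        # outside the box
        zc = np.clip(np.asarray(z, dtype=float), zlo, zhi)
        m = with_free(template, names, zc * scales)
        E = expected_cases(m, cells, strict=False)
        d = deviance_from_counts(cells.cases, E)
        return d if np.isfinite(d) else PENALTY_DEV
    return dev_z


def _minimize(dev_z, z0, zbounds, maxiter):
    res = optimize.minimize(
        dev_z, z0, method="L-BFGS-B", bounds=zbounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    return res


def fit_mle(
    template: HazardModel,
    table,
    start: dict | None = None,
    bounds: dict | None = None,
    dth_grid: np.ndarray | None = None,
    polish: bool | None = None,
    maxiter: int = 1000,
) -> FittedModel:
    """Maximum-likelihood fit of a hazard model to a grouped table.

    ``start``/``bounds`` override individual free parameters by name
    (``"dr:beta"`` etc.).  Families with a free threshold are profiled over
    a deterministic 21-point grid on the observed dose range before the
    threshold is released, because their likelihood is only piecewise smooth
    in the threshold; ``polish`` (default: on exactly for those families)
    adds a Nelder-Mead refinement.  Non-convergence is flagged on the
    result, never silently hidden.
    """
    cells = _as_cells(table)
    free = free_parameters(template)
    # data-driven intercept start when the template carries no opinion
    if (start is None or "bl:intercept" not in start):
        tot_py = float(cells.pyr.sum())
        tot_cases = float(cells.cases.sum())
        for i, p in enumerate(free):
            if p.name == "bl:intercept" and p.value == 0.0 and tot_py > 0 and tot_cases > 0:
                free[i] = dataclasses.replace(p, value=float(np.log(tot_cases / tot_py)))
    if start:
        free = [dataclasses.replace(p, value=float(start[p.name])) if p.name in start else p
                for p in free]
    if bounds:
        free = [dataclasses.replace(p, bounds=tuple(bounds[p.name])) if p.name in bounds else p
                for p in free]
    names = [p.name for p in free]
    scales = np.array([p.scale for p in free])
    x0 = np.array([p.value for p in free])
    xb = [p.bounds for p in free]
    z0 = x0 / scales
    zb = [(lo / s, hi / s) for (lo, hi), s in zip(xb, scales)]
    z0 = np.clip(z0, [b[0] for b in zb], [b[1] for b in zb])

    dev_z = _objective(template, names, scales, cells, zb)

    has_dth = "dr:dth" in names
    if polish is None:
        polish = has_dth

    if has_dth and dth_grid is None:
        dth_grid = DEFAULT_DTH_GRID
    best = None
    nit = 0
    if has_dth and len(dth_grid) > 0:
        i_dth = names.index("dr:dth")
        lo, hi = zb[i_dth]
        for d in dth_grid:
            zd = float(np.clip(d / scales[i_dth], lo, hi))
            z_try = z0.copy()
            z_try[i_dth] = zd
            zb_pin = list(zb)
            zb_pin[i_dth] = (zd, zd)
            res = _minimize(dev_z, z_try, zb_pin, maxiter=300)
            nit += res.nit
            if best is None or res.fun < best.fun:
                best = res
        # release the threshold and polish from the best grid point
        res = _minimize(dev_z, best.x, zb, maxiter=maxiter)
        nit += res.nit
        if res.fun <= best.fun:
            best = res
    else:
        best = _minimize(dev_z, z0, zb, maxiter=maxiter)
        nit = best.nit

    if polish:
        res = optimize.minimize(
            dev_z, best.x, method="Nelder-Mead",
            options={"maxiter": 400 * len(names), "xatol": 1e-8, "fatol": 1e-9},
        )
        z_cl = np.clip(res.x, [b[0] for b in zb], [b[1] for b in zb])
        if dev_z(z_cl) < best.fun:
            best = optimize.OptimizeResult(x=z_cl, fun=dev_z(z_cl),
                                           success=True, nit=best.nit + res.nit,
                                           message="NM polish")

    zhat = np.asarray(best.x, dtype=float)
    xhat = zhat * scales
    dev = float(dev_z(zhat))
    converged = bool(getattr(best, "success", True)) and dev < PENALTY_DEV / 2

    # Wald covariance: 2 * inverse Hessian of the deviance at the MLE.
    boundary = False
    if has_dth:
        i_dth = names.index("dr:dth")
        d = xhat[i_dth]
        boundary = bool(d <= DOSE_RANGE[0] + 1e-6 or d >= DOSE_RANGE[1] - 1e-6)
    cov_reliable = converged and not boundary
    try:
        H = approx_hess1(zhat, dev_z)
        H = 0.5 * (H + H.T)
        cov_z = 2.0 * np.linalg.pinv(H)
        cov_z = 0.5 * (cov_z + cov_z.T)
        if np.any(np.diag(cov_z) < -1e-8):
            cov_reliable = False
        cov = cov_z * np.outer(scales, scales)
    except Exception:  # Hessian evaluation failed entirely
        cov = np.full((len(names), len(names)), np.nan)
        cov_reliable = False

    model_hat = with_free(template, names, xhat)
    return FittedModel(
        model=model_hat, param_names=names, mle=xhat, cov=cov, deviance=dev,
        npar=len(names), converged=converged, boundary=boundary,
        cov_reliable=cov_reliable, n_iter=int(nit),
        message=str(getattr(best, "message", "")), start=x0,
    )
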