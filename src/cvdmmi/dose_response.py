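"""Dose-response families err(D) / ear(D).

Thirteen shapes are registered, covering linear, supra-linear, sub-linear,
threshold, step-like and J-shaped (protective-dip) behaviour:

======================  ====================================================
family                  form (all shifted so err(0) = 0 exactly)
======================  ====================================================
lnt                     beta * D
q                       beta * D**2
lq                      beta1 * D + beta2 * D**2
le                      beta * D * exp(-gamma * D)
lth                     beta * max(0, D - dth)
step                    A * (1 + tanh((D - dth)/w)) / 2, w fixed small
smooth_step             same, smoothness w free (>= 0.01 Gy)
step_linear             smooth step plus a linear term beta * D
sigmoid                 A / (1 + exp(-(D - dth)/w))
hockey_stick            plateau c (ramped over 5 mGy) then slope beta above dth
hormesis                (c*D + beta*D**2) / (1 + theta*D)  (Brain-Cousens type)
two_line_spline         two joined line segments, free knee dth
categorical             one free level per dose category, reference level 0
                        below 0.005 Gy
======================  ====================================================

The step-type forms are modified hyperbolic tangents, so a step is not
imposed a priori but emerges when the data support one.  Threshold
parameters ``dth`` are free on the observed dose range [0, 4] Gy.  The
hormesis form allows a protective dip below zero at low dose (c < 0) before
rising; its NOAEL (no-observed-adverse-effect level) is the dose at which
the response returns to zero from below.

Several exact parameter restrictions make one family a special case of
another (e.g. ``lth`` with dth = 0 is ``lnt``); the model-selection module
relies on these identities, which are property-tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

#: Fixed smoothness (Gy) of the pure step model; small enough that the
#: transition is complete within one dose category.
STEP_FIXED_W = 0.01
#: Equivalent sigmoid smoothness realizing the step (tanh(x/w) form equals a
#: logistic with half the width).
SIGMOID_STEP_W = STEP_FIXED_W / 2.0
#: Ramp width (Gy) over which the hockey-stick plateau is attained from zero;
#: below the lowest nonzero dose category so it never affects fitted cells.
HOCKEY_RAMP = 0.005
#: Dose below which the categorical model assigns zero risk by convention.
CATEGORICAL_ZERO_BELOW = 0.005

#: Dose range (Gy) of the data; thresholds are constrained to it.
DOSE_RANGE = (0.0, 4.0)


@dataclass(frozen=True)
class ParamDef:
    """Definition of one family parameter.

    ``kind`` is ``"magnitude"`` for parameters carrying the risk scale
    (rescaled when the family is used on the absolute-risk EAR scale) and
    ``"shape"`` for doses/smoothness/rates, which keep their units.
    """

    name: str
    default: float
    bounds: tuple[float, float]
    kind: str = "magnitude"
    fixed: bool = False


@dataclass(frozen=True)
class Family:
    name: str
    params: tuple[ParamDef, ...]
    fn: Callable[[np.ndarray, dict], np.ndarray]

    def param(self, name: str) -> ParamDef:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)


def _shifted_tanh(D, A, dth, w):
    val = A * (1.0 + np.tanh((D - dth) / w)) / 2.0
    val0 = A * (1.0 + np.tanh((0.0 - dth) / w)) / 2.0
    return val - val0


def _shifted_logistic(D, A, dth, w):
    val = A * expit((D - dth) / w)
    val0 = A * expit(-dth / w)
    return val - val0


def _fn_lnt(D, p):
    return p["beta"] * D


def _fn_q(D, p):
    return p["beta"] * D**2


def _fn_lq(D, p):
    return p["beta1"] * D + p["beta2"] * D**2


def _fn_le(D, p):
    return p["beta"] * D * np.exp(-p["gamma"] * D)


def _fn_lth(D, p):
    return p["beta"] * np.maximum(0.0, D - p["dth"])


def _fn_step(D, p):
    return _shifted_tanh(D, p["A"], p["dth"], STEP_FIXED_W)


def _fn_smooth_step(D, p):
    return _shifted_tanh(D, p["A"], p["dth"], p["w"])


def _fn_step_linear(D, p):
    return _shifted_tanh(D, p["A"], p["dth"], p["w"]) + p["beta"] * D


def _fn_sigmoid(D, p):
    return _shifted_logistic(D, p["A"], p["dth"], p["w"])


def _fn_hockey_stick(D, p):
    ramp = p["c"] * np.minimum(D, HOCKEY_RAMP) / HOCKEY_RAMP
    return ramp + p["beta"] * np.maximum(0.0, D - p["dth"])


def _fn_hormesis(D, p):
    return (p["c"] * D + p["beta"] * D**2) / (1.0 + p["theta"] * D)


def _fn_two_line_spline(D, p):
    return p["beta1"] * np.minimum(D, p["dth"]) + p["beta2"] * np.maximum(0.0, D - p["dth"])


def _fn_categorical(D, p, edges):
    # level_0 (reference, D below CATEGORICAL_ZERO_BELOW) is fixed at 0.
    levels = np.array([0.0] + [p[f"level_{i}"] for i in range(1, len(edges) + 1)])
    idx = np.searchsorted(np.asarray(edges), D, side="right")
    return levels[idx]


# Magnitude bounds keep the ERR transfer hazard-positive on [0, 4] Gy for a
# single active term (1 + err > 0); joint violations are handled by the
# fitting penalty.
_B_LIN = (-0.28, 10.0)      # slope per Gy
_B_QUAD = (-0.08, 10.0)     # curvature per Gy^2
_B_LEVEL = (-0.95, 10.0)    # plateau / step heights
_B_DTH = (*DOSE_RANGE,)
_B_W = (0.01, 4.0)

FAMILIES: dict[str, Family] = {
    f.name: f
    for f in (
        Family("lnt", (ParamDef("beta", 0.1, _B_LIN),), _fn_lnt),
        Family("q", (ParamDef("beta", 0.05, _B_QUAD),), _fn_q),
        Family(
            "lq",
            (ParamDef("beta1", 0.05, _B_LIN), ParamDef("beta2", 0.02, _B_QUAD)),
            _fn_lq,
        ),
        Family(
            "le",
            (ParamDef("beta", 0.1, _B_LIN), ParamDef("gamma", 0.1, (0.0, 10.0), "shape")),
            _fn_le,
        ),
        Family(
            "lth",
            (ParamDef("beta", 0.1, _B_LIN), ParamDef("dth", 0.5, _B_DTH, "shape")),
            _fn_lth,
        ),
        Family(
            "step",
            (
                ParamDef("A", 0.1, _B_LEVEL),
                ParamDef("dth", 1.0, _B_DTH, "shape"),
                ParamDef("w", STEP_FIXED_W, (STEP_FIXED_W, STEP_FIXED_W), "shape", fixed=True),
            ),
            _fn_step,
        ),
        Family(
            "smooth_step",
            (
                ParamDef("A", 0.1, _B_LEVEL),
                ParamDef("dth", 1.0, _B_DTH, "shape"),
                ParamDef("w", 0.3, _B_W, "shape"),
            ),
            _fn_smooth_step,
        ),
        Family(
            "step_linear",
            (
                ParamDef("A", 0.1, _B_LEVEL),
                ParamDef("dth", 1.0, _B_DTH, "shape"),
                ParamDef("w", 0.3, _B_W, "shape"),
                ParamDef("beta", 0.02, _B_LIN),
            ),
            _fn_step_linear,
        ),
        Family(
            "sigmoid",
            (
                ParamDef("A", 0.1, _B_LEVEL),
                ParamDef("dth", 1.0, _B_DTH, "shape"),
                ParamDef("w", 0.3, (SIGMOID_STEP_W, 4.0), "shape"),
            ),
            _fn_sigmoid,
        ),
        Family(
            "hockey_stick",
            (
                ParamDef("c", 0.0, _B_LEVEL),
                ParamDef("dth", 0.5, _B_DTH, "shape"),
                ParamDef("beta", 0.1, _B_LIN),
            ),
            _fn_hockey_stick,
        ),
        Family(
            "hormesis",
            (
                ParamDef("c", -0.05, _B_LIN),
                ParamDef("beta", 0.1, _B_QUAD),
                ParamDef("theta", 0.0, (0.0, 10.0), "shape"),
            ),
            _fn_hormesis,
        ),
        Family(
            "two_line_spline",
            (
                ParamDef("beta1", 0.05, (-5.0, 10.0)),
                ParamDef("dth", 0.5, _B_DTH, "shape"),
                ParamDef("beta2", 0.1, (-5.0, 10.0)),
            ),
            _fn_two_line_spline,
        ),
        # categorical is special-cased: its parameters depend on the edges.
        Family("categorical", (), _fn_categorical),  # type: ignore[arg-type]
    )
}

#: Nestedness edges (reduced family -> extended family) with the exact
#: parameter restriction realizing the nesting, used for warm starts.
NESTED_EDGES: tuple[tuple[str, str], ...] = (
    ("lnt", "lq"),
    ("q", "lq"),
    ("lnt", "le"),
    ("lnt", "lth"),
    ("lnt", "two_line_spline"),
    ("lth", "two_line_spline"),
    ("step", "smooth_step"),
    ("smooth_step", "step_linear"),
    ("step", "sigmoid"),
)

#: Embeddings: parameters of the extension that reproduce the reduction.
NESTED_EMBEDDINGS: dict[tuple[str, str], Callable[[dict], dict]] = {
    ("lnt", "lq"): lambda p: {"beta1": p["beta"], "beta2": 0.0},
    ("q", "lq"): lambda p: {"beta1": 0.0, "beta2": p["beta"]},
    ("lnt", "le"): lambda p: {"beta": p["beta"], "gamma": 0.0},
    ("lnt", "lth"): lambda p: {"beta": p["beta"], "dth": 0.0},
    ("lnt", "two_line_spline"): lambda p: {"beta1": p["beta"], "dth": 0.5, "beta2": p["beta"]},
    ("lth", "two_line_spline"): lambda p: {"beta1": 0.0, "dth": p["dth"], "beta2": p["beta"]},
    ("step", "smooth_step"): lambda p: {"A": p["A"], "dth": p["dth"], "w": STEP_FIXED_W},
    ("smooth_step", "step_linear"): lambda p: {"A": p["A"], "dth": p["dth"], "w": p["w"], "beta": 0.0},
    ("step", "sigmoid"): lambda p: {"A": p["A"], "dth": p["dth"], "w": SIGMOID_STEP_W},
}


@dataclass(frozen=True)
class DoseResponseSpec:
    """One dose-response family with a concrete named parameter vector."""

    family: str
    params: dict
    category_edges: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown dose-response family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))
        self.validate()

    # -- parameter bookkeeping --------------------------------------------
    def param_defs(self) -> tuple[ParamDef, ...]:
        if self.family == "categorical":
            if not self.category_edges:
                raise ValueError("categorical family requires category_edges")
            return tuple(
                ParamDef(f"level_{i}", 0.0, _B_LEVEL)
                for i in range(1, len(self.category_edges) + 1)
            )
        return FAMILIES[self.family].params

    def validate(self) -> None:
        defs = self.param_defs()
        names = {d.name for d in defs}
        missing = names - set(self.params)
        if missing:
            raise ValueError(f"{self.family}: missing parameter(s) {sorted(missing)}")
        for d in defs:
            v = self.params[d.name]
            if not np.isfinite(v):
                raise ValueError(f"{self.family}: parameter {d.name} is not finite")
            if d.name == "dth" and v < 0:
                raise ValueError(f"{self.family}: threshold dth must be >= 0")
            if d.name in ("w", "theta", "gamma") and v < 0:
                raise ValueError(f"{self.family}: shape parameter {d.name} must be >= 0")
        if self.family != "categorical" and self.category_edges is not None:
            raise ValueError("category_edges only apply to the categorical family")

    def replace(self, **params) -> "DoseResponseSpec":
        return dataclasses.replace(self, params={**self.params, **params})

    @classmethod
    def default(cls, family: str, category_edges: Sequence[float] | None = None,
                **overrides) -> "DoseResponseSpec":
        """Spec with the family's registry defaults, optionally overridden."""
        if family == "categorical":
            edges = tuple(category_edges or ())
            if not edges:
                raise ValueError("categorical family requires category_edges")
            params = {f"level_{i}": 0.0 for i in range(1, len(edges) + 1)}
            params.update(overrides)
            return cls(family, params, category_edges=edges)
        params = {d.name: d.default for d in FAMILIES[family].params}
        params.update(overrides)
        return cls(family, params)


def evaluate(spec: DoseResponseSpec, D) -> np.ndarray | float:
    """Evaluate err(D); vectorizes over D and is exactly 0 at D = 0."""
    Da = np.asarray(D, dtype=float)
    if np.any(Da < 0):
        raise ValueError("dose must be non-negative")
    if spec.family == "categorical":
        out = _fn_categorical(Da, spec.params, spec.category_edges)
    else:
        out = FAMILIES[spec.family].fn(Da, spec.params)
    out = np.where(Da == 0.0, 0.0, out)  # enforce err(0)=0 exactly
    return float(out) if out.ndim == 0 else out


def _first_sign_change(spec, grid):
    # A genuine crossing needs a sign change; exact zeros without one (e.g.
    # the flat zero segment of a threshold model) do not count.
    vals = evaluate(spec, grid)
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a * b < 0:
            return grid[i], grid[i + 1]
        if b == 0.0 and i + 2 < len(grid) and a * vals[i + 2] < 0:
            return grid[i + 1], grid[i + 1]
    return None


def zero_crossing(spec: DoseResponseSpec, lo: float = 0.0, hi: float = DOSE_RANGE[1],
                  tol: float = 1e-6) -> float | None:
    """Smallest D > 0 in (lo, hi] where err crosses zero (bisection to tol).

    Returns None when err has no sign change on the interval (e.g. any
    strictly positive response).
    """
    if not (hi > lo >= 0):
        raise ValueError("invalid search interval")
    start = max(lo, 1e-9) + tol
    grid = np.linspace(start, hi, 4001)
    hit = _first_sign_change(spec, grid)
    if hit is None:
        return None
    a, b = hit
    if a == b:
        return float(a)
    return float(brentq(lambda d: evaluate(spec, d), a, b, xtol=tol))


def noael(spec: DoseResponseSpec, hi: float = DOSE_RANGE[1], tol: float = 1e-6) -> float | None:
    """No-observed-adverse-effect level: dose where a dipping response
    returns to zero from below.

    Returns None for responses that never go negative on (0, hi].
    """
    grid = np.linspace(tol, hi, 4001)
    vals = evaluate(spec, grid)
    neg = np.nonzero(vals < -1e-12)[0]
    if len(neg) == 0:
        return None
    i0 = neg[0]
    rest = np.nonzero(vals[i0:] >= 0)[0]
    if len(rest) == 0:
        return None
    j = i0 + rest[0]
    if vals[j] == 0.0:
        return float(grid[j])
    return float(brentq(lambda d: evaluate(spec, d), grid[j - 1], grid[j], xtol=tol))
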