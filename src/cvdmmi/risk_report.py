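"""Result artifacts: excess-case tables, categorical fits, k-fold stability.

Excess cases are *fitted-model* excess: for each dose bin the sum over its
cells of (total hazard - baseline hazard) * person-years.  Negative entries
indicate a fitted protective effect.  Because this definition is linear in
the model, the MMI column of an excess-case table is exactly the
weight-linear combination of the per-model columns, bin by bin and in the
Sum row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import CATEGORICAL_ZERO_BELOW, DoseResponseSpec
from .fitting import FittedModel, fit_mle
from .grouped_data import GroupedTable
from .hazard_model import (CellArrays, DemParams, HazardModel, baseline_hazard,
                           total_hazard)

#: Default dose-bin edges (Gy) for excess-case tables, matching the
#: conventional low-dose-resolved binning of the grouped LSS data.
DEFAULT_EXCESS_BINS = (0.0, 0.005, 0.06, 0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, np.inf)

#: Default category edges (Gy) of the descriptive categorical model; risk is
#: fixed at zero below 0.005 Gy.
DEFAULT_CATEGORY_EDGES = (CATEGORICAL_ZERO_BELOW, 0.1, 0.5, 1.5)


def _bin_labels(edges) -> list[str]:
    lab = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lab.append(f"{lo:g}-{hi:g} Gy" if np.isfinite(hi) else f"{lo:g} Gy-")
    return lab


def excess_cases(fit: FittedModel, table: GroupedTable, bin_edges=DEFAULT_EXCESS_BINS
                 ) -> pd.DataFrame:
    """Per-dose-bin fitted excess cases, (h - h0) * PY summed over cells."""
    if not fit.converged:
        raise ValueError("excess cases require a converged fit")
    cells = CellArrays.from_table(table)
    edges = np.asarray(bin_edges, dtype=float)
    if cells.dose.min() < edges[0] or cells.dose.max() >= edges[-1] and np.isfinite(edges[-1]):
        raise ValueError("dose bins do not cover the data's dose range")
    h = total_hazard(fit.model, cells, strict=False)
    h0 = baseline_hazard(fit.model.baseline, cells)
    excess = (h - h0) * cells.pyr
    idx = np.clip(np.searchsorted(edges, cells.dose, side="right") - 1, 0, len(edges) - 2)
    per_bin = np.zeros(len(edges) - 1)
    np.add.at(per_bin, idx, excess)
    return pd.DataFrame({"bin": _bin_labels(edges), "excess_cases": per_bin})


def mmi_excess_cases(weights, model_tables: list[pd.DataFrame],
                     model_names: list[str] | None = None) -> pd.DataFrame:
    """Combine per-model excess-case tables into one table with an MMI column.

    ``weights`` may be a :class:`~cvdmmi.mmi.WeightedGroup` or a plain
    weight array aligned with ``model_tables``.  All tables must share
    identical bins.  A ``Sum`` row is appended; by linearity the MMI sum is
    the weighted sum of the per-model sums.
    """
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    names = model_names or list(getattr(weights, "names", [f"model_{i}" for i in range(len(w))]))
    if len(w) != len(model_tables) or len(names) != len(model_tables):
        raise ValueError("weights, names and model tables must align")
    bins = model_tables[0]["bin"].tolist()
    for t in model_tables[1:]:
        if t["bin"].tolist() != bins:
            raise ValueError("all model tables must use identical dose bins")
    out = pd.DataFrame({"bin": bins})
    mmi_col = np.zeros(len(bins))
    for name, wt, t in zip(names, w, model_tables):
        col = t["excess_cases"].to_numpy(float)
        out[name] = col
        mmi_col += wt * col
    out["MMI"] = mmi_col
    sums = {"bin": "Sum"}
    for c in out.columns[1:]:
        sums[c] = out[c].sum()
    return pd.concat([out, pd.DataFrame([sums])], ignore_index=True)


def fit_categorical(table: GroupedTable, edges=DEFAULT_CATEGORY_EDGES,
                    transfer: str = "ERR", dems: DemParams | None = None,
                    baseline=None, **fit_kw):
    """Descriptive categorical dose-response fit with Wald 95% CIs.

    One free risk level per dose category above the zero-risk reference
    (D < 0.005 Gy).  Returns the fit and a per-category summary frame; the
    reference category is exactly zero with no CI by construction.
    """
    from .hazard_model import BaselineParams

    edges = tuple(float(e) for e in edges)
    if edges[0] != CATEGORICAL_ZERO_BELOW:
        raise ValueError(
            f"lowest category edge must be the zero-risk reference bound {CATEGORICAL_ZERO_BELOW} Gy"
        )
    cells = CellArrays.from_table(table)
    counts = np.bincount(np.searchsorted(edges, cells.dose, side="right"),
                         minlength=len(edges) + 1)
    if np.any(counts == 0):
        import warnings
        warnings.warn("empty dose category; consider merging with a neighbour")
    spec = DoseResponseSpec.default("categorical", category_edges=edges)
    template = HazardModel(transfer=transfer,
                           baseline=baseline if baseline is not None else BaselineParams(),
                           dose_response=spec, dems=dems or DemParams())
    fit = fit_mle(template, table, **fit_kw)
    rows = [{"category": f"<{edges[0]:g} Gy", "level": 0.0, "se": np.nan,
             "lo95": np.nan, "hi95": np.nan, "reference": True}]
    for i in range(1, len(edges) + 1):
        pname = f"dr:level_{i}"
        j = fit.param_names.index(pname)
        v, s = fit.mle[j], fit.se[j]
        hi = f"{edges[i]:g}" if i < len(edges) else ""
        rows.append({"category": f"{edges[i-1]:g}-{hi} Gy" if hi else f">={edges[i-1]:g} Gy",
                     "level": float(v), "se": float(s),
                     "lo95": float(v - 1.96 * s), "hi95": float(v + 1.96 * s),
                     "reference": False})
    return fit, pd.DataFrame(rows)


def kfold_stability(template: HazardModel, table: GroupedTable,
                    folds=(10, 20, 40, 80), seed: int = 0,
                    dose_grid=None, **fit_kw) -> dict:
    """Cross-validation stability of the dose-response MLEs.

    Cells are partitioned at random into k folds; the model is refitted on
    each training complement.  Reported per fold count: the spread
    (standard deviation) of each dose-response MLE across refits, the
    number of non-converged refits, and how many refits produce ERR < -1
    anywhere on the data's dose range (the negative-hazard instability that
    flexible spline-type fits can show).  Deterministic given the seed.
    """
    from .mmi import member_curve

    df = table.data
    n = len(df)
    if dose_grid is None:
        dose_grid = np.linspace(0.0, float(df["mean_dose"].max()), 101)[1:]
    report: dict = {"seed": int(seed), "folds": {}}
    for k in folds:
        if k > n:
            raise ValueError(f"{k} folds exceed the {n} available cells")
        rng = np.random.default_rng(seed + k)
        perm = rng.permutation(n)
        assignment = np.arange(n) % k
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = assignment
        params: list[np.ndarray] = []
        pnames = None
        n_nonconv = 0
        n_err_lt_m1 = 0
        for f in range(k):
            train = GroupedTable(df.iloc[fold_of != f].reset_index(drop=True),
                                 endpoint=table.endpoint)
            fit = fit_mle(template, train, **fit_kw)
            if not fit.converged:
                n_nonconv += 1
                continue
            dr = [(nm, v) for nm, v in zip(fit.param_names, fit.mle) if nm.startswith("dr:")]
            if pnames is None:
                pnames = [nm for nm, _ in dr]
            params.append(np.array([v for _, v in dr]))
            curve = member_curve(fit, dose_grid, scale="ERR")
            if curve.min() < -1.0:
                n_err_lt_m1 += 1
        arr = np.array(params) if params else np.empty((0, 0))
        report["folds"][int(k)] = {
            "n_refits": int(k),
            "n_nonconverged": int(n_nonconv),
            "n_err_below_neg1": int(n_err_lt_m1),
            "param_names": pnames or [],
            "mle_mean": [float(v) for v in arr.mean(axis=0)] if arr.size else [],
            "mle_sd": [float(v) for v in arr.std(axis=0, ddof=1)] if arr.shape[0] > 1 else [],
        }
    return report
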