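"""Published reference values for the LSS cerebrovascular / heart analysis.

These records transcribe the result tables of the published multi-model
dose-response analysis of grouped LSS mortality data (follow-up 1950-2003,
weighted colon dose): the final non-nested models of Occam's group with
their deviances and parameter counts, the per-model excess-case tables, and
cohort-level totals.  They serve two purposes:

* as *inputs* to the information-criterion and model-averaging arithmetic
  (weights and MMI excess-case totals are recomputed from deviances and
  parameter counts, never copied), and
* as the comparison side of the external-data validation hook
  (:func:`validate_against_cohort`) for users who have obtained the
  registration-gated grouped data file (lsscvd10.dat).

The underlying individual fits themselves are **not** reproducible without
that file and the exact 29-parameter baseline of the original analysis;
the point-estimate records below are therefore documentation, not
quantities this package recomputes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grouped_data import read_grouped_table, summarize

#: Occam's-group fit summaries: (model name, transfer, family, deviance,
#: number of parameters, printed AIC, printed delta-AIC, printed AIC weight).
OCCAMS_TABLE = {
    "cevd": [
        ("ERR-LNT", "ERR", "lnt", 13417.53, 16, 13449.53, 1.76, 0.2412),
        ("ERR-Q", "ERR", "q", 13415.77, 16, 13447.77, 0.00, 0.5823),
        ("ERR-two-line-spline", "ERR", "two_line_spline", 13414.15, 18, 13450.15, 2.39, 0.1765),
    ],
    "heart": [
        ("ERR-LNT", "ERR", "lnt", 13152.52, 21, 13194.52, 0.00, 0.3089),
        ("ERR-Q", "ERR", "q", 13154.54, 21, 13196.54, 2.02, 0.1123),
        ("ERR-smooth-step", "ERR", "smooth_step", 13153.66, 23, 13199.66, 5.14, 0.0236),
        ("EAR-LNT", "EAR", "lnt", 13151.22, 22, 13195.22, 0.71, 0.2171),
        ("EAR-Q", "EAR", "q", 13151.78, 22, 13195.78, 1.26, 0.1647),
        ("EAR-LTH", "EAR", "lth", 13152.29, 22, 13196.29, 1.78, 0.1271),
        ("EAR-smooth-step", "EAR", "smooth_step", 13152.31, 23, 13198.31, 3.79, 0.0464),
    ],
}

#: Streamlined-baseline-only fits: (deviance, Npar, AIC).
BASELINE_FITS = {"cevd": (13422.27, 15, 13452.27), "heart": (13163.17, 20, 13203.17)}

#: Full-baseline ERR-LNT / EAR-LNT starting deviances of the streamlining.
FULL_BASELINE_DEV = {
    "cevd": {"ERR-LNT": 13409.43, "EAR-LNT": 13407.44},
    "heart": {"ERR-LNT": 13148.55, "EAR-LNT": 13155.96},
}

#: Endpoint death counts: the observation count n used by the BIC.
N_CASES = {"cevd": 9622, "heart": 8463}

#: Published BIC weights (per endpoint; heart reported for ERR models only).
BIC_WEIGHTS = {
    "cevd": {"ERR-LNT": 0.2929, "ERR-Q": 0.7070, "ERR-two-line-spline": 0.000165},
    "heart": {"ERR-LNT": 0.708, "ERR-Q": 0.2574},
}

#: Cohort-level summary of the grouped data file.
COHORT = {
    "subjects": 86_611,
    "person_years": 3_294_282,
    "py_weighted_mean_dose": 0.116,      # Gy, whole cohort
    "case_weighted_mean_dose": 0.111,    # Gy, mortality cases
    "dose_range": (0.0, 4.0),            # Gy
    "cases": dict(N_CASES),
}

_EXCESS_BINS = ["0-0.005 Gy", "0.005-0.06 Gy", "0.06-0.1 Gy", "0.1-0.25 Gy",
                "0.25-0.5 Gy", "0.5-1 Gy", "1-1.5 Gy", "1.5-2 Gy", "2-2.5 Gy",
                "2.5-3 Gy", "3 Gy-"]

#: Radiation-associated excess cases per dose bin and model (no MMI column;
#: the MMI combination is recomputed, not transcribed).  Published MMI sums:
#: 41.0 (cevd) and 72.2 (heart).
EXCESS_CASES = {
    "cevd": pd.DataFrame({
        "bin": _EXCESS_BINS,
        "ERR-LNT": [0.3, 4.9, 3.5, 11.8, 15.9, 19.8, 12.0, 5.5, 5.3, 3.1, 0.1],
        "ERR-Q": [0.0, 0.1, 0.2, 1.4, 4.0, 9.9, 10.4, 6.7, 8.6, 5.8, 0.1],
        "ERR-two-line-spline": [-1.4, -20.0, -14.1, -35.7, -8.2, 11.6, 13.0, 7.0, 7.5, 4.5, 0.1],
    }),
    "heart": pd.DataFrame({
        "bin": _EXCESS_BINS,
        "ERR-LNT": [0.5, 7.2, 5.0, 17.1, 23.1, 28.5, 17.7, 7.7, 7.7, 4.5, 0.1],
        "ERR-Q": [0.0, 0.1, 0.2, 1.6, 4.5, 10.9, 11.6, 7.0, 9.3, 6.3, 0.1],
        "ERR-smooth-step": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 12.1, 10.2, 5.1, 0.1],
        "EAR-LNT": [0.4, 5.7, 3.9, 13.1, 18.2, 23.9, 14.8, 6.8, 7.0, 4.0, 0.1],
        "EAR-Q": [0.0, 0.0, 0.1, 1.0, 3.0, 8.1, 8.7, 5.7, 7.7, 5.2, 0.3],
        "EAR-LTH": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 4.9, 1.5],
        "EAR-smooth-step": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 6.1, 0.8],
    }),
}

MMI_EXCESS_SUM = {"cevd": 41.0, "heart": 72.2}

#: Point estimates from the original fits; require the external data file
#: plus the original baseline form, hence documentation/validation only.
POINT_ESTIMATES = {
    "cevd": {
        "spline_knee_gy": 0.14,          # two-line-spline inflection dose
        "spline_zero_crossing_gy": 0.46, # where the fitted spline re-crosses zero
        "lth_threshold_gy": 0.48,
        "hormesis_noael_gy": 0.55,
        "err_at_1gy_mmi": 0.0669,
        "err_at_1gy_mmi_ci": (0.0074, 0.14),
        "ci_includes_zero_up_to_gy": 0.75,
    },
    "heart": {
        "err_smooth_step_dth_gy": 1.52,
        "ear_lth_dth_gy": 2.36,
        "ear_smooth_step_dth_gy": 2.54,
        "err_at_1gy_mmi": 0.08,
        "err_at_1gy_mmi_ci": (0.0, 0.20),
        "ci_includes_zero_up_to_gy": 2.58,
    },
}


def occams_frame(endpoint: str) -> pd.DataFrame:
    """Published Occam's-group summaries as a DataFrame."""
    return pd.DataFrame(
        OCCAMS_TABLE[endpoint],
        columns=["model", "transfer", "family", "dev", "npar",
                 "aic_printed", "delta_aic_printed", "aic_weight_printed"],
    )


def lss_column_map() -> dict[str, str]:
    """Column map for a CSV export of the lsscvd10-style grouped data file.

    Users who obtain the original file (registration-gated) and export it
    to CSV with these headers can feed it straight into
    :func:`cvdmmi.grouped_data.read_grouped_table`.
    """
    return {
        "city": "city", "sex": "sex", "agxcat": "agex_cat", "agecat": "age_cat",
        "time": "period", "dosecat": "dose_cat", "subjects": "subjects",
        "pyr": "pyr", "agex": "mean_agex", "age": "mean_age",
        "colon10": "mean_dose", "cvddth": "cases_cevd", "hddth": "cases_heart",
    }


def validate_against_cohort(path, endpoint: str = "cevd",
                            schema: dict | None = None) -> dict:
    """External-data validation hook.

    Loads a user-supplied grouped cohort CSV (see :func:`lss_column_map`)
    and compares its totals with the published cohort summary.  This is the
    desk-side check available without refitting; the published deviances,
    thresholds and risk estimates additionally require the original
    parametric baseline and are not validated here.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"{p}: the grouped cohort data file is registration-gated and not "
            "distributed with this package; obtain it from the data holder and "
            "pass its path (CSV export, see lss_column_map())."
        )
    table = read_grouped_table(p, schema=schema or {}, endpoint=endpoint)
    s = summarize(table)
    return {
        "summary": s,
        "expected": {
            "total_cases": N_CASES[endpoint],
            "total_person_years": COHORT["person_years"],
            "py_weighted_mean_dose": COHORT["py_weighted_mean_dose"],
        },
        "matches_cases": abs(s["total_cases"] - N_CASES[endpoint]) < 0.5,
        "matches_person_years": abs(s["total_person_years"] - COHORT["person_years"]) < 1.0,
    }
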