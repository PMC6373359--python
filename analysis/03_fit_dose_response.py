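#!/usr/bin/env python
"""Fit the dose-response catalogue to one synthetic LSS-like cohort.

Fits a representative subset of the 13 families (linear, quadratic,
linear-quadratic, linear-threshold, smooth step, two-line spline) as ERR
models to the cerebrovascular-like cohort (linear truth, 0.09/Gy) and
tabulates deviance, parameter count, AIC and the fitted dose-response
parameters.  Writes results/family_fits.csv.

Finding: on linear-truth data the linear model attains (essentially) the
best AIC; flexible threshold shapes buy < 3.84 deviance for their extra
parameters and the fitted linear slope recovers the generating 0.09/Gy
within its standard error.
"""

from pathlib import Path

import pandas as pd

from cvdmmi.dose_response import DoseResponseSpec
from cvdmmi.fitting import fit_mle
from cvdmmi.hazard_model import BaselineParams, HazardModel
from cvdmmi.synthetic_cohort import generate, preset

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
FAMILIES = ("lnt", "q", "lq", "lth", "smooth_step", "two_line_spline")


def main() -> None:
    sc = preset("cevd_like")
    table, truth = generate(sc, seed=SEED)
    bl = BaselineParams(values={}, active=sc.truth.baseline.active)
    rows = []
    for fam in FAMILIES:
        fit = fit_mle(HazardModel("ERR", bl, DoseResponseSpec.default(fam)), table)
        dr = {k.split(":", 1)[1]: round(v, 4) for k, v in fit.params_dict().items()
              if k.startswith("dr:")}
        rows.append({"family": fam, "dev": fit.deviance, "npar": fit.npar,
                     "aic": fit.aic(), "converged": fit.converged,
                     "boundary": fit.boundary, "dose_params": str(dr)})
        print(f"{fam:>16}: dev={fit.deviance:9.2f} npar={fit.npar} "
              f"AIC={fit.aic():9.2f} {dr}")
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    path = ROOT / "results" / "family_fits.csv"
    path.parent.mkdir(exist_ok=True)
    df.to_csv(path, index=False, float_format="%.4f")
    print(f"truth: LNT beta = {truth['truth_params']['dose_response']['beta']}")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
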