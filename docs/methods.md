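# Methods and design notes

## Data model

All computation consumes a *grouped table*: one row per stratum cell
(city × sex × age-at-exposure category × attained-age category × calendar
period × dose category) with person-years `pyr`, PY-weighted mean
covariates (`mean_agex`, `mean_age`, `mean_dose`) and per-endpoint death
counts.  Invariants enforced at construction: non-negative person-years
and doses, integer non-negative counts, attained age ≥ age at exposure,
no cases on zero-person-year rows, unique stratum keys.  Doses are
weighted colon doses in Gy (γ + 10 × neutron); the cell dose used in the
likelihood is the cell's PY-weighted mean, and age covariates enter as
PY-weighted means rather than category midpoints.  Endpoint choice
(cerebrovascular vs heart) selects a case column; the ICD-9 definitions
are documented but never re-derived from cause codes.

## Hazard model

Baseline: log-linear form
`ln h0 = a0 + a_city·1[Nagasaki] + a_sex·1[female] + p1·ln(a/70) +
p2·ln²(a/70) + p3·(e−30)/10 + p4·1[female]·ln(a/70)`,
centred at the conventional reporting ages (attained age 70, age at
exposure 30).  Every non-intercept term carries an activity flag; inactive
terms contribute exactly zero, which is what baseline streamlining
toggles.  The original analysis used a richer 29-parameter baseline whose
exact composition is not available to us; this seven-term form keeps the
streamlining protocol meaningful while remaining swappable (the form is
confined to `hazard_model`).

Dose-effect modifiers:
`eps = exp(ts·1[female]) · (a/70)^ta · exp(te·(e−30)/10)`, each term
individually gated; with all inactive, eps ≡ 1.

Transfers: ERR `h = h0·(1 + err·eps)`; EAR `h = h0 + ear·eps`.  The two
coincide under `ear = h0·err` at matched covariates, which is also how
risk curves are converted between scales for joint reporting.  ERR
positivity (`1 + err·eps > 0`) is enforced during fitting by an effectively
infinite deviance penalty (fit rejection, not clamping); during CI
simulation offending draws are retained but counted and reported.

## Dose–response families

Thirteen families, all exactly zero at zero dose (module docstring of
`dose_response` lists the formulas).  The supplementary material with the
original closed forms is not available; the canonical forms here were
chosen to (a) match the published catalogue's shapes and (b) realize the
nestedness identities the selection stage needs, and each identity is
property-tested (e.g. linear-threshold at threshold 0 equals LNT, the
two-line spline with equal slopes equals LNT, the smooth step at its
minimum smoothness equals the step).  Specific choices:

- step-type families are modified hyperbolic tangents, shifted so
  err(0) = 0; the pure step fixes the smoothness at 0.01 Gy, free
  smoothness is bounded below by the same value to exclude
  infinite-gradient fits; the sigmoid's lower smoothness bound (0.005 Gy)
  is exactly the value at which it reproduces the step.
- the step-linear family adds a whole-range linear term to the smooth
  step (with zero slope it is exactly the smooth step).
- hormesis is a Brain–Cousens-type rational curve
  `(c·D + β·D²)/(1 + θ·D)`; `c < 0` produces a protective low-dose dip and
  its NOAEL (return to zero from below) is located by bisection.
- the hockey stick attains a (possibly negative) plateau through a fixed
  5 mGy linear ramp from zero — continuity plus err(0) = 0 forbid a jump,
  and the ramp sits below the lowest nonzero dose category so fitted cells
  never see it.
- thresholds are constrained to the observed dose range [0, 4] Gy.
- categorical: one free level per dose category with zero risk fixed
  below 0.005 Gy.

Shape diagnostics (`zero_crossing`, `noael`) use a 4001-point sign-change
scan followed by Brent bisection to 10⁻⁶ Gy; a flat zero segment without a
sign change is not a crossing.

## Fitting

Grouped Poisson deviance `2·Σ[O·ln(O/E) − (O − E)]` with `O·ln(O/E) := 0`
at `O = 0`; infinite when any `E ≤ 0` with `O > 0`.  Minimization:
L-BFGS-B with numerical derivatives inside box bounds, with coordinates
scaled so EAR-scale magnitude parameters (characteristic size 10⁻⁴ per PY
per Gy) appear O(1) to the optimizer.  Families with a free threshold are
profiled over a deterministic 21-point grid on [0, 4] Gy (the likelihood
is only piecewise smooth in the threshold), then the threshold is released
and a Nelder-Mead polish is applied.  Convergence: optimizer success plus
a finite deviance; threshold estimates within 10⁻⁶ Gy of the range edge
are flagged `boundary` and their covariance marked unreliable.  A
data-driven intercept start (log of the crude rate) is used when the
template provides none.

Wald covariance: `2 × pinv(Hessian of the deviance)` by central finite
differences at the MLE, symmetrized; negative diagonal entries mark the
covariance unreliable.  The LRT uses the protocol's two-decimal χ²₀.₉₅
cutoffs (3.84 for one added parameter, 5.99 for two), with the boundary
counting as significant; a reduction fitting *better* than its extension
beyond numerical tolerance raises a refit-ordering error (tiny optimizer
noise is clipped to zero improvement).

## Selection protocol

1. **Baseline streamlining** — greedy backward elimination: at each pass
   remove the term whose removal raises the deviance least, while that
   rise is < 3.84; ties break by declared parameter order.  The published
   protocol does not state its elimination order; greedy
   least-harmful-first is this package's choice and is logged step by
   step.
2. **Family competition** — all candidate families are fitted on the
   streamlined baseline (extensions warm-started from the embedded MLE of
   each fitted reduction); along every nestedness edge the extension
   survives only if it beats its reduction by the LRT, beaten reductions
   are dropped, and the survivor set is the antichain of the graph.  The
   categorical model is excluded from the default competition list: it is
   nested with nothing, so it would enter every Occam's group, whereas it
   serves as a descriptive comparator (`risk_report.fit_categorical`); a
   caller can compete it explicitly.
3. **DEM gating** — each modifier added singly and kept iff significant;
   jointly refitted and re-gated backward when several pass.
4. **Occam's group** — ERR and EAR survivors merged; AIC (or BIC) weights
   from criterion differences; members below the 0.05 weight floor are
   dropped and the rest reweighted unless the keep-subfloor switch is on
   (both behaviours exist because the published heart analysis retained
   two sub-floor members).

Every decision lands in an ordered selection log; with a fixed seed and
table the log and group reproduce bit for bit.

## Model averaging and uncertainty

AIC = dev + 2·Npar; BIC = dev + Npar·ln(n) with *n* the endpoint death
count (9622 / 8463 in the published analysis), not the cell count.
Weights are computed from ΔIC for numerical stability and are invariant
under constant shifts.  Central MMI curves are the weighted sums of member
MLE curves; ERR↔EAR conversion uses each member's own fitted baseline at
the reporting covariates (male, Hiroshima, attained age 70, age at
exposure 30 by default).  Uncertainty: member *i* contributes
`round(w_i · 10⁴)` draws (rounding residual to the highest-weight member)
from a multivariate normal at (MLE, Wald covariance) honouring the
parameter correlations, seeded per member (`seed + index`); the merged
pool's 2.5/97.5 percentiles form the 95% band.  Draws with ERR < −1 are
retained but counted; a rejection option is deliberately not the default
because the published analysis flags the issue without removing draws.

## Synthetic cohorts

The generator emulates: the grouped-table stratification (2 cities ×
2 sexes × 5 age-at-exposure bands × 4 periods × 11 dose categories =
880 cells at the full presets), a low-dose-weighted dose mass function
(PY-weighted mean dose 0.112 Gy, most person-years below 0.25 Gy), the
real person-year total, and expected death totals calibrated exactly by a
closed-form intercept shift.  Truth scale: ERR 0.09/Gy for the
cerebrovascular-like preset (the reported effect scale), an additive EAR
of 2.5·10⁻⁴ per PY per Gy with an attained-age modifier for the
heart-like preset, a no-dose-effect preset for type-I calibration (leaner
stratification, sized for repeated fits), and a sparse preset with a
deep-dip spline truth that stresses threshold fitting.

It does **not** emulate: dosimetry error, calendar-period baseline trends,
migration/censoring structure, the exact category boundaries of the real
file, or between-disease heterogeneity within an aggregate endpoint.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under the assumed Poisson model, not the epidemiological
conclusions for the real cohort — those require the registration-gated
data file (see `published.validate_against_cohort`).

## Problem sizes used in tests and the acceptance script

Simulation-based checks use: 100 replicates (LNT coverage at full cohort
scale; 60 in the acceptance script), 30 replicates for the quadratic and
spline recovery checks, 400 seeds for LRT type-I calibration (200 in the
acceptance script), 10⁴ draws for Monte-Carlo bands, 1000 random tables
for the deviance oracle.  These sizes make the binomial/Monte-Carlo noise
small relative to each assertion's margin.

## Known limitations

- The baseline and dose-response closed forms are this package's
  canonical reconstructions, isolated in their modules; fits to the real
  file will differ from the published deviances until the original
  supplement forms are substituted.
- Wald covariances for boundary-threshold fits are unreliable (flagged);
  profile-likelihood intervals are out of scope, as in the original
  protocol.
- Cross-validation folds partition cells (grouped data has no
  individuals); the original fold construction is unspecified.
- The published MMI deviance for the cerebrovascular endpoint (13,415.46)
  has no stated definition; no operation claims to reproduce it.
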