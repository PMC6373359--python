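"""Two-stage model-selection protocol yielding Occam's group.

Stage 1 (baseline streamlining): starting from the full parametric baseline
combined with the linear no-threshold model, baseline terms are removed by
greedy backward elimination — at each pass the term whose removal raises the
deviance least is deactivated, as long as that rise stays below the
one-parameter LRT cutoff of 3.84.

Stage 2 (family competition): with the streamlined baseline structure
fixed, every candidate dose-response family is fitted; along each edge of
the nestedness graph the extended family survives only if it beats its
reduction by the LRT, and reductions beaten by any surviving extension are
dropped.  The survivors form an antichain of the graph.  Each survivor's
dose-effect modifiers are then gated by single and joint LRTs.  Survivors
from the ERR and EAR transfers are merged, weighted, and (optionally)
filtered by an AIC-weight floor to form Occam's group.

Every decision is appended to a selection log, which fully determines the
group: rerunning with the same table and seed reproduces it bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import (DoseResponseSpec, NESTED_EDGES, NESTED_EMBEDDINGS)
from .fitting import FittedModel, fit_mle, lrt_improves
from .hazard_model import BaselineParams, DemParams, HazardModel
from .mmi import WeightedGroup, ic_weights

#: Default family list for the competition: every registered parametric
#: family.  The categorical model is a descriptive comparator (it is nested
#: in nothing and nests nothing, so it would enter every group by default);
#: include "categorical" explicitly to compete it.
DEFAULT_FAMILIES = (
    "lnt", "q", "step", "lth", "le", "lq", "smooth_step", "sigmoid",
    "two_line_spline", "step_linear", "hockey_stick", "hormesis",
)


@dataclass
class SelectionLog:
    entries: list[dict] = field(default_factory=list)

    def append(self, stage: str, **kw) -> None:
        self.entries.append({"stage": stage, **kw})

    def to_records(self) -> list[dict]:
        return list(self.entries)


def streamline_baseline(full: HazardModel, table, log: SelectionLog | None = None,
                        **fit_kw) -> tuple[BaselineParams, FittedModel, SelectionLog]:
    """Greedy backward elimination of baseline terms under the LRT.

    Returns the streamlined baseline structure, its final fit (still with
    the template's dose-response attached) and the selection log.
    """
    log = log if log is not None else SelectionLog()
    current = fit_mle(full, table, **fit_kw)
    if not current.converged:
        raise RuntimeError("full model did not converge; cannot streamline")
    model = current.model
    while True:
        candidates = [t for t in model.baseline.active if t != "intercept"]
        if not candidates:
            break
        trials = []
        for term in candidates:
            reduced = model.replace(baseline=model.baseline.deactivate(term))
            fit_r = fit_mle(reduced, table, **fit_kw)
            delta = fit_r.deviance - current.deviance
            trials.append((delta, term, fit_r))
            log.append("streamline_test", term=term, delta_dev=float(delta),
                       converged=bool(fit_r.converged))
        # deterministic tie-break: declared parameter order
        delta, term, fit_r = min(trials, key=lambda t: (t[0], candidates.index(t[1])))
        decision = lrt_improves(max(fit_r.deviance, current.deviance),
                                current.deviance, 1)
        if decision.significant:
            # removing any remaining term costs >= 3.84: stop
            log.append("streamline_stop", remaining=list(model.baseline.active))
            break
        log.append("streamline_remove", term=term, delta_dev=float(delta))
        model = fit_r.model
        current = fit_r
    return current.model.baseline, current, log


def _template(transfer: str, baseline: BaselineParams, family: str,
              dems: DemParams | None = None,
              category_edges=None) -> HazardModel:
    return HazardModel(
        transfer=transfer, baseline=baseline,
        dose_response=DoseResponseSpec.default(family, category_edges=category_edges),
        dems=dems or DemParams(),
    )


def compete_families(baseline: BaselineParams, table, transfer: str,
                     families=DEFAULT_FAMILIES, log: SelectionLog | None = None,
                     **fit_kw) -> tuple[dict[str, FittedModel], SelectionLog]:
    """Fit candidate families and prune the nestedness graph by LRT.

    Families are fitted in an order that puts reductions before their
    extensions so extended fits can warm-start from the embedded reduced
    MLE.  Returns the antichain of survivors.
    """
    log = log if log is not None else SelectionLog()
    families = list(families)
    fits: dict[str, FittedModel] = {}
    for fam in families:
        tmpl = _template(transfer, baseline, fam)
        starts = [None]
        for red, ext in NESTED_EDGES:
            if ext == fam and red in fits and fits[red].converged:
                emb = NESTED_EMBEDDINGS[(red, ext)](
                    fits[red].model.dose_response.params)
                starts.append({f"dr:{k}": v for k, v in emb.items()})
        best = None
        for st in starts:
            f = fit_mle(tmpl, table, start=st, **fit_kw)
            if best is None or f.deviance < best.deviance - 1e-9:
                best = f
        fits[fam] = best
        log.append("family_fit", transfer=transfer, family=fam,
                   deviance=float(best.deviance), npar=int(best.npar),
                   converged=bool(best.converged))

    usable = {f: v for f, v in fits.items() if v.converged}
    for fam in families:
        if fam not in usable:
            log.append("family_dropped_nonconverged", transfer=transfer, family=fam)

    dropped: set[str] = set()
    for red, ext in NESTED_EDGES:
        if red not in usable or ext not in usable:
            continue
        fr, fe = usable[red], usable[ext]
        extra = fe.npar - fr.npar
        # guard against optimizer noise producing a marginally "worse" extension
        dev_red = max(fr.deviance, fe.deviance)
        decision = lrt_improves(dev_red, fe.deviance, max(extra, 1))
        log.append("family_lrt", transfer=transfer, reduced=red, extended=ext,
                   delta_dev=float(fr.deviance - fe.deviance),
                   cutoff=float(decision.cutoff), significant=decision.significant)
        if decision.significant:
            dropped.add(red)
        else:
            dropped.add(ext)
    survivors = {f: v for f, v in usable.items() if f not in dropped}
    log.append("family_survivors", transfer=transfer, survivors=sorted(survivors))
    return survivors, log


def gate_dems(fit: FittedModel, table, log: SelectionLog | None = None,
              **fit_kw) -> tuple[FittedModel, SelectionLog]:
    """Test the three dose-effect modifiers and keep the significant ones.

    Each DEM (sex, attained age, age at exposure) is added singly and kept
    if LRT-significant; when several pass singly they are refitted jointly
    and re-gated by backward elimination within the joint fit.
    """
    log = log if log is not None else SelectionLog()
    if not fit.converged:
        raise RuntimeError("cannot gate DEMs on a non-converged fit")
    base_model = fit.model
    single: list[str] = []
    for term in ("sex", "attained_age", "age_at_exposure"):
        trial = base_model.replace(dems=base_model.dems.activate(term))
        f = fit_mle(trial, table, **fit_kw)
        dec = lrt_improves(max(fit.deviance, f.deviance), f.deviance, 1)
        log.append("dem_single", term=term, delta_dev=float(fit.deviance - f.deviance),
                   significant=dec.significant, converged=bool(f.converged))
        if dec.significant and f.converged:
            single.append(term)
    if not single:
        return fit, log
    dems = base_model.dems
    for t in single:
        dems = dems.activate(t)
    joint = fit_mle(base_model.replace(dems=dems), table, **fit_kw)
    # re-test each kept DEM within the joint model
    while len(joint.model.dems.active) > 1:
        worst = None
        for term in joint.model.dems.active:
            reduced_dems = DemParams(
                values={k: v for k, v in joint.model.dems.values.items() if k != term},
                active=tuple(t for t in joint.model.dems.active if t != term),
            )
            f = fit_mle(joint.model.replace(dems=reduced_dems), table, **fit_kw)
            delta = f.deviance - joint.deviance
            if worst is None or delta < worst[0]:
                worst = (delta, term, f)
        dec = lrt_improves(worst[2].deviance, joint.deviance, 1)
        log.append("dem_joint_retest", term=worst[1], delta_dev=float(worst[0]),
                   significant=dec.significant)
        if dec.significant:
            break
        joint = worst[2]
    if len(joint.model.dems.active) == 0:
        return fit, log
    log.append("dem_final", active=list(joint.model.dems.active))
    return joint, log


def assemble_occams_group(survivors: dict[str, FittedModel], criterion: str = "AIC",
                          n: int | None = None, weight_floor: float = 0.05,
                          keep_subfloor: bool = False,
                          log: SelectionLog | None = None
                          ) -> tuple[WeightedGroup, SelectionLog]:
    """Merge transfer-wise survivors into the weighted Occam's group.

    ``survivors`` maps display names (e.g. ``"ERR-lnt"``) to converged
    fits.  Members whose weight falls below ``weight_floor`` are dropped and
    the rest reweighted, unless ``keep_subfloor`` retains them (the
    behaviour used when sub-floor models are deliberately kept).
    """
    log = log if log is not None else SelectionLog()
    if not survivors:
        raise ValueError("empty survivor set; no models to average")
    names = list(survivors)
    fits = [survivors[k] for k in names]
    if any(not f.converged for f in fits):
        raise ValueError("all Occam's group members must have converged")
    group = ic_weights(fits, criterion=criterion, n=n, names=names)
    if not keep_subfloor and weight_floor > 0 and len(group) > 1:
        keep = group.weights >= weight_floor
        if keep.sum() < len(names):
            dropped = [nm for nm, k in zip(names, keep) if not k]
            log.append("weight_floor_drop", dropped=dropped, floor=weight_floor)
            names = [nm for nm, k in zip(names, keep) if k]
            fits = [f for f, k in zip(fits, keep) if k]
            group = ic_weights(fits, criterion=criterion, n=n, names=names)
    log.append("occams_group", members=names,
               weights=[float(w) for w in group.weights], criterion=criterion)
    return group, log
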