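"""Paired control-vs-treatment comparison with uncertainty propagation.

Relative differences use the control as denominator:
diff_pct = (treatment - control) / control * 100, so a negative value is a
reduction achieved by supplementation. Monte Carlo propagation pairs the two
systems through common random numbers: the same emission-factor draw is
applied to both systems in each iteration, so shared background uncertainty
cancels out of the difference — the pairing that off-the-shelf unpaired
sampling cannot express for small between-system differences.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .datamodel import EmissionFactorTable, FarmSystem, TrialRecord
from .emissions import EmissionParams
from .errors import (
    InvalidInputError,
    UnknownParameterError,
    WindowMismatchError,
    ZeroDivisionInputError,
)
from .lcia import CharacterizationFactors, ImpactResult


class CategoryComparison(BaseModel):
    """One category's paired values and relative difference."""

    control: float = Field(ge=0)
    treatment: float = Field(ge=0)
    diff_pct: float
    additive_share_pct: Optional[float] = None

    @model_validator(mode="after")
    def _sign(self) -> "CategoryComparison":
        if self.treatment > self.control and self.diff_pct < 0:
            raise ValueError("diff_pct sign contradicts value ordering")
        if self.treatment < self.control and self.diff_pct > 0:
            raise ValueError("diff_pct sign contradicts value ordering")
        return self


class UncertaintySummary(BaseModel):
    """Percentile summary of diff_pct across Monte Carlo iterations."""

    median: float
    p2_5: float
    p97_5: float
    mean: float
    sd: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "UncertaintySummary":
        if not (self.p2_5 <= self.median <= self.p97_5):
            raise ValueError("percentiles must be ordered")
        return self


class ComparisonReport(BaseModel):
    """Paired impacts per category with optional breakdowns and uncertainty."""

    label: str = ""
    categories: dict[str, CategoryComparison]
    cc_breakdown_control: Optional[dict[str, float]] = None
    cc_breakdown_treatment: Optional[dict[str, float]] = None
    window_only: bool = False
    uncertainty: Optional[dict[str, UncertaintySummary]] = None
    config: dict = Field(default_factory=dict)

    def diff_pct(self, category: str) -> float:
        return self.categories[category].diff_pct


def _diff_pct(control: float, treatment: float) -> float:
    if control == 0:
        if treatment == 0:
            return 0.0
        raise ZeroDivisionInputError("control value is zero; diff_pct undefined")
    return (treatment - control) / control * 100.0


def compare(
    control: ImpactResult, treatment: ImpactResult, label: str = "", window_only: bool = False
) -> ComparisonReport:
    """Per-category relative differences between one paired system."""
    if set(control.categories()) != set(treatment.categories()):
        raise InvalidInputError("control and treatment report different category sets")
    cats: dict[str, CategoryComparison] = {}
    for cat in control.categories():
        c, t = control.totals[cat], treatment.totals[cat]
        additive_share = None
        if t > 0 and "additive" in treatment.per_kg[cat]:
            additive_share = treatment.per_kg[cat]["additive"] / t * 100.0
        cats[cat] = CategoryComparison(
            control=c, treatment=t, diff_pct=_diff_pct(c, t), additive_share_pct=additive_share
        )
    return ComparisonReport(
        label=label,
        categories=cats,
        cc_breakdown_control=control.per_kg.get("CC"),
        cc_breakdown_treatment=treatment.per_kg.get("CC"),
        window_only=window_only,
    )


def aggregate(reports: list[ComparisonReport], label: str = "mean") -> ComparisonReport:
    """Unweighted mean of per-trial control and treatment values; the pooled
    diff_pct is recomputed from the unrounded means."""
    if not reports:
        raise InvalidInputError("no reports to aggregate")
    cat_sets = [set(r.categories) for r in reports]
    if any(s != cat_sets[0] for s in cat_sets):
        raise InvalidInputError("reports have different category sets")
    cats: dict[str, CategoryComparison] = {}
    for cat in reports[0].categories:
        c = float(np.mean([r.categories[cat].control for r in reports]))
        t = float(np.mean([r.categories[cat].treatment for r in reports]))
        shares = [
            r.categories[cat].additive_share_pct
            for r in reports
            if r.categories[cat].additive_share_pct is not None
        ]
        cats[cat] = CategoryComparison(
            control=c,
            treatment=t,
            diff_pct=_diff_pct(c, t),
            additive_share_pct=float(np.mean(shares)) if shares else None,
        )
    return ComparisonReport(label=label, categories=cats)


def supplementation_window_compare(
    control_system: FarmSystem,
    treatment_system: FarmSystem,
    ef: EmissionFactorTable,
    params: Optional[EmissionParams] = None,
    cf: Optional[CharacterizationFactors] = None,
) -> ComparisonReport:
    """Paired comparison restricted to the supplementation window: impacts and
    FPCM both accounted over the trial days only."""
    cw, tw = control_system.trial.window, treatment_system.trial.window
    if (cw.start_day, cw.end_day) != (tw.start_day, tw.end_day):
        raise WindowMismatchError(
            f"windows differ: {cw.start_day}-{cw.end_day} vs {tw.start_day}-{tw.end_day}"
        )
    from .model import evaluate_system

    res_c = evaluate_system(control_system, ef, params=params, cf=cf, window_only=True)
    res_t = evaluate_system(
        treatment_system,
        ef,
        params=params,
        cf=cf,
        control_trial=control_system.trial,
        window_only=True,
    )
    return compare(
        res_c.impacts,
        res_t.impacts,
        label=f"{control_system.label} vs {treatment_system.label} (window)",
        window_only=True,
    )


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


def _perturb_trial(trial: TrialRecord, rng: np.random.Generator) -> TrialRecord:
    """Draw zootechnical inputs from normal distributions around the trial
    means with the reported standard errors (degenerate when SE = 0)."""
    update: dict[str, float] = {}
    for field, se_field, lo, hi in (
        ("milk_yield_daily", "milk_yield_se", 1e-6, math.inf),
        ("dmi_daily", "dmi_se", 1e-6, math.inf),
        ("fat_pct", "fat_se", 1e-3, 10 - 1e-9),
        ("protein_pct", "protein_se", 1e-3, 10 - 1e-9),
    ):
        se = getattr(trial, se_field)
        if se > 0:
            value = rng.normal(getattr(trial, field), se)
            update[field] = min(max(value, lo), hi)
    return trial.model_copy(update=update) if update else trial


def _draw_ef_multipliers(
    ef: EmissionFactorTable, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    return {
        key: float(np.exp(rng.normal(0.0, math.log(ef.gsd(*key)))))
        for key in ef.keys()
        if ef.gsd(*key) > 1.0
    }


class MonteCarloResult:
    """Paired Monte Carlo draws of per-category relative differences."""

    def __init__(self, diff_pct: pd.DataFrame, point: dict[str, float], paired: bool, seed):
        self.diff_pct = diff_pct
        self.point_estimate = point
        self.paired = paired
        self.seed = seed
        self.n_iter = len(diff_pct)

    def summary(self) -> dict[str, UncertaintySummary]:
        out = {}
        for cat in self.diff_pct.columns:
            x = self.diff_pct[cat].to_numpy()
            out[cat] = UncertaintySummary(
                median=float(np.median(x)),
                p2_5=float(np.percentile(x, 2.5)),
                p97_5=float(np.percentile(x, 97.5)),
                mean=float(np.mean(x)),
                sd=float(np.std(x)),
            )
        return out

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {cat: s.model_dump() for cat, s in self.summary().items()}
        ).T[["median", "p2_5", "p97_5", "mean", "sd"]]


def monte_carlo(
    control_system: FarmSystem,
    treatment_system: FarmSystem,
    ef: EmissionFactorTable,
    n_iter: int = 1000,
    seed: Optional[int] = None,
    paired: bool = True,
    params: Optional[EmissionParams] = None,
    cf: Optional[CharacterizationFactors] = None,
) -> MonteCarloResult:
    """Propagate emission-factor (lognormal, via gsd) and zootechnical
    (normal, via SE) uncertainty through both systems.

    With ``paired=True`` (default) the same emission-factor draw is applied
    to both systems per iteration; an unpaired mode exists for comparison.
    Bit-reproducible for a fixed seed.
    """
    if n_iter < 1:
        raise InvalidInputError("n_iter must be >= 1")
    from .model import evaluate_system

    rng = np.random.default_rng(seed)
    res_c0 = evaluate_system(control_system, ef, params=params, cf=cf)
    res_t0 = evaluate_system(
        treatment_system, ef, params=params, cf=cf, control_trial=control_system.trial
    )
    point = {
        cat: _diff_pct(res_c0.impacts.totals[cat], res_t0.impacts.totals[cat])
        for cat in res_c0.impacts.categories()
    }
    rows = []
    for _ in range(n_iter):
        mult_c = _draw_ef_multipliers(ef, rng)
        mult_t = mult_c if paired else _draw_ef_multipliers(ef, rng)
        trial_c = _perturb_trial(control_system.trial, rng)
        trial_t = _perturb_trial(treatment_system.trial, rng)
        sys_c = control_system.model_copy(update={"trial": trial_c})
        sys_t = treatment_system.model_copy(update={"trial": trial_t})
        res_c = evaluate_system(sys_c, ef.scaled(mult_c), params=params, cf=cf)
        res_t = evaluate_system(
            sys_t, ef.scaled(mult_t), params=params, cf=cf, control_trial=trial_c
        )
        rows.append(
            {
                cat: _diff_pct(res_c.impacts.totals[cat], res_t.impacts.totals[cat])
                for cat in point
            }
        )
    return MonteCarloResult(pd.DataFrame(rows), point, paired, seed)


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity
# ---------------------------------------------------------------------------

_TRIAL_FIELDS = ("milk_yield_daily", "dmi_daily", "fat_pct", "protein_pct", "additive_dose")
_TRIAL_ALIASES = {
    "my": "milk_yield_daily",
    "dmi": "dmi_daily",
    "fat": "fat_pct",
    "protein": "protein_pct",
    "dose": "additive_dose",
}


class SensitivityItem(BaseModel):
    """Elasticities of the control total and of diff_pct to one parameter."""

    name: str
    elasticity_total: float
    diff_sensitivity: float  # percentage points of diff_pct per 100% parameter change


def _perturbed_inputs(
    control_system: FarmSystem,
    treatment_system: FarmSystem,
    params: EmissionParams,
    name: str,
    factor: float,
) -> tuple[FarmSystem, FarmSystem, EmissionParams]:
    for suffix, which in (("_control", 0), ("_treatment", 1)):
        if name.endswith(suffix):
            field = name[: -len(suffix)]
            field = _TRIAL_ALIASES.get(field, field)
            if field not in _TRIAL_FIELDS:
                raise UnknownParameterError(f"unknown trial parameter {field!r}")
            systems = [control_system, treatment_system]
            sys = systems[which]
            trial = sys.trial.model_copy(
                update={field: getattr(sys.trial, field) * factor}
            )
            systems[which] = sys.model_copy(update={"trial": trial})
            return systems[0], systems[1], params
    if name in EmissionParams.model_fields:
        new_params = params
        base = getattr(params, name)
        if base is not None:
            new_params = params.model_copy(update={name: base * factor})
        # per-system overrides shadow base params, so scale them too

        def scaled(sys: FarmSystem) -> FarmSystem:
            if name in sys.emission_overrides:
                ov = dict(sys.emission_overrides)
                ov[name] = ov[name] * factor
                return sys.model_copy(update={"emission_overrides": ov})
            return sys

        return scaled(control_system), scaled(treatment_system), new_params
    raise UnknownParameterError(f"unknown parameter {name!r}")


def sensitivity_oat(
    control_system: FarmSystem,
    treatment_system: FarmSystem,
    ef: EmissionFactorTable,
    parameters: list[str],
    perturbation: float = 0.1,
    params: Optional[EmissionParams] = None,
    cf: Optional[CharacterizationFactors] = None,
    category: str = "CC",
) -> list[SensitivityItem]:
    """One-at-a-time elasticities, ranked by magnitude.

    For each parameter the inputs are scaled by (1 +/- perturbation) and the
    central difference gives the elasticity of the control category total and
    the sensitivity of diff_pct (in percentage points per 100% change).
    """
    from .model import evaluate_system

    base_params = params if params is not None else EmissionParams()

    def outputs(sys_c: FarmSystem, sys_t: FarmSystem, p: EmissionParams) -> tuple[float, float]:
        rc = evaluate_system(sys_c, ef, params=p, cf=cf)
        rt = evaluate_system(sys_t, ef, params=p, cf=cf, control_trial=sys_c.trial)
        c = rc.impacts.totals[category]
        return c, _diff_pct(c, rt.impacts.totals[category])

    total0, _ = outputs(control_system, treatment_system, base_params)
    items = []
    for name in parameters:
        if perturbation == 0:
            # verify the name resolves even when nothing is perturbed
            _perturbed_inputs(control_system, treatment_system, base_params, name, 1.0)
            items.append(SensitivityItem(name=name, elasticity_total=0.0, diff_sensitivity=0.0))
            continue
        hi = outputs(*_perturbed_inputs(control_system, treatment_system, base_params, name, 1 + perturbation))
        lo = outputs(*_perturbed_inputs(control_system, treatment_system, base_params, name, 1 - perturbation))
        items.append(
            SensitivityItem(
                name=name,
                elasticity_total=(hi[0] - lo[0]) / (2 * perturbation * total0),
                diff_sensitivity=(hi[1] - lo[1]) / (2 * perturbation),
            )
        )
    return sorted(items, key=lambda i: abs(i.elasticity_total), reverse=True)
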