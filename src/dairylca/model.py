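"""Model/Results interface tying the pipeline stages together.

`DairySystemLCA` assesses one cradle-to-farm-gate system; `PairedTrialLCA`
pairs a control and a supplemented system and exposes the comparison,
Monte Carlo uncertainty and one-at-a-time sensitivity on its results.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .compare import ComparisonReport, MonteCarloResult, SensitivityItem
from .compare import compare as compare_impacts
from .compare import monte_carlo as _monte_carlo
from .compare import sensitivity_oat as _sensitivity_oat
from .compare import supplementation_window_compare
from .categories import CATEGORIES, CATEGORY_UNITS, SOURCE_LABELS, SOURCES
from .datamodel import AnnualHerdProfile, EmissionFactorTable, FarmSystem, TrialRecord
from .emissions import EmissionFlows, EmissionParams, compute_flows, utility_impacts
from .errors import InvalidInputError
from .feed import FeedFootprint, feed_impacts
from .herd import annualize, window_profile
from .lcia import (
    CharacterizationFactors,
    ImpactResult,
    allocation_factor,
    characterize,
    contribution_analysis,
)


def resolve_params(system: FarmSystem, params: Optional[EmissionParams]) -> EmissionParams:
    """Base emission parameters with the system's overrides applied on top."""
    base = params if params is not None else EmissionParams()
    if system.emission_overrides:
        return base.model_copy(update=dict(system.emission_overrides))
    return base


def system_allocation_factor(system: FarmSystem, profile: AnnualHerdProfile) -> float:
    """Biophysical milk allocation for one system (1.0 when allocation is off).

    Mmilk defaults to the system's own annual FPCM when the reference system
    does not state the herd-level FPCM sold.
    """
    if system.allocation_mode == "none":
        return 1.0
    m_milk = system.reference.herd_annual_fpcm_sold or profile.fpcm_annual
    return allocation_factor(system.reference.herd_coproduct_liveweight, m_milk)


def evaluate_system(
    system: FarmSystem,
    ef: EmissionFactorTable,
    params: Optional[EmissionParams] = None,
    cf: Optional[CharacterizationFactors] = None,
    control_trial: Optional[TrialRecord] = None,
    window_only: bool = False,
) -> "SystemLCAResults":
    """Run annualize -> emissions -> feed -> characterize for one system.

    ``control_trial`` drives the outside-window extrapolation for treatment
    systems. ``window_only`` restricts impacts and FPCM to the trial window
    (utility use pro-rated by window length; a supplied annual N intake is
    scaled by the window's intake share).
    """
    ef.resolve(system.item_keys())
    run_params = resolve_params(system, params)
    run_cf = cf if cf is not None else CharacterizationFactors()
    annual = annualize(
        system.trial,
        system.reference,
        control=control_trial,
        gaei_annual=system.gaei_annual,
        diet=system.diet,
    )
    af = system_allocation_factor(system, annual)
    if window_only:
        profile = window_profile(
            system.trial,
            gaei_annual=system.gaei_annual,
            fi_annual_full=annual.fi_annual,
            diet=system.diet,
        )
        util_scale = system.trial.duration_days / 365.0
        if run_params.n_intake_annual is not None:
            run_params = run_params.model_copy(
                update={
                    "n_intake_annual": run_params.n_intake_annual
                    * profile.fi_annual
                    / annual.fi_annual
                }
            )
    else:
        profile = annual
        util_scale = 1.0
    util = utility_impacts(system.reference, ef, scale=util_scale)
    flows = compute_flows(profile, run_params, trial=system.trial, diet=system.diet)
    feed = feed_impacts(profile, system.diet, ef, additive_key=system.additive_key)
    impacts = characterize(flows, feed, run_cf, profile, af, utility=util)
    return SystemLCAResults(
        system=system,
        annual_profile=annual,
        profile=profile,
        flows=flows,
        feed=feed,
        impacts=impacts,
        params=run_params,
        cf=run_cf,
        window_only=window_only,
    )


class SystemLCAResults:
    """Results of one system assessment: profile, flows and per-kg impacts."""

    def __init__(
        self,
        system: FarmSystem,
        annual_profile: AnnualHerdProfile,
        profile: AnnualHerdProfile,
        flows: EmissionFlows,
        feed: FeedFootprint,
        impacts: ImpactResult,
        params: EmissionParams,
        cf: CharacterizationFactors,
        window_only: bool = False,
    ):
        self.system = system
        self.annual_profile = annual_profile
        self.profile = profile
        self.flows = flows
        self.feed = feed
        self.impacts = impacts
        self.params = params
        self.cf = cf
        self.window_only = window_only

    def contributions(self, category: str = "CC") -> dict[str, float]:
        """Per-source percentage shares of one category total."""
        return contribution_analysis(self.impacts, category)

    def breakdown_frame(self) -> pd.DataFrame:
        """Source x category table of per-kg-FPCM impacts."""
        data = {cat: self.impacts.per_kg[cat] for cat in self.impacts.categories()}
        frame = pd.DataFrame(data)
        return frame.reindex(SOURCES)

    def summary(self) -> str:
        p = self.profile
        lines = [
            f"Dairy system LCA results: {self.system.label}"
            + (" (supplementation window only)" if self.window_only else ""),
            "=" * 60,
            f"Milk (kg/cow/yr):            {p.milk_annual:12.1f}",
            f"FPCM (kg/cow/yr):            {p.fpcm_annual:12.1f}",
            f"Feed intake (kg DM/cow/yr):  {p.fi_annual:12.1f}",
            f"Gross energy (MJ/cow/yr):    {p.ge_annual:12.0f}",
            f"Trial feed efficiency:       {p.fe_trial:12.2f}  kg FPCM/kg DMI",
            f"Allocation factor (milk):    {self.impacts.allocation_factor:12.4f}",
            f"Enteric CH4 source:          {'measured (trial window)' if self.flows.ch4_measured else 'Tier-2 model':>24}",
            "-" * 60,
            f"{'Category':<10}{'per kg FPCM':>16}  unit",
        ]
        for cat in self.impacts.categories():
            lines.append(
                f"{cat:<10}{self.impacts.totals[cat]:>16.4g}  {CATEGORY_UNITS.get(cat, '')}"
            )
        lines.append("-" * 60)
        lines.append("CC contribution breakdown (kg CO2 eq/kg FPCM):")
        for source in SOURCES:
            value = self.impacts.per_kg.get("CC", {}).get(source)
            if value is not None:
                lines.append(f"  {SOURCE_LABELS[source]:<18}{value:>12.4f}")
        return "\n".join(lines)

    def plot_contributions(self, category: str = "CC", ax=None):
        """Bar chart of the per-source breakdown for one category."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        breakdown = self.impacts.per_kg[category]
        labels = [SOURCE_LABELS[s] for s in SOURCES if s in breakdown]
        values = [breakdown[s] for s in SOURCES if s in breakdown]
        ax.bar(labels, values)
        ax.set_ylabel(f"{category} ({CATEGORY_UNITS.get(category, '')}/kg FPCM)")
        ax.set_title(self.system.label)
        ax.tick_params(axis="x", rotation=60)
        return ax


class DairySystemLCA:
    """One cradle-to-farm-gate dairy system assessment.

    Parameters
    ----------
    system : FarmSystem
        Trial record, reference system and ration.
    ef_table : EmissionFactorTable
        Background factors for feed, utilities and the additive.
    params, cf : optional
        Emission-model parameters and characterization factors.
    control : TrialRecord, optional
        Control record driving the outside-window extrapolation when this
        system is a treatment group.
    """

    def __init__(
        self,
        system: FarmSystem,
        ef_table: EmissionFactorTable,
        params: Optional[EmissionParams] = None,
        cf: Optional[CharacterizationFactors] = None,
        control: Optional[TrialRecord] = None,
    ):
        self.system = system
        self.ef_table = ef_table
        self.params = params
        self.cf = cf
        self.control = control

    @classmethod
    def from_files(cls, system_path, ef_path, **kwargs) -> "DairySystemLCA":
        from .io import read_ef_table, read_farm_system

        return cls(read_farm_system(system_path), read_ef_table(ef_path), **kwargs)

    def fit(self, window_only: bool = False) -> SystemLCAResults:
        return evaluate_system(
            self.system,
            self.ef_table,
            params=self.params,
            cf=self.cf,
            control_trial=self.control,
            window_only=window_only,
        )


class ComparisonResults:
    """Fitted paired comparison with access to both per-system results."""

    def __init__(
        self,
        report: ComparisonReport,
        control_results: SystemLCAResults,
        treatment_results: SystemLCAResults,
    ):
        self.report = report
        self.control_results = control_results
        self.treatment_results = treatment_results

    def diff_pct(self, category: str = "CC") -> float:
        return self.report.categories[category].diff_pct

    def summary(self) -> str:
        title = "Paired comparison" + (
            " (supplementation window only)" if self.report.window_only else " (annual)"
        )
        lines = [
            f"{title}: {self.report.label}",
            "=" * 72,
            f"{'Category':<10}{'Unit':<14}{'Control':>12}{'Treatment':>12}{'Diff':>9}",
        ]
        for cat, comp in self.report.categories.items():
            lines.append(
                f"{cat:<10}{CATEGORY_UNITS.get(cat, ''):<14}"
                f"{comp.control:>12.4g}{comp.treatment:>12.4g}{comp.diff_pct:>8.2f}%"
            )
        cc = self.report.categories.get("CC")
        if cc is not None and cc.additive_share_pct is not None:
            lines.append(
                f"Additive share of treatment carbon footprint: {cc.additive_share_pct:.4f}%"
            )
        return "\n".join(lines)


class PairedTrialLCA:
    """Paired control-vs-supplemented assessment of one feeding trial.

    The treatment system inherits the control group's outside-window feed
    intake so that the two systems differ only through trial effects.
    """

    def __init__(
        self,
        control_system: FarmSystem,
        treatment_system: FarmSystem,
        ef_table: EmissionFactorTable,
        params: Optional[EmissionParams] = None,
        cf: Optional[CharacterizationFactors] = None,
    ):
        if control_system.trial.group_label != "control":
            raise InvalidInputError("control_system must carry a control trial record")
        self.control_system = control_system
        self.treatment_system = treatment_system
        self.ef_table = ef_table
        self.params = params
        self.cf = cf

    def fit(self, window_only: bool = False) -> ComparisonResults:
        if window_only:
            report = supplementation_window_compare(
                self.control_system,
                self.treatment_system,
                self.ef_table,
                params=self.params,
                cf=self.cf,
            )
            res_c = evaluate_system(
                self.control_system, self.ef_table, self.params, self.cf, window_only=True
            )
            res_t = evaluate_system(
                self.treatment_system,
                self.ef_table,
                self.params,
                self.cf,
                control_trial=self.control_system.trial,
                window_only=True,
            )
            return ComparisonResults(report, res_c, res_t)
        res_c = evaluate_system(self.control_system, self.ef_table, self.params, self.cf)
        res_t = evaluate_system(
            self.treatment_system,
            self.ef_table,
            self.params,
            self.cf,
            control_trial=self.control_system.trial,
        )
        report = compare_impacts(
            res_c.impacts,
            res_t.impacts,
            label=f"{self.control_system.label} vs {self.treatment_system.label}",
        )
        return ComparisonResults(report, res_c, res_t)

    def monte_carlo(
        self, n_iter: int = 1000, seed: Optional[int] = None, paired: bool = True
    ) -> MonteCarloResult:
        return _monte_carlo(
            self.control_system,
            self.treatment_system,
            self.ef_table,
            n_iter=n_iter,
            seed=seed,
            paired=paired,
            params=self.params,
            cf=self.cf,
        )

    def sensitivity(
        self, parameters: list[str], perturbation: float = 0.1, category: str = "CC"
    ) -> list[SensitivityItem]:
        return _sensitivity_oat(
            self.control_system,
            self.treatment_system,
            self.ef_table,
            parameters,
            perturbation=perturbation,
            params=self.params,
            cf=self.cf,
            category=category,
        )
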