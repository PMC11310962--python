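"""Characterization into midpoint categories, biophysical milk/meat
allocation, normalization per kg FPCM, and contribution analysis.

The milk allocation factor is the dairy biophysical rule

    AF = 1 - 6.04 * Mmeat / Mmilk

with Mmilk the fat- and protein-corrected milk sold per year and Mmeat the
live weight of animals sold; the meat share is the complement 1 - AF.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .categories import CATEGORIES, SOURCES
from .datamodel import AnnualHerdProfile
from .emissions import EmissionFlows
from .errors import AllocationCollapseError, InvalidInputError, ZeroDivisionInputError
from .feed import FeedFootprint

BIOPHYSICAL_SLOPE = 6.04


class CharacterizationFactors(BaseModel):
    """Midpoint characterization factors per emission flow.

    Climate-change factors default to AR6 GWP100 values; acidification and
    eutrophication use PEF-style midpoint factors. All configurable because
    absolute results depend on the factor vintage.
    """

    gwp_ch4: float = Field(default=27.0, ge=0, description="kg CO2 eq/kg biogenic CH4")
    gwp_ch4_fossil: float = Field(default=29.8, ge=0)
    gwp_n2o: float = Field(default=273.0, ge=0)
    nh3_tfwac: float = Field(default=3.02, ge=0, description="mol H+ eq/kg NH3")
    nh3_teu: float = Field(default=4.25, ge=0, description="mol N eq/kg NH3")
    n_leach_meu: float = Field(default=300.0, ge=0, description="g N eq/kg N leached")


class ImpactResult(BaseModel):
    """Per-functional-unit impacts with the per-source breakdown.

    ``per_kg[category][source]`` holds impact per kg FPCM after allocation;
    ``totals[category]`` equals the breakdown sum (checked to 1e-12 relative).
    """

    per_kg: dict[str, dict[str, float]]
    totals: dict[str, float]
    allocation_factor: float = Field(gt=0, le=1)
    fpcm_annual: float = Field(gt=0)
    ch4_measured: bool = False

    @model_validator(mode="after")
    def _closure(self) -> "ImpactResult":
        for cat, breakdown in self.per_kg.items():
            total = self.totals.get(cat)
            if total is None:
                raise ValueError(f"missing total for category {cat!r}")
            s = sum(breakdown.values())
            if abs(s - total) > 1e-12 * max(1.0, abs(total)):
                raise ValueError(f"breakdown does not sum to total for {cat!r}")
            if any(v < 0 for v in breakdown.values()):
                raise ValueError(f"negative per-kg value in {cat!r}")
        return self

    def categories(self) -> tuple[str, ...]:
        return tuple(self.per_kg)

    @classmethod
    def from_breakdowns(
        cls,
        per_kg: dict[str, dict[str, float]],
        allocation_factor: float = 1.0,
        fpcm_annual: float = 1.0,
    ) -> "ImpactResult":
        """Build a result directly from per-kg breakdown tables (e.g. published
        contribution analyses used as comparison inputs)."""
        totals = {cat: sum(bd.values()) for cat, bd in per_kg.items()}
        return cls(
            per_kg=per_kg,
            totals=totals,
            allocation_factor=allocation_factor,
            fpcm_annual=fpcm_annual,
        )


def allocation_factor(m_meat: float, m_milk_fpcm: float) -> float:
    """Milk share of farm impacts under biophysical allocation."""
    if m_milk_fpcm <= 0:
        raise ZeroDivisionInputError("m_milk_fpcm must be > 0")
    if m_meat < 0:
        raise InvalidInputError("m_meat must be >= 0")
    ratio = BIOPHYSICAL_SLOPE * m_meat / m_milk_fpcm
    if ratio >= 1.0:
        raise AllocationCollapseError(
            f"6.04 * Mmeat / Mmilk = {ratio:.3f} >= 1: allocation collapses"
        )
    return 1.0 - ratio


def characterize(
    flows: EmissionFlows,
    feed: FeedFootprint,
    cf: CharacterizationFactors,
    profile: AnnualHerdProfile,
    af: float,
    utility: Optional[dict[str, dict[str, float]]] = None,
) -> ImpactResult:
    """Characterize flows and feed impacts into per-kg-FPCM category scores.

    Per category: total = AF x (sum over source rows) / FPCM_annual, keeping
    the nine-source breakdown. ``utility`` carries the pre-computed per-
    category impacts of fuel, energy/bedding and water items.
    """
    if profile.fpcm_annual <= 0:
        raise ZeroDivisionInputError("fpcm_annual must be > 0")
    if not 0 < af <= 1:
        raise InvalidInputError(f"allocation factor must be in (0, 1], got {af}")
    utility = utility or {
        "onfarm_co2": {cat: 0.0 for cat in CATEGORIES},
        "energy": {cat: 0.0 for cat in CATEGORIES},
        "water": {cat: 0.0 for cat in CATEGORIES},
    }
    scale = af / profile.fpcm_annual
    per_kg: dict[str, dict[str, float]] = {}
    for cat in CATEGORIES:
        row = {source: 0.0 for source in SOURCES}
        row["feed_compounds"] = feed.compound.get(cat, 0.0)
        row["roughages"] = feed.roughages.get(cat, 0.0)
        row["additive"] = feed.additive.get(cat, 0.0)
        row["luc"] = feed.luc.get(cat, 0.0)
        row["onfarm_co2"] = utility["onfarm_co2"].get(cat, 0.0)
        row["energy"] = utility["energy"].get(cat, 0.0)
        row["water"] = utility["water"].get(cat, 0.0)
        if cat == "CC":
            row["onfarm_ch4"] = flows.ch4_total * cf.gwp_ch4
            row["onfarm_n2o"] = flows.n2o_total * cf.gwp_n2o
            row["onfarm_co2"] += flows.co2_energy
        elif cat == "TFWAC":
            row["onfarm_n2o"] += flows.nh3 * cf.nh3_tfwac
        elif cat == "TEU":
            row["onfarm_n2o"] += flows.nh3 * cf.nh3_teu
        elif cat == "MEU":
            row["onfarm_n2o"] += flows.n_leached * cf.n_leach_meu
        per_kg[cat] = {source: value * scale for source, value in row.items()}
    totals = {cat: sum(per_kg[cat].values()) for cat in CATEGORIES}
    return ImpactResult(
        per_kg=per_kg,
        totals=totals,
        allocation_factor=af,
        fpcm_annual=profile.fpcm_annual,
        ch4_measured=flows.ch4_measured,
    )


def contribution_analysis(result: ImpactResult, category: str = "CC") -> dict[str, float]:
    """Per-source percentage shares of one category total (sum to 100)."""
    breakdown = result.per_kg.get(category)
    if breakdown is None:
        raise InvalidInputError(f"category {category!r} not in result")
    total = result.totals[category]
    if total <= 0:
        raise ZeroDivisionInputError(f"total for {category!r} must be > 0")
    return {source: value / total * 100.0 for source, value in breakdown.items()}
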