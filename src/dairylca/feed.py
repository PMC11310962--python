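"""Upstream feed-chain footprint: compound feed, roughages, the additive,
and land-use-change adders, all per cow-year before allocation."""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field

from .categories import CATEGORIES, LUC_COLUMN
from .datamodel import AnnualHerdProfile, Diet, EmissionFactorTable
from .errors import InvalidInputError


class FeedFootprint(BaseModel):
    """Per-category feed-chain impacts (impact units per cow-year).

    ``luc`` carries the land-use-change adder, populated from the dedicated
    LUC column of the emission-factor table (a climate-change lump; other
    categories stay zero).
    """

    compound: dict[str, float] = Field(default_factory=dict)
    roughages: dict[str, float] = Field(default_factory=dict)
    additive: dict[str, float] = Field(default_factory=dict)
    luc: dict[str, float] = Field(default_factory=dict)


def feed_impacts(
    profile: AnnualHerdProfile,
    diet: Optional[Diet],
    ef: EmissionFactorTable,
    additive_key: str = "yeast_probiotic",
) -> FeedFootprint:
    """Feed-chain impacts for one system.

    Each ingredient contributes ``fi_annual x share x EF(ingredient, cat)``;
    the additive contributes its annual mass times its own factors. Without a
    ration the feed rows are zero (the feed chain is then outside the model).
    """
    zeros = {cat: 0.0 for cat in CATEGORIES}
    compound = dict(zeros)
    roughage = dict(zeros)
    luc = dict(zeros)
    if diet is not None:
        for ing in diet.ingredients:
            mass = profile.fi_annual * ing.share_dm
            target = roughage if ing.is_roughage else compound
            for cat in CATEGORIES:
                target[cat] += mass * ef.factor(ing.key, cat)
            luc["CC"] += mass * ef.get(ing.key, LUC_COLUMN, 0.0)
    additive = dict(zeros)
    if profile.additive_mass_annual > 0:
        for cat in CATEGORIES:
            additive[cat] = profile.additive_mass_annual * ef.factor(additive_key, cat)
    return FeedFootprint(compound=compound, roughages=roughage, additive=additive, luc=luc)


def economic_allocation(coproducts: list[tuple[float, float]]) -> list[float]:
    """Value shares of crop-level coproducts: share_i = m_i p_i / sum m_j p_j.

    Used when building synthetic emission-factor rows from crop-process
    descriptions; shares sum to 1 exactly.
    """
    if not coproducts:
        raise InvalidInputError("at least one coproduct is required")
    values = []
    for mass, price in coproducts:
        if mass < 0 or price < 0:
            raise InvalidInputError("coproduct masses and prices must be >= 0")
        values.append(mass * price)
    total = sum(values)
    if total <= 0:
        raise InvalidInputError("total coproduct value must be > 0")
    return [v / total for v in values]
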