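"""Impact-category and source-row vocabulary shared by all stages.

The eight midpoint categories follow the EU Product Environmental Footprint
(PEF) naming used in dairy reporting; the nine source rows are the standard
cradle-to-farm-gate contribution breakdown (feed chain, on-farm gas flows,
utilities, the additive itself, and land-use change).
"""

from __future__ import annotations

#: Midpoint impact categories, in reporting order.
CATEGORIES: tuple[str, ...] = ("CC", "LU", "WU", "RU", "TFWAC", "FEU", "MEU", "TEU")

#: Fixed display units per category (one unit per quantity; no unit parsing).
CATEGORY_UNITS: dict[str, str] = {
    "CC": "kg CO2 eq",
    "LU": "Pt",
    "WU": "m3 depriv eq",
    "RU": "MJ",
    "TFWAC": "mol H+ eq",
    "FEU": "g P eq",
    "MEU": "g N eq",
    "TEU": "mol N eq",
}

CATEGORY_NAMES: dict[str, str] = {
    "CC": "climate change",
    "LU": "land use",
    "WU": "water use",
    "RU": "resource use (fossil)",
    "TFWAC": "terrestrial and freshwater acidification",
    "FEU": "freshwater eutrophication",
    "MEU": "marine eutrophication",
    "TEU": "terrestrial eutrophication",
}

#: Pseudo-category column of the emission-factor table holding the
#: land-use-change CO2 adder per kg of feed ingredient.
LUC_COLUMN = "LUC"

#: Source rows of the contribution breakdown, in reporting order.
SOURCES: tuple[str, ...] = (
    "feed_compounds",
    "roughages",
    "onfarm_co2",
    "onfarm_n2o",
    "onfarm_ch4",
    "energy",
    "water",
    "additive",
    "luc",
)

#: Human-readable row labels used by the plain-text contribution table.
SOURCE_LABELS: dict[str, str] = {
    "feed_compounds": "Feed compounds",
    "roughages": "Roughages",
    "onfarm_co2": "On farm CO2",
    "onfarm_n2o": "On-farm N2O",
    "onfarm_ch4": "On farm CH4",
    "energy": "Energy at Farm",
    "water": "Water at Farm",
    "additive": "Additive",
    "luc": "Land use change",
}
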