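"""Domain types shared by every pipeline stage.

All quantities carry one fixed unit per field (kg, d, MJ, %); lactation
windows are 1-based inclusive days in milk, so a window from day 1 to day
108 has a duration of 108 days.
"""

from __future__ import annotations

from typing import Literal, Optional

import pandas as pd
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

from .categories import CATEGORIES, LUC_COLUMN
from .errors import DuplicateFactorError, InvalidInputError, MissingFactorError

GroupLabel = Literal["control", "treatment"]


class LactationWindow(BaseModel):
    """Inclusive 1-based days-in-milk window of a feeding trial."""

    model_config = ConfigDict(frozen=True)

    start_day: int = Field(ge=1)
    end_day: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "LactationWindow":
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")
        return self

    @property
    def duration(self) -> int:
        return self.end_day - self.start_day + 1


class TrialRecord(BaseModel):
    """Per-group zootechnical measurements over a defined lactation window.

    Daily rates are per-cow group means; optional standard errors feed the
    Monte Carlo uncertainty stage. ``measured_ch4_daily``, when present,
    overrides the Tier-2 enteric model inside the trial window.
    """

    group_label: GroupLabel
    duration_days: int = Field(gt=0)
    window: LactationWindow
    milk_yield_daily: float = Field(gt=0, description="kg/cow/d")
    fat_pct: float = Field(gt=0, lt=10)
    protein_pct: float = Field(gt=0, lt=10)
    dmi_daily: float = Field(gt=0, description="kg DM/cow/d")
    additive_dose: float = Field(ge=0, description="g/cow/d")
    n_cows: int = Field(gt=0)
    measured_ch4_daily: Optional[float] = Field(default=None, gt=0, description="kg/cow/d")
    milk_yield_se: float = Field(default=0.0, ge=0)
    dmi_se: float = Field(default=0.0, ge=0)
    fat_se: float = Field(default=0.0, ge=0)
    protein_se: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _duration_consistent(self) -> "TrialRecord":
        if self.duration_days != self.window.duration:
            raise ValueError(
                "duration_days must equal end_day - start_day + 1 "
                f"({self.duration_days} != {self.window.duration})"
            )
        return self

    @property
    def milk_trial(self) -> float:
        """Cumulative milk over the trial window (kg/cow)."""
        return self.milk_yield_daily * self.duration_days

    @property
    def fi_trial(self) -> float:
        """Cumulative dry-matter intake over the trial window (kg DM/cow)."""
        return self.dmi_daily * self.duration_days

    @property
    def additive_mass_kg(self) -> float:
        """Additive fed over the trial (kg/cow): dose [g/d] x days / 1000."""
        return self.additive_dose * self.duration_days / 1000.0


class ReferenceSystem(BaseModel):
    """Country average-farm parameters filling in what the trial did not measure.

    ``milk_outside_window`` is the reference-system milk produced outside the
    trial window (shared by both groups); when absent it is pro-rated from the
    annual reference yield. ``fi_outside_override`` pins the outside-window
    feed intake when a published value should take precedence over the
    proportional extrapolation.
    """

    country_label: str
    annual_reference_milk: float = Field(ge=0, description="kg/cow/yr")
    lactation_days: int = Field(default=305, gt=0)
    dry_days: int = Field(default=60, ge=0)
    dry_period_fi: float = Field(default=600.0, ge=0, description="kg DM/cow")
    herd_coproduct_liveweight: float = Field(default=0.0, ge=0, description="kg LW sold/yr")
    herd_annual_fpcm_sold: Optional[float] = Field(default=None, gt=0)
    milk_outside_window: Optional[float] = Field(default=None, ge=0)
    fi_outside_override: Optional[float] = Field(default=None, ge=0)
    energy_use: dict[str, float] = Field(default_factory=dict)
    water_use: dict[str, float] = Field(default_factory=dict)
    bedding_use: dict[str, float] = Field(default_factory=dict)
    fuel_use: dict[str, float] = Field(default_factory=dict)
    manure_system_label: str = "liquid_slurry"

    @model_validator(mode="after")
    def _calendar(self) -> "ReferenceSystem":
        if self.lactation_days + self.dry_days > 366:
            raise ValueError("lactation_days + dry_days must be <= 366")
        for name in ("energy_use", "water_use", "bedding_use", "fuel_use"):
            for key, qty in getattr(self, name).items():
                if qty < 0:
                    raise ValueError(f"{name}[{key!r}] must be >= 0")
        return self


class DietIngredient(BaseModel):
    """One ration component with its dry-matter share and nutritional traits."""

    key: str
    share_dm: float = Field(gt=0, le=1)
    dm_fraction: float = Field(default=1.0, gt=0, le=1)
    ge_mj_per_kg_dm: float = Field(default=18.45, gt=0)
    cp_fraction: float = Field(default=0.165, ge=0, le=1)
    digestibility: float = Field(default=0.70, ge=0, le=1)
    is_roughage: bool = False


class Diet(BaseModel):
    """A ration as dry-matter shares; lets gross energy and crude protein be
    derived when the trial only reported intake."""

    ingredients: list[DietIngredient]

    @model_validator(mode="after")
    def _shares(self) -> "Diet":
        total = sum(i.share_dm for i in self.ingredients)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"DM shares must sum to 1 (got {total})")
        return self

    def _weighted(self, attr: str) -> float:
        return sum(i.share_dm * getattr(i, attr) for i in self.ingredients)

    @property
    def ge_density(self) -> float:
        """Share-weighted gross energy density (MJ/kg DM)."""
        return self._weighted("ge_mj_per_kg_dm")

    @property
    def cp_fraction(self) -> float:
        return self._weighted("cp_fraction")

    @property
    def digestibility(self) -> float:
        return self._weighted("digestibility")


class FarmSystem(BaseModel):
    """One runnable cradle-to-farm-gate system: trial + reference + ration.

    ``emission_overrides`` holds per-system emission-parameter values (e.g. a
    calibrated Ym) applied on top of the defaults at evaluation time.
    """

    label: str
    trial: TrialRecord
    reference: ReferenceSystem
    diet: Optional[Diet] = None
    gaei_annual: Optional[float] = Field(default=None, gt=0, description="MJ/cow/yr")
    allocation_mode: Literal["biophysical", "none"] = "biophysical"
    emission_overrides: dict[str, float] = Field(default_factory=dict)
    additive_key: str = "yeast_probiotic"

    def item_keys(self) -> set[str]:
        """Every emission-factor item this system references."""
        keys: set[str] = set()
        if self.diet is not None:
            keys |= {i.key for i in self.diet.ingredients}
        for use in (
            self.reference.energy_use,
            self.reference.water_use,
            self.reference.bedding_use,
            self.reference.fuel_use,
        ):
            keys |= set(use)
        if self.trial.additive_dose > 0:
            keys.add(self.additive_key)
        return keys


class AnnualHerdProfile(BaseModel):
    """Annualized per-cow profile: milk, FPCM, feed intake, gross energy.

    The intake decomposition ``fi_annual == fi_trial + fi_outside + fi_dry``
    is exact by construction and re-checked here.
    """

    milk_annual: float = Field(ge=0)
    fpcm_annual: float = Field(gt=0)
    fi_trial: float = Field(ge=0)
    fi_outside: float = Field(ge=0)
    fi_dry: float = Field(ge=0)
    fi_annual: float = Field(gt=0)
    ge_annual: float = Field(ge=0)
    fe_trial: float = Field(gt=0)
    additive_mass_annual: float = Field(ge=0)

    @model_validator(mode="after")
    def _decomposition(self) -> "AnnualHerdProfile":
        parts = self.fi_trial + self.fi_outside + self.fi_dry
        if abs(self.fi_annual - parts) > 1e-9 * max(1.0, parts):
            raise ValueError("fi_annual must equal fi_trial + fi_outside + fi_dry")
        return self


class EmissionFactorTable:
    """Per-item, per-category factors with lognormal uncertainty (gsd).

    The pluggable stand-in for proprietary background databases: rows are
    keyed by ``(item_key, category)`` where category is one of the eight
    midpoint categories or the land-use-change adder column.
    """

    VALID_COLUMNS = set(CATEGORIES) | {LUC_COLUMN}

    def __init__(self, cells: dict[tuple[str, str], tuple[float, float]]):
        for (item, cat), (value, gsd) in cells.items():
            if cat not in self.VALID_COLUMNS:
                raise InvalidInputError(f"unknown category {cat!r} for item {item!r}")
            if value < 0:
                raise InvalidInputError(f"negative factor for ({item!r}, {cat!r})")
            if gsd < 1.0:
                raise InvalidInputError(f"gsd must be >= 1 for ({item!r}, {cat!r})")
        self._cells = dict(cells)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, float]] | list[tuple[str, str, float, float]]
    ) -> "EmissionFactorTable":
        cells: dict[tuple[str, str], tuple[float, float]] = {}
        for rec in records:
            item, cat, value = rec[0], rec[1], float(rec[2])
            gsd = float(rec[3]) if len(rec) > 3 else 1.0
            if (item, cat) in cells:
                raise DuplicateFactorError(f"duplicate factor key ({item!r}, {cat!r})")
            cells[(item, cat)] = (value, gsd)
        return cls(cells)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EmissionFactorTable":
        required = {"item_key", "category", "factor"}
        if not required.issubset(frame.columns):
            raise InvalidInputError(
                f"emission-factor table needs columns {sorted(required)}"
            )
        records = []
        has_gsd = "gsd" in frame.columns
        for row in frame.itertuples(index=False):
            gsd = getattr(row, "gsd", None) if has_gsd else None
            if gsd is None or pd.isna(gsd):
                gsd = 1.0
            records.append((str(row.item_key), str(row.category), float(row.factor), float(gsd)))
        return cls.from_records(records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item_key": item, "category": cat, "factor": value, "gsd": gsd}
            for (item, cat), (value, gsd) in sorted(self._cells.items())
        ]
        return pd.DataFrame(rows, columns=["item_key", "category", "factor", "gsd"])

    # -- access -----------------------------------------------------------
    def factor(self, item_key: str, category: str) -> float:
        try:
            return self._cells[(item_key, category)][0]
        except KeyError:
            raise MissingFactorError(item_key, category) from None

    def get(self, item_key: str, category: str, default: float = 0.0) -> float:
        cell = self._cells.get((item_key, category))
        return cell[0] if cell is not None else default

    def gsd(self, item_key: str, category: str) -> float:
        cell = self._cells.get((item_key, category))
        return cell[1] if cell is not None else 1.0

    def has_item(self, item_key: str) -> bool:
        return any(item == item_key for item, _ in self._cells)

    def items(self) -> set[str]:
        return {item for item, _ in self._cells}

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._cells)

    def __len__(self) -> int:
        return len(self._cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmissionFactorTable):
            return NotImplemented
        return self._cells == other._cells

    # -- transforms -------------------------------------------------------
    def scaled(self, multipliers: dict[tuple[str, str], float]) -> "EmissionFactorTable":
        """A copy with per-cell multiplicative perturbations (Monte Carlo draws)."""
        cells = {
            key: (value * multipliers.get(key, 1.0), gsd)
            for key, (value, gsd) in self._cells.items()
        }
        return EmissionFactorTable(cells)

    def with_uniform_gsd(self, gsd: float) -> "EmissionFactorTable":
        """A copy assigning one geometric standard deviation to every cell."""
        return EmissionFactorTable(
            {key: (value, gsd) for key, (value, _) in self._cells.items()}
        )

    def resolve(self, item_keys: set[str]) -> None:
        """Raise :class:`MissingFactorError` if any item has no row at all."""
        table_items = self.items()
        for key in sorted(item_keys):
            if key not in table_items:
                raise MissingFactorError(key, "*")
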