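"""On-farm emission flows per cow-year.

Enteric methane follows the IPCC Tier-2 form (gross energy intake times the
methane conversion factor Ym over the energy density of methane); manure
methane uses volatile-solids excretion times B0 and the manure-system MCF;
manure nitrous oxide uses excreted nitrogen with direct (EF3) and indirect
(volatilization EF4, leaching EF5) pathways. Ammonia, NMVOC and particulate
matter use inventory-guidebook-style per-head factors.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .categories import CATEGORIES
from .datamodel import (
    AnnualHerdProfile,
    Diet,
    EmissionFactorTable,
    ReferenceSystem,
    TrialRecord,
)
from .errors import InvalidInputError

#: kg N per kg crude protein.
CP_TO_N = 1.0 / 6.25
#: Molar conversions.
N2O_N_TO_N2O = 44.0 / 28.0
NH3_N_TO_NH3 = 17.0 / 14.0
#: Volumetric CH4 density (kg/m3) in the manure pathway.
CH4_DENSITY = 0.67


class EmissionParams(BaseModel):
    """Tunable parameters of the on-farm emission models.

    Defaults are Tier-2 dairy conventions (Ym 6.5% of gross energy, methane
    energy density 55.65 MJ/kg, B0 0.24 m3 CH4/kg VS, liquid-slurry MCF);
    every value is configurable per system.
    """

    ym: float = Field(default=6.5, gt=0, lt=15, description="% of GE as enteric CH4")
    ch4_energy_density: float = Field(default=55.65, gt=0, description="MJ/kg CH4")
    digestibility: float = Field(default=0.70, ge=0, le=1)
    ash_fraction: float = Field(default=0.08, ge=0, le=1)
    urinary_energy_fraction: float = Field(default=0.04, ge=0, le=1)
    b0: float = Field(default=0.24, ge=0, description="m3 CH4/kg VS")
    mcf: float = Field(default=0.17, ge=0, le=1)
    cp_fraction: float = Field(default=0.165, ge=0, le=1)
    n_intake_annual: Optional[float] = Field(default=None, ge=0, description="kg N/cow/yr")
    n_retention_fraction: float = Field(default=0.25, ge=0, le=1)
    ef3: float = Field(default=0.005, ge=0, le=1, description="kg N2O-N/kg N")
    frac_gas: float = Field(default=0.30, ge=0, le=1)
    ef4: float = Field(default=0.01, ge=0, le=1)
    frac_leach: float = Field(default=0.10, ge=0, le=1)
    ef5: float = Field(default=0.011, ge=0, le=1)
    nh3_ef: Optional[float] = Field(default=None, ge=0, description="kg NH3/cow/yr")
    nmvoc_ef: float = Field(default=8.9, ge=0, description="kg/cow/yr")
    pm10_ef: float = Field(default=0.63, ge=0)
    pm25_ef: float = Field(default=0.41, ge=0)

    @model_validator(mode="after")
    def _sane(self) -> "EmissionParams":
        if self.digestibility + self.urinary_energy_fraction > 1.0:
            raise ValueError("digestibility + urinary_energy_fraction must be <= 1")
        return self


class EmissionFlows(BaseModel):
    """Per-cow-year emission masses (kg), plus bookkeeping for nitrogen fate."""

    ch4_enteric: float = Field(ge=0)
    ch4_manure: float = Field(ge=0)
    n2o_direct: float = Field(ge=0)
    n2o_indirect: float = Field(ge=0)
    nh3: float = Field(ge=0)
    n_leached: float = Field(ge=0)
    nmvoc: float = Field(ge=0)
    pm10: float = Field(ge=0)
    pm25: float = Field(ge=0)
    co2_energy: float = Field(ge=0)
    ch4_measured: bool = False

    @property
    def ch4_total(self) -> float:
        return self.ch4_enteric + self.ch4_manure

    @property
    def n2o_total(self) -> float:
        return self.n2o_direct + self.n2o_indirect


def enteric_ch4(ge_annual: float, params: EmissionParams) -> float:
    """Tier-2 enteric methane (kg/yr): GE x Ym/100 / energy density."""
    if ge_annual < 0:
        raise InvalidInputError("ge_annual must be >= 0")
    return ge_annual * params.ym / 100.0 / params.ch4_energy_density


def vs_excretion(fi_annual: float, params: EmissionParams) -> float:
    """Volatile solids excreted (kg/yr): intake-derived organic matter that is
    neither digested nor mineral, plus the urinary fraction."""
    if fi_annual < 0:
        raise InvalidInputError("fi_annual must be >= 0")
    return (
        fi_annual
        * (1.0 - params.digestibility + params.urinary_energy_fraction)
        * (1.0 - params.ash_fraction)
    )


def manure_ch4(fi_annual: float, params: EmissionParams) -> float:
    """Manure-management methane (kg/yr): VS x B0 x 0.67 x MCF."""
    return vs_excretion(fi_annual, params) * params.b0 * CH4_DENSITY * params.mcf


def n_intake_annual(fi_annual: float, params: EmissionParams, diet: Optional[Diet] = None) -> float:
    """Annual nitrogen intake (kg N): supplied directly, or from crude protein
    (N = CP/6.25) using the ration's CP when a diet is present."""
    if params.n_intake_annual is not None:
        return params.n_intake_annual
    cp = diet.cp_fraction if diet is not None else params.cp_fraction
    return fi_annual * cp * CP_TO_N


def manure_n2o(n_excreted: float, params: EmissionParams) -> tuple[float, float, float]:
    """Direct and indirect N2O plus NH3 from excreted nitrogen (kg/yr).

    direct   = Nex x EF3 x 44/28
    indirect = (Nex x FracGas x EF4 + Nex x FracLeach x EF5) x 44/28
    NH3      = Nex x FracGas x 17/14 (unless a per-head factor overrides)
    """
    if n_excreted < 0:
        raise InvalidInputError("n_excreted must be >= 0")
    direct = n_excreted * params.ef3 * N2O_N_TO_N2O
    indirect = (
        n_excreted * params.frac_gas * params.ef4
        + n_excreted * params.frac_leach * params.ef5
    ) * N2O_N_TO_N2O
    nh3 = (
        params.nh3_ef
        if params.nh3_ef is not None
        else n_excreted * params.frac_gas * NH3_N_TO_NH3
    )
    return direct, indirect, nh3


def utility_impacts(
    ref: ReferenceSystem, ef: EmissionFactorTable, scale: float = 1.0
) -> dict[str, dict[str, float]]:
    """Per-category impacts of utility items (per cow-year, before allocation).

    Returns three source rows: ``onfarm_co2`` (fuel combustion), ``energy``
    (purchased energy plus bedding material) and ``water``. ``scale``
    pro-rates utility use for window-only accounting.
    """
    groups = {
        "onfarm_co2": [ref.fuel_use],
        "energy": [ref.energy_use, ref.bedding_use],
        "water": [ref.water_use],
    }
    out: dict[str, dict[str, float]] = {}
    for source, uses in groups.items():
        out[source] = {
            cat: sum(
                qty * scale * ef.factor(item, cat) for use in uses for item, qty in use.items()
            )
            for cat in CATEGORIES
        }
    return out


def utility_co2(ref: ReferenceSystem, ef: EmissionFactorTable, scale: float = 1.0) -> float:
    """On-farm CO2 from fuel combustion (kg CO2/yr)."""
    return utility_impacts(ref, ef, scale=scale)["onfarm_co2"]["CC"]


def compute_flows(
    profile: AnnualHerdProfile,
    params: EmissionParams,
    trial: Optional[TrialRecord] = None,
    diet: Optional[Diet] = None,
    utility_co2_mass: float = 0.0,
) -> EmissionFlows:
    """Assemble all on-farm flows for one annualized system.

    When the trial carries measured daily enteric CH4, the measurement feeds
    the inventory inside the trial window and the Tier-2 model covers the
    rest of the year (flagged via ``ch4_measured``).
    """
    if trial is not None and trial.measured_ch4_daily is not None:
        ch4_window = trial.measured_ch4_daily * trial.duration_days
        if profile.fi_annual > 0:
            ge_window = profile.ge_annual * profile.fi_trial / profile.fi_annual
        else:
            ge_window = 0.0
        ch4_ent = ch4_window + enteric_ch4(max(profile.ge_annual - ge_window, 0.0), params)
        measured = True
    else:
        ch4_ent = enteric_ch4(profile.ge_annual, params)
        measured = False
    ch4_man = manure_ch4(profile.fi_annual, params)
    n_in = n_intake_annual(profile.fi_annual, params, diet)
    nex = n_in * (1.0 - params.n_retention_fraction)
    n2o_d, n2o_i, nh3 = manure_n2o(nex, params)
    return EmissionFlows(
        ch4_enteric=ch4_ent,
        ch4_manure=ch4_man,
        n2o_direct=n2o_d,
        n2o_indirect=n2o_i,
        nh3=nh3,
        n_leached=nex * params.frac_leach,
        nmvoc=params.nmvoc_ef,
        pm10=params.pm10_ef,
        pm25=params.pm25_ef,
        co2_energy=utility_co2_mass,
        ch4_measured=measured,
    )
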