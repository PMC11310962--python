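"""Annualization of trial-window records into per-cow yearly profiles.

A feeding trial covers part of one lactation. Annual figures combine the
trial window with reference-system milk outside the window (identical for
control and treatment, so the only group differences are trial effects),
feed intake extrapolated in proportion to milk yield, and a fixed dry-period
intake. FPCM is the fat- and protein-corrected milk normalization:

    FPCM (kg) = milk (kg) x (0.1226 * fat% + 0.0776 * protein% + 0.2534)
"""

from __future__ import annotations

from typing import Optional

from .datamodel import AnnualHerdProfile, Diet, ReferenceSystem, TrialRecord
from .errors import InvalidInputError, ZeroDivisionInputError

#: FPCM correction coefficients (European Commission definition).
FPCM_FAT_COEF = 0.1226
FPCM_PROTEIN_COEF = 0.0776
FPCM_CONST = 0.2534

#: Default dietary gross-energy density (MJ/kg DM) when no ration is supplied.
DEFAULT_GE_DENSITY = 18.45


def fpcm_factor(fat_pct: float, protein_pct: float) -> float:
    """Milk-to-FPCM correction factor for a given composition."""
    for name, value in (("fat_pct", fat_pct), ("protein_pct", protein_pct)):
        if not 0.0 <= value < 10.0:
            raise InvalidInputError(f"{name} must be in [0, 10), got {value}")
    return FPCM_FAT_COEF * fat_pct + FPCM_PROTEIN_COEF * protein_pct + FPCM_CONST


def fpcm(milk_kg: float, fat_pct: float, protein_pct: float) -> float:
    """Fat- and protein-corrected milk mass (kg FPCM)."""
    if milk_kg < 0:
        raise InvalidInputError(f"milk_kg must be >= 0, got {milk_kg}")
    return milk_kg * fpcm_factor(fat_pct, protein_pct)


def extrapolate_fi_outside(fi_trial: float, my_outside: float, my_trial: float) -> float:
    """Feed intake outside the trial window, scaled in proportion to milk:

        FI_outside = FI_trial * MY_outside / MY_trial
    """
    if my_trial <= 0:
        raise ZeroDivisionInputError(
            "trial-window milk yield must be > 0 to extrapolate feed intake"
        )
    if fi_trial < 0 or my_outside < 0:
        raise InvalidInputError("masses must be >= 0")
    return fi_trial * my_outside / my_trial


def milk_outside_window(trial: TrialRecord, ref: ReferenceSystem) -> float:
    """Reference-system milk outside the trial window (kg/cow).

    Uses the reference system's stated value when present, else pro-rates the
    annual reference yield over the remaining lactation days. Shared by both
    groups of a pair by construction (it depends only on the window length).
    """
    if ref.milk_outside_window is not None:
        return ref.milk_outside_window
    remaining = ref.lactation_days - trial.duration_days
    if remaining < 0:
        raise InvalidInputError(
            f"trial window ({trial.duration_days} d) exceeds the lactation "
            f"period ({ref.lactation_days} d)"
        )
    return ref.annual_reference_milk * remaining / ref.lactation_days


def annualize(
    trial: TrialRecord,
    ref: ReferenceSystem,
    control: Optional[TrialRecord] = None,
    gaei_annual: Optional[float] = None,
    diet: Optional[Diet] = None,
) -> AnnualHerdProfile:
    """Build the annual per-cow profile from a trial record and reference system.

    ``control`` supplies the record whose trial-window intake and milk drive
    the outside-window extrapolation; treatment groups receive the control
    group's outside-window intake so that groups differ only inside the
    window. When omitted, the record extrapolates from itself.

    Gross energy comes from ``gaei_annual`` when supplied, else from the
    ration's energy density (default 18.45 MJ/kg DM) applied to annual intake.
    """
    if trial.duration_days > ref.lactation_days:
        raise InvalidInputError(
            f"trial window ({trial.duration_days} d) exceeds the lactation "
            f"period ({ref.lactation_days} d)"
        )
    basis = control if control is not None else trial
    my_out = milk_outside_window(trial, ref)
    if ref.fi_outside_override is not None:
        fi_outside = ref.fi_outside_override
    elif my_out == 0.0:
        fi_outside = 0.0
    else:
        fi_outside = extrapolate_fi_outside(basis.fi_trial, my_out, basis.milk_trial)

    milk_annual = trial.milk_trial + my_out
    fpcm_annual = fpcm(milk_annual, trial.fat_pct, trial.protein_pct)
    fi_annual = trial.fi_trial + fi_outside + ref.dry_period_fi
    ge_density = diet.ge_density if diet is not None else DEFAULT_GE_DENSITY
    ge_annual = gaei_annual if gaei_annual is not None else fi_annual * ge_density
    fe_trial = fpcm(trial.milk_yield_daily, trial.fat_pct, trial.protein_pct) / trial.dmi_daily
    return AnnualHerdProfile(
        milk_annual=milk_annual,
        fpcm_annual=fpcm_annual,
        fi_trial=trial.fi_trial,
        fi_outside=fi_outside,
        fi_dry=ref.dry_period_fi,
        fi_annual=fi_annual,
        ge_annual=ge_annual,
        fe_trial=fe_trial,
        additive_mass_annual=trial.additive_mass_kg,
    )


def window_profile(
    trial: TrialRecord,
    gaei_annual: Optional[float] = None,
    fi_annual_full: Optional[float] = None,
    diet: Optional[Diet] = None,
) -> AnnualHerdProfile:
    """Trial-window-only profile for supplementation-period accounting.

    Outside-window and dry-period terms are zero; gross energy is the
    window's share of the annual figure when one is supplied (keeping the
    implied energy density consistent), else density times window intake.
    """
    fi_window = trial.fi_trial
    if gaei_annual is not None and fi_annual_full:
        ge = gaei_annual * fi_window / fi_annual_full
    else:
        density = diet.ge_density if diet is not None else DEFAULT_GE_DENSITY
        ge = fi_window * density
    return AnnualHerdProfile(
        milk_annual=trial.milk_trial,
        fpcm_annual=fpcm(trial.milk_trial, trial.fat_pct, trial.protein_pct),
        fi_trial=fi_window,
        fi_outside=0.0,
        fi_dry=0.0,
        fi_annual=fi_window,
        ge_annual=ge,
        fe_trial=fpcm(trial.milk_yield_daily, trial.fat_pct, trial.protein_pct)
        / trial.dmi_daily,
        additive_mass_annual=trial.additive_mass_kg,
    )
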