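"""On-farm emission models: Tier-2 enteric CH4, manure CH4/N2O, utilities."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dairylca as d
from dairylca.emissions import (
    compute_flows,
    enteric_ch4,
    manure_ch4,
    manure_n2o,
    n_intake_annual,
    utility_co2,
    utility_impacts,
    vs_excretion,
)
from dairylca.errors import InvalidInputError
from dairylca.model import evaluate_system


class TestEntericCH4:
    def test_tier2_form(self):
        params = d.EmissionParams(ym=6.5)
        # 122,122 MJ of gross energy at the default conversion factor
        assert enteric_ch4(122122.0, params) == pytest.approx(142.65, abs=0.01)

    def test_zero_energy(self):
        assert enteric_ch4(0.0, d.EmissionParams()) == 0.0

    @given(ge=st.floats(0, 2e5), scale=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_homogeneous_in_energy(self, ge, scale):
        params = d.EmissionParams()
        assert enteric_ch4(ge * scale, params) == pytest.approx(
            scale * enteric_ch4(ge, params), rel=1e-12, abs=1e-12
        )


class TestManureCH4:
    def test_closed_form(self):
        params = d.EmissionParams(
            digestibility=0.70, ash_fraction=0.08, urinary_energy_fraction=0.04, mcf=0.10
        )
        fi = 1000.0 / (0.34 * 0.92)  # intake giving exactly 1000 kg VS
        assert vs_excretion(fi, params) == pytest.approx(1000.0)
        assert manure_ch4(fi, params) == pytest.approx(16.08, abs=1e-9)

    def test_zero_intake(self):
        assert manure_ch4(0.0, d.EmissionParams()) == 0.0

    def test_linear_in_mcf(self):
        p1 = d.EmissionParams(mcf=0.1)
        p2 = d.EmissionParams(mcf=0.2)
        assert manure_ch4(5000.0, p2) == pytest.approx(2 * manure_ch4(5000.0, p1))


class TestManureN2O:
    def test_stoichiometric_direct(self):
        params = d.EmissionParams(ef3=0.02)
        direct, _, _ = manure_n2o(100.0, params)
        assert direct == pytest.approx(100.0 * 0.02 * 44.0 / 28.0, rel=1e-12)
        assert direct == pytest.approx(3.143, abs=0.001)

    def test_zero_excretion(self):
        assert manure_n2o(0.0, d.EmissionParams()) == (0.0, 0.0, 0.0)

    def test_no_volatilization_no_leaching(self):
        params = d.EmissionParams(frac_gas=0.0, frac_leach=0.0)
        _, indirect, nh3 = manure_n2o(50.0, params)
        assert indirect == 0.0 and nh3 == 0.0

    def test_negative_excretion_raises(self):
        with pytest.raises(InvalidInputError):
            manure_n2o(-1.0, d.EmissionParams())

    def test_nitrogen_intake_routes(self):
        params = d.EmissionParams(cp_fraction=0.16)
        assert n_intake_annual(6250.0, params) == pytest.approx(6250.0 * 0.16 / 6.25)
        direct_params = d.EmissionParams(n_intake_annual=120.0)
        assert n_intake_annual(6250.0, direct_params) == 120.0


class TestUtilities:
    def test_no_utilities_zero(self):
        ref = d.ReferenceSystem(country_label="x", annual_reference_milk=9000.0)
        ef = d.EmissionFactorTable.from_records([("electricity", "CC", 0.3)])
        assert utility_co2(ref, ef) == 0.0

    def test_quantity_times_factor(self):
        ref = d.ReferenceSystem(
            country_label="x", annual_reference_milk=9000.0,
            fuel_use={"diesel": 1000.0},
        )
        ef = d.EmissionFactorTable.from_records(
            [("diesel", cat, 0.3 if cat == "CC" else 0.0) for cat in d.CATEGORIES]
        )
        assert utility_co2(ref, ef) == pytest.approx(300.0)

    def test_missing_item_named(self):
        ref = d.ReferenceSystem(
            country_label="x", annual_reference_milk=9000.0,
            energy_use={"mystery": 10.0},
        )
        ef = d.EmissionFactorTable.from_records([("diesel", "CC", 0.3)])
        with pytest.raises(d.errors.MissingFactorError, match="mystery"):
            utility_impacts(ref, ef)


class TestMeasuredOverride:
    def test_measured_ch4_feeds_window_inventory(self, fixtures):
        control, _ = fixtures.pair("uk")
        res = evaluate_system(control, fixtures.ef_table)
        assert res.flows.ch4_measured
        # the measured window mass (0.467 kg/d x 120 d) is a floor
        assert res.flows.ch4_enteric > 0.467 * 120

    def test_override_changes_only_ch4(self, fixtures):
        control, _ = fixtures.pair("uk")
        res_meas = evaluate_system(control, fixtures.ef_table)
        modelled = control.model_copy(
            update={"trial": control.trial.model_copy(update={"measured_ch4_daily": None})}
        )
        res_model = evaluate_system(modelled, fixtures.ef_table)
        assert res_meas.flows.ch4_enteric != res_model.flows.ch4_enteric
        for field in ("ch4_manure", "n2o_direct", "n2o_indirect", "nh3", "co2_energy"):
            assert getattr(res_meas.flows, field) == getattr(res_model.flows, field)
        for cat in d.CATEGORIES:
            for source, value in res_meas.impacts.per_kg[cat].items():
                if source != "onfarm_ch4":
                    assert value == res_model.impacts.per_kg[cat][source]


def test_flows_nonnegative_across_scenarios(scenario):
    pairs, ef = scenario
    for control, treatment in pairs:
        for system, basis in ((control, None), (treatment, control.trial)):
            res = evaluate_system(system, ef, control_trial=basis)
            flows = res.flows
            assert min(
                flows.ch4_enteric, flows.ch4_manure, flows.n2o_direct,
                flows.n2o_indirect, flows.nh3, flows.nmvoc, flows.pm10, flows.pm25,
            ) >= 0


def test_flows_scale_with_drivers():
    profile_kwargs = dict(
        milk_annual=9000.0, fpcm_annual=9000.0, fi_trial=2000.0, fi_outside=2500.0,
        fi_dry=600.0, fi_annual=5100.0, ge_annual=5100.0 * 18.45, fe_trial=1.6,
        additive_mass_annual=0.0,
    )
    profile = d.AnnualHerdProfile(**profile_kwargs)
    doubled = d.AnnualHerdProfile(
        **{
            **profile_kwargs,
            "fi_trial": 4000.0, "fi_outside": 5000.0, "fi_dry": 1200.0,
            "fi_annual": 10200.0, "ge_annual": 10200.0 * 18.45,
        }
    )
    params = d.EmissionParams()
    f1 = compute_flows(profile, params)
    f2 = compute_flows(doubled, params)
    assert f2.ch4_enteric == pytest.approx(2 * f1.ch4_enteric)
    assert f2.ch4_manure == pytest.approx(2 * f1.ch4_manure)
    assert f2.n2o_direct == pytest.approx(2 * f1.n2o_direct)
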