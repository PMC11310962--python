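"""Paired comparison, Monte Carlo propagation and OAT sensitivity."""

import numpy as np
import pytest

import dairylca as d
from dairylca.compare import _diff_pct
from dairylca.errors import (
    InvalidInputError,
    UnknownParameterError,
    WindowMismatchError,
)
from dairylca.model import evaluate_system


def _published_pair(name):
    breakdowns = d.reference_cc_breakdowns()[name]
    return (
        d.ImpactResult.from_breakdowns({"CC": breakdowns["control"]}),
        d.ImpactResult.from_breakdowns({"CC": breakdowns["treatment"]}),
    )


class TestCompare:
    def test_uk_published_carbon_reduction(self):
        control, treatment = _published_pair("uk")
        report = d.compare(control, treatment)
        assert report.diff_pct("CC") == pytest.approx(-3.1, abs=0.1)

    def test_identical_systems_zero_everywhere(self, fixtures):
        control, _ = fixtures.pair("french")
        res = evaluate_system(control, fixtures.ef_table)
        report = d.compare(res.impacts, res.impacts)
        assert all(c.diff_pct == 0.0 for c in report.categories.values())

    def test_antisymmetry_up_to_denominator(self, fixtures):
        control, treatment = fixtures.pair("uk")
        res_c = evaluate_system(control, fixtures.ef_table)
        res_t = evaluate_system(treatment, fixtures.ef_table, control_trial=control.trial)
        fwd = d.compare(res_c.impacts, res_t.impacts)
        rev = d.compare(res_t.impacts, res_c.impacts)
        for cat in d.CATEGORIES:
            c, t = fwd.categories[cat].control, fwd.categories[cat].treatment
            if c != t:
                assert np.sign(fwd.categories[cat].diff_pct) == -np.sign(
                    rev.categories[cat].diff_pct
                )
                # same absolute gap, opposite denominators
                assert fwd.categories[cat].diff_pct * c == pytest.approx(
                    -rev.categories[cat].diff_pct * t, rel=1e-9
                )

    def test_category_mismatch_rejected(self):
        control, _ = _published_pair("uk")
        other = d.ImpactResult.from_breakdowns({"LU": {"feed_compounds": 1.0}})
        with pytest.raises(InvalidInputError):
            d.compare(control, other)

    def test_mean_of_three_control_totals(self):
        totals = d.reference_cc_totals()
        reports = []
        for name in ("french", "uk", "german"):
            c, t = totals[name]["control"], totals[name]["treatment"]
            reports.append(
                d.ComparisonReport(
                    label=name,
                    categories={
                        "CC": d.CategoryComparison(
                            control=c, treatment=t, diff_pct=_diff_pct(c, t)
                        )
                    },
                )
            )
        mean = d.aggregate(reports)
        assert mean.categories["CC"].control == pytest.approx(1.1527, abs=1e-4)
        assert round(mean.categories["CC"].control, 2) == 1.15
        assert round(mean.categories["CC"].treatment, 2) == 1.12


class TestWindowCompare:
    def test_null_pair_is_zero(self, fixtures):
        control, _ = fixtures.pair("french")
        twin = control.model_copy(
            update={
                "label": "twin",
                "trial": control.trial.model_copy(update={"group_label": "treatment"}),
            }
        )
        report = d.supplementation_window_compare(control, twin, fixtures.ef_table)
        assert all(c.diff_pct == 0.0 for c in report.categories.values())

    def test_mismatched_windows_rejected(self, fixtures):
        control, _ = fixtures.pair("french")
        _, other_treatment = fixtures.pair("uk")
        with pytest.raises(WindowMismatchError):
            d.supplementation_window_compare(control, other_treatment, fixtures.ef_table)

    def test_window_reduction_exceeds_annual(self, fixtures):
        """Equal outside-window performance dilutes the annual-scale benefit."""
        for name in fixtures.names:
            control, treatment = fixtures.pair(name)
            model = d.PairedTrialLCA(control, treatment, fixtures.ef_table)
            annual = model.fit().diff_pct("CC")
            window = model.fit(window_only=True).diff_pct("CC")
            assert abs(window) >= abs(annual)

    def test_mean_window_reduction_near_five_pct(self, fixtures):
        diffs = []
        for name in fixtures.names:
            control, treatment = fixtures.pair(name)
            model = d.PairedTrialLCA(control, treatment, fixtures.ef_table)
            diffs.append(model.fit(window_only=True).diff_pct("CC"))
        assert np.mean(diffs) == pytest.approx(-5.0, abs=1.0)


class TestMonteCarlo:
    def test_degenerate_distributions_collapse_to_point(self, fixtures):
        control, treatment = fixtures.pair("uk")  # gsd 1.0 and SE 0 throughout
        mc = d.monte_carlo(control, treatment, fixtures.ef_table, n_iter=5, seed=1)
        for cat in d.CATEGORIES:
            assert np.allclose(mc.diff_pct[cat], mc.point_estimate[cat])

    def test_seed_reproducibility(self, scenario):
        pairs, ef = scenario
        control, treatment = pairs[0]
        a = d.monte_carlo(control, treatment, ef, n_iter=20, seed=7)
        b = d.monte_carlo(control, treatment, ef, n_iter=20, seed=7)
        c = d.monte_carlo(control, treatment, ef, n_iter=20, seed=8)
        assert a.diff_pct.equals(b.diff_pct)
        assert not a.diff_pct.equals(c.diff_pct)

    def test_joint_ef_scaling_cancels_in_ef_driven_categories(self, fixtures):
        control, treatment = fixtures.pair("french")
        doubled = fixtures.ef_table.scaled(
            {key: 2.0 for key in fixtures.ef_table.keys()}
        )
        model_1 = d.PairedTrialLCA(control, treatment, fixtures.ef_table)
        model_2 = d.PairedTrialLCA(control, treatment, doubled)
        r1, r2 = model_1.fit(), model_2.fit()
        for cat in ("LU", "WU", "RU", "FEU"):  # categories fed only by EF rows
            assert r1.diff_pct(cat) == pytest.approx(r2.diff_pct(cat), abs=1e-9)

    def test_median_consistent_with_point_estimate(self, fixtures):
        control, treatment = fixtures.pair("uk")
        ef = fixtures.ef_table.with_uniform_gsd(1.2)
        mc = d.monte_carlo(control, treatment, ef, n_iter=300, seed=11)
        x = mc.diff_pct["CC"].to_numpy()
        se_median = 1.2533 * x.std(ddof=1) / np.sqrt(len(x))
        assert abs(np.median(x) - mc.point_estimate["CC"]) <= max(3 * se_median, 0.05)

    def test_invalid_iterations(self, fixtures):
        control, treatment = fixtures.pair("uk")
        with pytest.raises(InvalidInputError):
            d.monte_carlo(control, treatment, fixtures.ef_table, n_iter=0, seed=1)

    def test_percentiles_ordered(self, scenario):
        pairs, ef = scenario
        control, treatment = pairs[0]
        summary = d.monte_carlo(control, treatment, ef, n_iter=50, seed=3).summary()
        for s in summary.values():
            assert s.p2_5 <= s.median <= s.p97_5


class TestSensitivity:
    def test_zero_perturbation_zero_elasticities(self, fixtures):
        control, treatment = fixtures.pair("french")
        items = d.sensitivity_oat(
            control, treatment, fixtures.ef_table, ["ym", "dmi_control"], perturbation=0.0
        )
        assert all(i.elasticity_total == 0.0 for i in items)

    def test_ym_elasticity_equals_modelled_enteric_share(self, fixtures):
        """In a fully modelled trial the carbon total is linear in Ym, so its
        elasticity equals the enteric-methane contribution share."""
        control, treatment = fixtures.pair("french")
        res = evaluate_system(control, fixtures.ef_table)
        enteric_fraction = res.flows.ch4_enteric / res.flows.ch4_total
        expected = (
            res.impacts.per_kg["CC"]["onfarm_ch4"] / res.impacts.totals["CC"]
        ) * enteric_fraction
        (item,) = d.sensitivity_oat(control, treatment, fixtures.ef_table, ["ym"])
        assert item.elasticity_total == pytest.approx(expected, abs=1e-6)

    def test_linear_parameter_elasticity_stable_under_halving(self, fixtures):
        control, treatment = fixtures.pair("french")
        e1 = d.sensitivity_oat(control, treatment, fixtures.ef_table, ["ym"], 0.1)
        e2 = d.sensitivity_oat(control, treatment, fixtures.ef_table, ["ym"], 0.05)
        assert e1[0].elasticity_total == pytest.approx(e2[0].elasticity_total, abs=1e-9)

    def test_ranked_by_magnitude(self, fixtures):
        control, treatment = fixtures.pair("french")
        items = d.sensitivity_oat(
            control, treatment, fixtures.ef_table,
            ["ym", "dmi_control", "milk_yield_daily_control", "ef3"],
        )
        magnitudes = [abs(i.elasticity_total) for i in items]
        assert magnitudes == sorted(magnitudes, reverse=True)

    def test_unknown_parameter_rejected(self, fixtures):
        control, treatment = fixtures.pair("french")
        with pytest.raises(UnknownParameterError):
            d.sensitivity_oat(control, treatment, fixtures.ef_table, ["bogus"])
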