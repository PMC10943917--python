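"""Costing, QALY/MD accrual, discounting and incremental comparison."""
import copy

import numpy as np
import pytest

from migraine_cea import ArmResult, accrue, classify_band, compare, evaluate_params
from migraine_cea.outcomes import (acute_med_cost, cycle_direct_cost, cycle_qaly,
                                   discount_factor, resource_cost)
from migraine_cea.params import ModelSettings


class TestClassifyBand:
    @pytest.mark.parametrize("mmd, band", [
        (0, "no_migraine"), (0.9, "no_migraine"), (1, "low"), (3.9, "low"),
        (4, "intermediate"), (7.42, "intermediate"), (8, "high"), (14.5, "high"),
        (15, "chronic"), (28, "chronic"),
    ])
    def test_examples(self, mmd, band):
        assert classify_band(mmd) == band

    def test_exhaustive_and_exclusive_over_spectrum(self):
        for mmd in np.arange(0, 28.01, 0.5):
            assert classify_band(float(mmd)) in (
                "no_migraine", "low", "intermediate", "high", "chronic")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_band(28.3)


class TestDiscountFactor:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, ModelSettings()) == 1.0

    def test_closed_form(self):
        # 1.03^(-4*84/365.25)
        assert discount_factor(4, ModelSettings()) == pytest.approx(
            1.03 ** (-4 * 84 / 365.25))

    def test_zero_rate(self):
        s = ModelSettings(discount_rate_costs=0.0)
        assert all(discount_factor(k, s) == 1.0 for k in range(10))


class TestCycleCosts:
    def test_no_migraine_off_treatment_is_other_medication_only(self, em_params):
        got = cycle_direct_cost(0.0, em_params.costs, em_params.comparator,
                                on_treatment=False)
        assert got == pytest.approx(3.56)

    def test_chronic_band_hospitalisation_component(self, em_params):
        # 17% of patients x one stay x EUR 2,044.61 = EUR 347.58
        res = resource_cost("chronic", em_params.costs, hospital_dispensed=False)
        parts = {r.resource: r.unit_cost * r.units * r.fraction
                 for r in em_params.costs.band_resource_use["chronic"]}
        assert parts["hospitalisation"] == pytest.approx(347.5837)
        assert res == pytest.approx(sum(v for k, v in parts.items()
                                        if k != "pharmacy_visit"))

    def test_chronic_triptan_midpoint(self, em_params):
        # triptans (21.70+41.10)/2 = 31.40 plus other medication (13.50+22.20)/2
        assert acute_med_cost("chronic", em_params.costs) == pytest.approx(31.40 + 17.85)

    def test_pharmacy_visit_only_for_hospital_dispensed_arms(self, em_params):
        with_pharm = resource_cost("chronic", em_params.costs, hospital_dispensed=True)
        without = resource_cost("chronic", em_params.costs, hospital_dispensed=False)
        assert with_pharm - without == pytest.approx(5.89)

    def test_statutory_discount_applies_to_hospital_dispensed_drug(self, em_params):
        ere, topi = em_params.intervention, em_params.comparator
        on = cycle_direct_cost(0.0, em_params.costs, ere, on_treatment=True)
        off = cycle_direct_cost(0.0, em_params.costs, ere, on_treatment=False)
        assert on - off == pytest.approx(500.0 * 0.925)
        on_t = cycle_direct_cost(0.0, em_params.costs, topi, on_treatment=True)
        off_t = cycle_direct_cost(0.0, em_params.costs, topi, on_treatment=False)
        assert on_t - off_t == pytest.approx(30.0)  # retail price, no discount


class TestCycleQaly:
    def test_no_migraine_cycle(self, em_params):
        # 0.85 utility over an 84-day cycle
        got = cycle_qaly(0.0, em_params.utility, 0.0, em_params.settings)
        assert got == pytest.approx(0.85 * 84 / 365.25)  # 0.19548

    def test_ae_decrement_reduces_qalys(self, em_params):
        base = cycle_qaly(5.0, em_params.utility, 0.0, em_params.settings)
        hit = cycle_qaly(5.0, em_params.utility, 0.05, em_params.settings)
        assert base - hit == pytest.approx(0.05 * 84 / 365.25)

    def test_floored_at_zero(self, em_params):
        assert cycle_qaly(28.0, em_params.utility, 1.0, em_params.settings) == 0.0


class TestAccrue:
    def test_migraine_day_conversion(self, em_params):
        """One person-cycle at 10 MMD accrues 10 x 84/30.4375 = 27.60 MDs."""
        arm_results, _, traces = evaluate_params(em_params)
        trace = traces["erenumab"]
        md_expected = sum(
            (trace.on_treatment[k] * trace.mmd_on[k]
             + trace.discontinued[k] * trace.mmd_discontinued)
            * trace.weight[k] * 84 / 30.4375
            for k in range(1, trace.n_cycles + 1))
        assert arm_results["erenumab"].migraine_days == pytest.approx(md_expected)
        assert 84 / 30.4375 * 10 == pytest.approx(27.5975, abs=1e-4)

    def test_cost_additivity_by_category(self, em_params):
        results, _, _ = evaluate_params(em_params, perspective="societal")
        for r in results.values():
            for bd in (r.discounted, r.undiscounted):
                assert bd.total == pytest.approx(
                    bd.drug + bd.acute_med + bd.resource + bd.indirect, abs=1e-9)

    def test_discounted_below_undiscounted(self, em_params):
        results, _, _ = evaluate_params(em_params)
        for r in results.values():
            assert r.discounted.total < r.undiscounted.total
            assert r.qalys < r.qalys_undiscounted

    @pytest.mark.parametrize("rates", [(0.0, 0.03), (0.03, 0.05)])
    def test_totals_decrease_with_discount_rate(self, em_params, rates):
        lo, hi = rates
        low = copy.deepcopy(em_params)
        low.settings.discount_rate_costs = low.settings.discount_rate_effects = lo
        high = copy.deepcopy(em_params)
        high.settings.discount_rate_costs = high.settings.discount_rate_effects = hi
        r_lo, _, _ = evaluate_params(low)
        r_hi, _, _ = evaluate_params(high)
        for name in r_lo:
            assert r_hi[name].total_cost <= r_lo[name].total_cost
            assert r_hi[name].qalys <= r_lo[name].qalys

    def test_societal_equals_healthcare_plus_indirect(self, em_params):
        hc, _, _ = evaluate_params(em_params, perspective="healthcare")
        soc, _, _ = evaluate_params(em_params, perspective="societal")
        for name in hc:
            assert soc[name].discounted.indirect > 0
            assert soc[name].total_cost == pytest.approx(
                hc[name].total_cost + soc[name].discounted.indirect)
            assert soc[name].qalys == pytest.approx(hc[name].qalys)
            assert soc[name].migraine_days == pytest.approx(hc[name].migraine_days)

    def test_dead_accrue_nothing(self, cm_params):
        """Forcing everyone dead from cycle 1 zeroes every total."""
        from migraine_cea import LifeTable
        import pandas as pd
        ages = np.arange(30, 121)
        lethal = LifeTable(pd.concat([
            pd.DataFrame({"age": ages, "sex": s, "qx": 1.0}) for s in ("F", "M")
        ], ignore_index=True))
        p = copy.deepcopy(cm_params)
        p.life_table = lethal
        for arm in p.arms:  # skip trajectory calibration: no survivors to carry it
            arm.mmd_targets = []
        results, _, _ = evaluate_params(p)
        for r in results.values():
            assert r.total_cost == 0.0
            assert r.qalys == 0.0
            assert r.migraine_days == 0.0


class TestCompare:
    def test_printed_totals_reproduce_printed_icer(self):
        topi = ArmResult.from_totals("topiramate", 17059, 5.8839, 1049)
        ere = ArmResult.from_totals("erenumab", 21479, 6.1150, 877)
        ce = compare(ere, topi)
        assert ce.delta_cost == pytest.approx(4420)
        assert ce.delta_qaly == pytest.approx(0.2311)
        assert ce.md_avoided == pytest.approx(172)
        assert ce.icer_per_qaly == pytest.approx(4420 / 0.2311, rel=1e-9)
        # within 0.1% of the published EUR 19,122/QALY
        assert ce.icer_per_qaly == pytest.approx(19122, rel=1e-3)
        assert ce.cost_per_md_avoided == pytest.approx(25.70, abs=0.01)
        assert ce.dominance == "none"

    def test_dominant_intervention_flags_icer_undefined(self):
        comp = ArmResult.from_totals("c", 1000, 1.0, 100)
        dom = ArmResult.from_totals("i", 900, 1.2, 80)
        ce = compare(dom, comp)
        assert ce.dominance == "intervention_dominant"
        assert ce.icer_per_qaly is None

    def test_dominated_intervention(self):
        comp = ArmResult.from_totals("c", 1000, 1.2, 80)
        bad = ArmResult.from_totals("i", 1100, 1.0, 100)
        assert compare(bad, comp).dominance == "intervention_dominated"

    def test_zero_qaly_delta_leaves_icer_undefined(self):
        a = ArmResult.from_totals("i", 1100, 1.0, 90)
        b = ArmResult.from_totals("c", 1000, 1.0, 100)
        ce = compare(a, b)
        assert ce.icer_per_qaly is None
        assert ce.cost_per_md_avoided == pytest.approx(10.0)

    def test_mismatched_settings_rejected(self, em_params):
        results, _, _ = evaluate_params(em_params)
        other = copy.deepcopy(em_params)
        other.settings.discount_rate_costs = 0.05
        results2, _, _ = evaluate_params(other)
        with pytest.raises(ValueError, match="different settings"):
            compare(results["erenumab"], results2["topiramate"])
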