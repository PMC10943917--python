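"""Moment matching, PSA sampling, CEAC, tornado and scenarios."""
import copy

import numpy as np
import pytest

from migraine_cea import evaluate_params, moment_match, run_psa, run_scenario
from migraine_cea.sensitivity import (PSADistributionSpec, apply_scenario,
                                      build_default_psa_specs, ceac,
                                      derive_response_from_or,
                                      sample_moment_matched,
                                      sample_parameter_set, tornado)


class TestMomentMatch:
    def test_beta_symmetric_case(self):
        pars = moment_match("beta", 0.5, 0.1)
        assert pars["alpha"] == pytest.approx(12.0)
        assert pars["beta"] == pytest.approx(12.0)

    def test_gamma_identities(self):
        pars = moment_match("gamma", 2.0, 1.0)
        assert pars["shape"] == pytest.approx(4.0)
        assert pars["rate"] == pytest.approx(2.0)

    def test_lognormal_identities(self):
        pars = moment_match("lognormal", 2.76, 1.16)
        sigma2 = np.log(1 + 1.16**2 / 2.76**2)
        assert pars["sigma"] == pytest.approx(np.sqrt(sigma2))
        assert pars["mu"] == pytest.approx(np.log(2.76) - sigma2 / 2)
        # implied mean is preserved
        assert np.exp(pars["mu"] + sigma2 / 2) == pytest.approx(2.76)

    def test_zero_se_collapses_to_point_mass(self):
        pars = moment_match("lognormal", 2.27, 0.0)
        assert pars == {"family": "fixed", "value": 2.27}
        rng = np.random.default_rng(0)
        assert sample_moment_matched(pars, rng) == 2.27

    def test_beta_variance_bound_enforced(self):
        with pytest.raises(ValueError, match="beta variance"):
            moment_match("beta", 0.5, 0.6)

    @pytest.mark.parametrize("family", ["gamma", "lognormal"])
    def test_nonpositive_mean_rejected(self, family):
        with pytest.raises(ValueError):
            moment_match(family, -1.0, 0.5)


class TestOddsTransform:
    def test_published_inputs(self):
        # base p 0.18, OR 2.76 -> 0.3773
        assert derive_response_from_or(0.18, 2.76) == pytest.approx(0.3773, abs=1e-4)

    def test_unit_or_is_identity(self):
        assert derive_response_from_or(0.3, 1.0) == pytest.approx(0.3)


class TestSampleParameterSet:
    def _fixed_specs(self, params):
        specs = build_default_psa_specs(params)
        fixed = []
        for s in specs:
            if s.family == "multivariate_normal":
                s = PSADistributionSpec(s.parameter_name, "multivariate_normal",
                                        s.paths, mean_vec=s.mean_vec,
                                        cov=np.zeros((2, 2)))
            else:
                s = PSADistributionSpec(s.parameter_name, "fixed", s.paths,
                                        s.mean, 0.0)
            fixed.append(s)
        return fixed

    def test_all_fixed_specs_leave_probabilities_at_base(self, cm_params):
        """Degenerate draws reproduce the base set (modulo the OR-derived
        intervention response, which the published set rounds)."""
        rng = np.random.default_rng(1)
        draw = sample_parameter_set(cm_params, self._fixed_specs(cm_params), rng)
        assert draw.comparator.response_prob == cm_params.comparator.response_prob
        assert draw.utility.slope_per_mmd == cm_params.utility.slope_per_mmd
        # intervention response re-derived from fixed comparator p and OR
        assert draw.intervention.response_prob == pytest.approx(
            derive_response_from_or(0.17, 2.27))

    def test_sampled_probabilities_stay_in_unit_interval(self, em_params):
        specs = build_default_psa_specs(em_params)
        rng = np.random.default_rng(7)
        for _ in range(50):
            draw = sample_parameter_set(em_params, specs, rng)
            for arm in draw.arms:
                assert 0.0 <= arm.response_prob <= 1.0
                assert 0.0 <= arm.longterm_discontinuation_prob_per_cycle <= 1.0
            assert draw.utility.intercept_u0 - 28 * draw.utility.slope_per_mmd >= -1e-12

    def test_beta_sampler_mean_recovered(self):
        pars = moment_match("beta", 0.3026, 0.0177)
        rng = np.random.default_rng(11)
        draws = np.array([sample_moment_matched(pars, rng) for _ in range(10000)])
        assert draws.mean() == pytest.approx(0.3026, abs=3 * 0.0177 / np.sqrt(10000))


class TestCEAC:
    def test_hand_enumerated_curve(self):
        iters = np.array([[100.0, 0.01], [-50.0, 0.02]])
        probs = ceac(iters, np.array([0.0, 10000.0, 20000.0]))
        # wtp 0: only the cost-saving iteration; 10k: NMB1 = 0 (not > 0);
        # 20k: both positive
        assert probs == pytest.approx([0.5, 0.5, 1.0])

    def test_all_dominant_iterations_give_unit_curve(self):
        iters = np.tile([[-10.0, 0.1]], (20, 1))
        assert np.all(ceac(iters, np.array([0.0, 30000.0])) == 1.0)

    def test_large_wtp_limit_is_positive_qaly_fraction(self):
        rng = np.random.default_rng(3)
        iters = np.column_stack([rng.normal(0, 100, 500), rng.normal(0, 0.1, 500)])
        limit = ceac(iters, np.array([0.0, 1e12]))[-1]
        assert limit == pytest.approx((iters[:, 1] > 0).mean(), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.empty((0, 2)), np.array([0.0, 1.0]))


class TestRunPSA:
    def test_fixed_seed_reproducible(self, em_params):
        a = run_psa(em_params, n_iterations=20, seed=5)
        b = run_psa(em_params, n_iterations=20, seed=5)
        assert np.array_equal(a.iterations, b.iterations)
        assert np.array_equal(a.ceac_prob, b.ceac_prob)

    def test_degenerate_distributions_reproduce_deterministic_result(self, em_params):
        specs = TestSampleParameterSet()._fixed_specs(em_params)
        # align the base intervention response with its OR-derived value so the
        # deterministic run and the degenerate PSA share one parameter set
        base = copy.deepcopy(em_params)
        base.intervention.response_prob = derive_response_from_or(
            base.comparator.response_prob, base.comparator.response_or)
        _, ce, _ = evaluate_params(base)
        res = run_psa(base, specs=specs, n_iterations=10, seed=2)
        assert np.allclose(res.iterations[:, 0], ce.delta_cost)
        assert np.allclose(res.iterations[:, 1], ce.delta_qaly)

    def test_partitioned_uncertainty_leaves_qalys_constant(self, em_params):
        """Varying only a unit cost moves costs but never QALYs."""
        specs = TestSampleParameterSet()._fixed_specs(em_params)
        for s in specs:
            if s.parameter_name == "unit_cost.hospitalisation":
                s.family, s.se = "gamma", 0.2 * s.mean
        res = run_psa(em_params, specs=specs, n_iterations=15, seed=3)
        assert np.ptp(res.iterations[:, 1]) == 0.0
        assert np.ptp(res.iterations[:, 0]) > 0.0


class TestTornado:
    def test_zero_influence_parameter_has_zero_width(self, em_params):
        # monthly wage does not enter the healthcare perspective
        entries = tornado(em_params,
                          {"wage": ["costs.wage_monthly"],
                           "response": ["arms[0].response_prob"]})
        by_name = {e.parameter_name: e for e in entries}
        assert by_name["wage"].range_width == 0.0
        assert by_name["response"].range_width > 0.0
        assert entries[0].parameter_name == "response"  # sorted by swing

    def test_probability_capped_at_one_with_warning(self, em_params):
        p = copy.deepcopy(em_params)
        p.arms[0].response_prob = 0.9
        with pytest.warns(UserWarning, match="capped"):
            entries = tornado(p, {"resp": ["arms[0].response_prob"]})
        assert entries[0].high_value == 1.0

    def test_permutation_invariant_ordering(self, em_params):
        groups = {"a: response": ["arms[0].response_prob"],
                  "b: slope": ["utility.slope_per_mmd"],
                  "c: drug": ["arms[0].drug_cost_per_cycle"]}
        fwd = tornado(em_params, dict(groups))
        rev = tornado(em_params, dict(reversed(list(groups.items()))))
        assert [e.parameter_name for e in fwd] == [e.parameter_name for e in rev]

    def test_unknown_path_rejected(self, em_params):
        with pytest.raises(KeyError, match="unknown parameter path"):
            tornado(em_params, {"bad": ["arms[0].no_such_field"]})


class TestScenarios:
    def test_healthcare_base_equals_unmodified_run(self, em_params):
        _, base_ce, _ = evaluate_params(em_params)
        ce = run_scenario(em_params, "healthcare_base")
        assert ce.delta_cost == pytest.approx(base_ce.delta_cost)
        assert ce.delta_qaly == pytest.approx(base_ce.delta_qaly)

    def test_societal_differs_only_in_indirect_costs(self, em_params):
        _, hc, _ = evaluate_params(em_params)
        soc = run_scenario(em_params, "societal")
        assert soc.delta_qaly == pytest.approx(hc.delta_qaly)
        assert soc.md_avoided == pytest.approx(hc.md_avoided)
        assert soc.delta_cost != pytest.approx(hc.delta_cost)

    def test_overlay_never_mutates_base(self, em_params):
        before = em_params.settings.perspective
        apply_scenario(em_params, "societal")
        run_scenario(em_params, "wpai_workloss")
        assert em_params.settings.perspective == before
        _, ce1, _ = evaluate_params(em_params)
        ce2 = run_scenario(em_params, "healthcare_base")
        assert ce1.delta_cost == pytest.approx(ce2.delta_cost)

    def test_unknown_scenario_rejected(self, em_params):
        with pytest.raises(KeyError, match="unknown scenario"):
            run_scenario(em_params, "lunar")
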