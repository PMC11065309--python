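"""Deterministic decision engine: lifetime expectations, ICER, dominance."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceemod import engine
from ceemod.engine import (
    ArmResult,
    compare_arms,
    discounted_qale,
    evaluate_arm,
    evaluate_base_case,
    expected_lifetime_cost,
    expected_lifetime_qale,
    no_event_outcome,
)
from ceemod.params import (
    EVENT_CATEGORIES,
    ArmStateProbabilities,
    PrincipalEventDistribution,
)


class TestNoEventOutcome:
    def test_ward_mix_weighting(self, params):
        cost, qale = no_event_outcome(params.health_states, 0.56)
        assert cost == pytest.approx(0.44 * 28694 + 0.56 * 10555)  # 18,536.16
        assert qale == pytest.approx(0.44 * 7.4965 + 0.56 * 7.9866)  # 7.7710

    @pytest.mark.parametrize("mix,state", [(0.0, "ward_gastroenterology"),
                                           (1.0, "ward_respiratory")])
    def test_pure_mix_recovers_ward_values(self, params, mix, state):
        cost, qale = no_event_outcome(params.health_states, mix)
        assert cost == params.health_states[state].lifetime_cost
        assert qale == params.health_states[state].qale

    def test_missing_ward_state_errors(self, params):
        states = {k: v for k, v in params.health_states.items()
                  if k != "ward_respiratory"}
        with pytest.raises(ValueError, match="ward"):
            no_event_outcome(states, 0.5)


class TestLifetimeExpectations:
    def test_qale_matches_published_table(self, params):
        mix = params.resource_use.ward_mix_pulmonology
        qi = expected_lifetime_qale(params.state_probs["intervention"],
                                    params.principal_events["intervention"],
                                    params.health_states, mix)
        qc = expected_lifetime_qale(params.state_probs["control"],
                                    params.principal_events["control"],
                                    params.health_states, mix)
        assert qi == pytest.approx(7.3702, abs=1e-3)
        assert qc == pytest.approx(7.3415, abs=1e-3)

    def test_lifetime_cost_matches_published_table(self, params):
        mix = params.resource_use.ward_mix_pulmonology
        ci = expected_lifetime_cost(params.state_probs["intervention"],
                                    params.principal_events["intervention"],
                                    params.health_states, mix)
        cc = expected_lifetime_cost(params.state_probs["control"],
                                    params.principal_events["control"],
                                    params.health_states, mix)
        assert ci == pytest.approx(17644.52, rel=1e-3)
        assert cc == pytest.approx(17687.70, rel=1e-3)

    def test_pure_no_event_arm(self, params):
        probs = ArmStateProbabilities(1.0, 0.0, 0.0, (3787, 0, 0))
        mix = 0.56
        qale = expected_lifetime_qale(probs, params.principal_events["control"],
                                      params.health_states, mix)
        _, noe = no_event_outcome(params.health_states, mix)
        assert qale == pytest.approx(noe)

    def test_all_death_arm_has_zero_payoffs(self, params):
        probs = ArmStateProbabilities(0.0, 0.0, 1.0, (0, 0, 3787))
        ped = params.principal_events["control"]
        assert expected_lifetime_qale(probs, ped, params.health_states, 0.56) == 0.0
        assert expected_lifetime_cost(probs, ped, params.health_states, 0.56) == 0.0

    def test_carry_forward_prices_embolism_at_no_event_cost(self, params):
        """A survivor cohort discharged entirely with pulmonary embolism costs
        the same as the no-event profile."""
        probs = ArmStateProbabilities(0.0, 1.0, 0.0, (0, 3787, 0))
        ped = PrincipalEventDistribution(
            probabilities={c: 1.0 if c == "pulmonary_embolism" else 0.0
                           for c in EVENT_CATEGORIES},
            concentrations={c: 0.0 for c in EVENT_CATEGORIES})
        cost = expected_lifetime_cost(probs, ped, params.health_states, 0.56)
        noe_cost, _ = no_event_outcome(params.health_states, 0.56)
        assert cost == pytest.approx(noe_cost)

    def test_unnormalized_distribution_rejected(self, params):
        probs = ArmStateProbabilities(0.5, 0.2, 0.2, (1, 1, 1))  # sums to 0.9
        with pytest.raises(ValueError):
            expected_lifetime_qale(probs, params.principal_events["control"],
                                   params.health_states, 0.56)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_convex_combination_bounds(self, params, u, v, mix):
        """Expected QALE/cost stay inside the range spanned by the state
        payoffs (death included at zero)."""
        p_death = u * 0.3
        p_surv = (1 - u * 0.3) * v
        probs = ArmStateProbabilities(1 - p_death - p_surv, p_surv, p_death, (1, 1, 1))
        ped = params.principal_events["control"]
        q = expected_lifetime_qale(probs, ped, params.health_states, mix)
        c = expected_lifetime_cost(probs, ped, params.health_states, mix)
        qales = [0.0] + [hs.qale for hs in params.health_states.values()]
        costs = [0.0] + [hs.lifetime_cost for hs in params.health_states.values()
                         if hs.lifetime_cost is not None]
        assert min(qales) - 1e-9 <= q <= max(qales) + 1e-9
        assert min(costs) - 1e-9 <= c <= max(costs) + 1e-9

    def test_qale_decreasing_in_inpatient_mortality(self, params):
        ped = params.principal_events["control"]
        base = params.state_probs["control"]
        results = []
        for p_death in (0.02, 0.05, 0.10):
            scale = (1 - p_death) / (base.p_no_event + base.p_event_survive)
            probs = ArmStateProbabilities(base.p_no_event * scale,
                                          base.p_event_survive * scale,
                                          p_death, base.dirichlet_counts)
            results.append(expected_lifetime_qale(probs, ped,
                                                  params.health_states, 0.56))
        assert results[0] > results[1] > results[2]


class TestArmEvaluation:
    def test_totals_match_published_table(self, params):
        i = evaluate_arm(params, "intervention")
        c = evaluate_arm(params, "control")
        assert i.total_cost == pytest.approx(19691.52, rel=1e-3)
        assert c.total_cost == pytest.approx(19746.86, rel=1e-3)
        # additivity to the penny of our own components
        assert i.total_cost == pytest.approx(i.hospital_cost + i.lifetime_cost, abs=1e-9)

    def test_expected_events_come_from_adjusted_rates(self, params):
        assert evaluate_arm(params, "intervention").expected_events == 0.0666
        assert evaluate_arm(params, "control").expected_events == 0.0933

    def test_unknown_arm_rejected(self, params):
        with pytest.raises(ValueError):
            evaluate_arm(params, "sham")

    def test_zero_lifetime_cost_config(self, params):
        zeroed = {name: replace(hs, lifetime_cost=0.0, cost_distribution=None,
                                cost_carry_forward=False)
                  for name, hs in params.health_states.items()}
        p = replace(params, health_states=zeroed)
        arm = evaluate_arm(p, "intervention")
        assert arm.lifetime_cost == 0.0
        assert arm.total_cost == arm.hospital_cost


class TestIncrementalComparison:
    def test_lifetime_comparison_is_dominant(self, params):
        res = evaluate_base_case(params)
        inc = res["lifetime"]
        assert inc.dominance == "dominant"
        assert inc.quadrant == "SE"
        assert inc.delta_cost == pytest.approx(-55.35, rel=0.05)
        assert inc.delta_effect == pytest.approx(0.0287, abs=5e-4)
        assert inc.icer is None

    def test_short_term_comparison(self, params):
        inc = evaluate_base_case(params)["short_term"]
        assert inc.delta_cost == pytest.approx(-12.17, abs=1e-9)
        assert inc.delta_effect == pytest.approx(0.0267, abs=1e-9)  # events avoided

    def test_identical_arms(self):
        a = ArmResult("intervention", 100.0, 50.0, 0.1, 5.0)
        b = ArmResult("control", 100.0, 50.0, 0.1, 5.0)
        inc = compare_arms(a, b)
        assert inc.delta_cost == 0.0
        assert inc.delta_effect == 0.0
        assert inc.nmb == 0.0
        assert inc.icer is None

    @pytest.mark.parametrize("dc,dq,verdict,quadrant", [
        (-10.0, 0.1, "dominant", "SE"),
        (10.0, -0.1, "dominated", "NW"),
        (10.0, 0.1, "icer", "NE"),
        (-10.0, -0.1, "icer", "SW"),
    ])
    def test_dominance_classification(self, dc, dq, verdict, quadrant):
        a = ArmResult("intervention", 100.0 + dc, 0.0, 0.1, 5.0 + dq)
        b = ArmResult("control", 100.0, 0.0, 0.1, 5.0)
        inc = compare_arms(a, b)
        assert inc.dominance == verdict
        assert inc.quadrant == quadrant
        if verdict == "icer":
            assert inc.icer == pytest.approx(dc / dq)

    def test_nmb_sign_matches_dominance_in_se_quadrant(self, params):
        inc = evaluate_base_case(params)["lifetime"]
        assert inc.quadrant == "SE"
        assert inc.nmb > 0
        assert inc.nhb == pytest.approx(inc.nmb / 20_000.0)


class TestDiscountedQale:
    def test_zero_rate_equals_undiscounted_years(self):
        assert discounted_qale(1.0, 10.0, 0.0) == 10.0

    def test_half_utility_over_model_life_expectancy(self):
        assert discounted_qale(0.5, 17.74, 0.035) == pytest.approx(6.52, abs=0.01)

    def test_healthy_reference_implies_utility_near_three_quarters(self, params):
        """Inverting the healthy-population QALE gives an annual utility of
        ~0.749 over 17.74 years at 3.5%."""
        u = 0.749
        got = discounted_qale(u, params.life_expectancy, params.discount_rate)
        assert got == pytest.approx(params.healthy_qale, rel=2e-3)

    def test_out_of_range_utility_rejected(self):
        with pytest.raises(ValueError):
            discounted_qale(1.5, 10, 0.035)


def test_life_years_saved_extrapolation(params):
    got = engine.life_years_saved(params)
    assert got == pytest.approx((0.0499 - 0.0485) * 17.74)
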