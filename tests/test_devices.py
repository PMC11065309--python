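"""Device costing: annualization, throughput, and threshold analysis."""

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceemod.devices import (
    annual_patients,
    annuity_factor,
    device_cost_per_patient,
    threshold_device_cost,
)
from ceemod.params import ArmInterval, EpisodeCosts


class TestAnnualPatients:
    @pytest.mark.parametrize("beds,los,expected", [
        (54, 8.62, 2286.54),   # reported as 2,287 patients/year
        (54, 8.90, 2214.61),
        (1, 365, 1.0),
    ])
    def test_throughput(self, beds, los, expected):
        assert annual_patients(beds, los) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("beds,los", [(0, 8.62), (54, 0), (-1, 5)])
    def test_non_positive_inputs_rejected(self, beds, los):
        with pytest.raises(ValueError):
            annual_patients(beds, los)

    def test_occupancy_scales_linearly(self):
        full = annual_patients(54, 8.62, 1.0)
        assert annual_patients(54, 8.62, 0.85) == pytest.approx(0.85 * full)


class TestAnnuity:
    def test_five_years_at_nice_rate(self):
        assert annuity_factor(5, 0.035) == pytest.approx(4.515, abs=5e-4)

    @pytest.mark.parametrize("n", [1, 5, 17.74])
    def test_zero_rate_limit_is_n(self, n):
        assert annuity_factor(n, 0.0) == n

    def test_life_expectancy_annuity(self):
        assert annuity_factor(17.74, 0.035) == pytest.approx(13.05, abs=0.01)


class TestDeviceCost:
    def test_intervention_straight_line_matches_published(self, params):
        res = device_cost_per_patient(params.device_prices, params.resource_use,
                                      "intervention")
        assert res.per_patient == pytest.approx(19.98, rel=0.005)
        assert res.per_bed_year == pytest.approx(846.14, rel=0.005)
        assert res.annual_total == pytest.approx(45691.66, rel=0.005)

    def test_control_straight_line_matches_published(self, params):
        res = device_cost_per_patient(params.device_prices, params.resource_use,
                                      "control")
        assert res.annual_total == pytest.approx(3360.00, abs=0.01)
        assert res.per_bed_year == pytest.approx(62.22, abs=0.01)
        assert res.per_patient == pytest.approx(1.52, rel=0.005)

    def test_equivalent_annual_cost_matches_published(self, params):
        i = device_cost_per_patient(params.device_prices, params.resource_use,
                                    "intervention", method="equivalent_annual_cost",
                                    discount_rate=0.035)
        c = device_cost_per_patient(params.device_prices, params.resource_use,
                                    "control", method="equivalent_annual_cost",
                                    discount_rate=0.035)
        assert i.per_patient == pytest.approx(20.71, rel=0.005)
        assert c.per_patient == pytest.approx(1.68, rel=0.005)

    def test_internal_consistency(self, params):
        res = device_cost_per_patient(params.device_prices, params.resource_use,
                                      "intervention")
        assert res.per_patient * res.annual_patients == pytest.approx(
            res.annual_total, rel=1e-6)
        assert res.per_bed_year * params.resource_use.beds == pytest.approx(
            res.annual_total, rel=1e-6)

    def test_unknown_arm_and_method_rejected(self, params):
        with pytest.raises(ValueError, match="arm"):
            device_cost_per_patient(params.device_prices, params.resource_use, "placebo")
        with pytest.raises(ValueError, match="method"):
            device_cost_per_patient(params.device_prices, params.resource_use,
                                    "control", method="magic")

    def test_control_has_no_variable_cost(self, params):
        ru0 = replace(params.resource_use, cableless_rate=0.0)
        ru1 = replace(params.resource_use, cableless_rate=1.0)
        c0 = device_cost_per_patient(params.device_prices, ru0, "control")
        c1 = device_cost_per_patient(params.device_prices, ru1, "control")
        assert c0.annual_total == c1.annual_total

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rate=st.floats(0.0, 1.0), delta=st.floats(0.01, 0.5))
    def test_per_patient_affine_in_cableless_rate(self, params, rate, delta):
        """Slope of per-patient cost in the sensor rate equals the unit price."""
        delta = min(delta, 1.0 - rate)
        if delta <= 0:
            return
        ru_a = replace(params.resource_use, cableless_rate=rate)
        ru_b = replace(params.resource_use, cableless_rate=rate + delta)
        a = device_cost_per_patient(params.device_prices, ru_a, "intervention")
        b = device_cost_per_patient(params.device_prices, ru_b, "intervention")
        slope = (b.per_patient - a.per_patient) / delta
        assert slope == pytest.approx(params.device_prices.sensor_unit, rel=1e-9)

    def test_methods_coincide_at_zero_discount(self, params):
        sl = device_cost_per_patient(params.device_prices, params.resource_use,
                                     "intervention", method="straight_line")
        eac = device_cost_per_patient(params.device_prices, params.resource_use,
                                      "intervention", method="equivalent_annual_cost",
                                      discount_rate=0.0)
        assert sl.per_patient == pytest.approx(eac.per_patient, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(beds=st.integers(10, 200), extra=st.integers(1, 50))
    def test_fixed_cost_dilution_in_beds(self, params, beds, extra):
        """More beds spread the fixed cost: per-patient cost strictly falls."""
        ru_small = replace(params.resource_use, beds=beds)
        ru_big = replace(params.resource_use, beds=beds + extra)
        small = device_cost_per_patient(params.device_prices, ru_small, "intervention")
        big = device_cost_per_patient(params.device_prices, ru_big, "intervention")
        assert big.per_patient < small.per_patient

    def test_per_patient_increases_with_length_of_stay(self, params):
        def pp(los):
            ru = replace(params.resource_use,
                         mean_los={"intervention": los, "control": los})
            return device_cost_per_patient(params.device_prices, ru,
                                           "intervention").per_patient
        assert pp(8.62) < pp(10.0) < pp(14.0)


class TestThreshold:
    def test_threshold_matches_published(self, params):
        t = threshold_device_cost(params)
        assert not t.intervention_already_more_costly
        assert t.threshold_per_patient == pytest.approx(32.06, rel=0.02)

    def test_zero_saving_threshold_equals_base_cost(self, params):
        iv = params.episode_costs.by_arm["control"]
        even = replace(params, episode_costs=EpisodeCosts(by_arm={
            "intervention": iv, "control": iv}))
        t = threshold_device_cost(even)
        assert t.threshold_per_patient == pytest.approx(t.base_per_patient)

    def test_threshold_additive_in_saving(self, params):
        """Doubling the hospital saving raises the threshold by the same amount."""
        i = params.episode_costs.by_arm["intervention"]
        doubled = replace(params, episode_costs=EpisodeCosts(by_arm={
            "intervention": replace(i, mean=i.mean - 12.17, low=i.low - 12.17,
                                    high=i.high - 12.17),
            "control": params.episode_costs.by_arm["control"]}))
        t = threshold_device_cost(doubled)
        assert t.threshold_per_patient == pytest.approx(19.98 + 24.34, rel=0.01)

    def test_more_costly_baseline_flagged(self, params):
        i = params.episode_costs.by_arm["intervention"]
        costly = replace(params, episode_costs=EpisodeCosts(by_arm={
            "intervention": replace(i, mean=i.mean + 100, low=i.low + 100,
                                    high=i.high + 100),
            "control": params.episode_costs.by_arm["control"]}))
        t = threshold_device_cost(costly)
        assert t.intervention_already_more_costly
        assert t.threshold_per_patient < t.base_per_patient
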