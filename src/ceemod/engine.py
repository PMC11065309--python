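"""Deterministic decision engine: one-shot decision tree with lifetime payoffs.

Each arm's cohort discharges into one of three branches — no event, a
non-fatal principal serious adverse event, or inpatient death — with the
principal-event branch subdividing over seven event categories.  Each
discharge health state carries a published lifetime cost and a discounted
quality-adjusted life expectancy (QALE); death contributes zero for both.
The "no event" state is a ward-mix weighted average of the gastroenterology
and respiratory ward chronic-condition profiles.  Where an event state's
lifetime cost is below the no-event cost (pulmonary embolism in the base
case), the no-event cost is carried forward.

Expected totals per arm combine the adjusted inpatient episode cost
(short-term, device cost included, undiscounted) with the expected lifetime
cost; incremental comparisons report the ICER or a dominance verdict,
together with net monetary and net health benefit at a willingness-to-pay
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .devices import annuity_factor
from .params import (
    ARMS,
    EVENT_CATEGORIES,
    ArmStateProbabilities,
    HealthStateOutcome,
    ParameterSet,
    PrincipalEventDistribution,
)

_PROB_TOL = 1e-9
QUADRANTS = ("NE", "NW", "SE", "SW")


@dataclass(frozen=True)
class ArmResult:
    arm: str
    hospital_cost: float      # inpatient episode, GBP (short-term)
    lifetime_cost: float      # expected post-discharge cost, GBP (discounted)
    expected_events: float    # mean serious adverse events per patient
    qale: float               # expected discounted QALYs at discharge

    @property
    def total_cost(self) -> float:
        return self.hospital_cost + self.lifetime_cost


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_effect: float
    effect_units: str            # "qaly" or "event"
    wtp: float                   # willingness-to-pay threshold (lambda)
    icer: float | None           # GBP per unit gained; None when undefined
    dominance: str               # "dominant", "dominated", or "icer"
    quadrant: str | None         # NE / NW / SE / SW on the CE plane

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_effect - self.delta_cost

    @property
    def nhb(self) -> float:
        return self.nmb / self.wtp if self.wtp > 0 else math.nan


def no_event_outcome(
    states: Mapping[str, HealthStateOutcome], ward_mix_pulmonology: float
) -> tuple[float, float]:
    """Lifetime (cost, QALE) of the "no event" state: convex combination of
    the respiratory-ward (weight = pulmonology mix) and gastroenterology-ward
    profiles."""
    if not (0.0 <= ward_mix_pulmonology <= 1.0):
        raise ValueError("ward mix must be in [0, 1]")
    try:
        g = states["ward_gastroenterology"]
        r = states["ward_respiratory"]
    except KeyError as e:
        raise ValueError(f"missing ward no-event state: {e}") from None
    w = ward_mix_pulmonology
    cost = (1.0 - w) * g.lifetime_cost + w * r.lifetime_cost
    qale = (1.0 - w) * g.qale + w * r.qale
    return cost, qale


def _check_distributions(probs: ArmStateProbabilities, events: PrincipalEventDistribution) -> None:
    if abs(sum(probs.as_tuple()) - 1.0) > 1e-6:
        raise ValueError("discharge-state probabilities do not sum to 1")
    if abs(sum(events.prob_vector()) - 1.0) > 1e-6:
        raise ValueError("principal-event distribution is not normalized")


def expected_lifetime_qale(
    probs: ArmStateProbabilities,
    events: PrincipalEventDistribution,
    states: Mapping[str, HealthStateOutcome],
    ward_mix_pulmonology: float,
) -> float:
    """p(no event) x QALE_no-event + p(survive) x E[QALE | event] + p(death) x 0."""
    _check_distributions(probs, events)
    _, noe_qale = no_event_outcome(states, ward_mix_pulmonology)
    event_qale = sum(
        events.probabilities[c] * states[c].qale for c in EVENT_CATEGORIES
    )
    return probs.p_no_event * noe_qale + probs.p_event_survive * event_qale


def expected_lifetime_cost(
    probs: ArmStateProbabilities,
    events: PrincipalEventDistribution,
    states: Mapping[str, HealthStateOutcome],
    ward_mix_pulmonology: float,
) -> float:
    """Same expectation as the QALE, with death costing zero and carry-forward
    states priced at the no-event weighted cost."""
    _check_distributions(probs, events)
    noe_cost, _ = no_event_outcome(states, ward_mix_pulmonology)

    def state_cost(name: str) -> float:
        hs = states[name]
        if hs.cost_carry_forward or hs.lifetime_cost is None:
            return noe_cost
        return hs.lifetime_cost

    event_cost = sum(events.probabilities[c] * state_cost(c) for c in EVENT_CATEGORIES)
    return probs.p_no_event * noe_cost + probs.p_event_survive * event_cost


def evaluate_arm(params: ParameterSet, arm: str) -> ArmResult:
    """Expected per-patient costs, events and QALE for one arm of the model."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    probs = params.state_probs[arm]
    events = params.principal_events[arm]
    mix = params.resource_use.ward_mix_pulmonology
    return ArmResult(
        arm=arm,
        hospital_cost=params.episode_costs.by_arm[arm].mean,
        lifetime_cost=expected_lifetime_cost(probs, events, params.health_states, mix),
        expected_events=params.event_rates.by_arm[arm].mean,
        qale=expected_lifetime_qale(probs, events, params.health_states, mix),
    )


def _classify(delta_cost: float, delta_effect: float) -> tuple[str, str | None, float | None]:
    """Dominance verdict, CE-plane quadrant, and ICER (if defined)."""
    if delta_effect == 0.0:
        return "icer", None, None
    if delta_effect > 0:
        quadrant = "NE" if delta_cost > 0 else "SE"
    else:
        quadrant = "NW" if delta_cost > 0 else "SW"
    if delta_cost <= 0 and delta_effect > 0:
        return "dominant", quadrant, None
    if delta_cost > 0 and delta_effect < 0:
        return "dominated", quadrant, None
    return "icer", quadrant, delta_cost / delta_effect


def compare_arms(
    a: ArmResult,
    b: ArmResult,
    wtp: float = 20_000.0,
    effect: str = "qaly",
) -> IncrementalResult:
    """Incremental comparison of arm ``a`` (new strategy) vs ``b`` (comparator).

    ``effect="qaly"`` compares lifetime totals per QALY; ``effect="event"``
    compares short-term hospital costs per event avoided (the effect is the
    reduction in events, so fewer events counts as a gain).
    """
    if effect == "qaly":
        delta_cost = a.total_cost - b.total_cost
        delta_effect = a.qale - b.qale
    elif effect == "event":
        delta_cost = a.hospital_cost - b.hospital_cost
        delta_effect = b.expected_events - a.expected_events  # events avoided
    else:
        raise ValueError(f"unknown effect measure {effect!r}")
    dominance, quadrant, icer = _classify(delta_cost, delta_effect)
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        effect_units=effect,
        wtp=wtp,
        icer=icer,
        dominance=dominance,
        quadrant=quadrant,
    )


def evaluate_base_case(params: ParameterSet, wtp: float = 20_000.0) -> dict:
    """Full deterministic base case: both arms, lifetime and short-term
    incremental comparisons."""
    arms = {arm: evaluate_arm(params, arm) for arm in ARMS}
    return {
        "arms": arms,
        "lifetime": compare_arms(arms["intervention"], arms["control"], wtp, "qaly"),
        "short_term": compare_arms(arms["intervention"], arms["control"], wtp, "event"),
    }


def discounted_qale(annual_utility: float, life_expectancy: float, rate: float) -> float:
    """Discounted QALE of a constant annual utility over a life expectancy:
    utility x annuity_factor(life expectancy, rate)."""
    if not (0.0 <= annual_utility <= 1.2):
        raise ValueError("annual utility outside the plausible [0, 1.2] range")
    if life_expectancy <= 0:
        raise ValueError("life expectancy must be positive")
    return annual_utility * annuity_factor(life_expectancy, rate)


def life_years_saved(params: ParameterSet) -> float:
    """Extrapolated life-years gained per patient from averted inpatient
    deaths: (p_death_control - p_death_intervention) x life expectancy.

    A labelled extrapolation convention for the cost-per-life-year-saved
    view of the short-term analysis.
    """
    dp = (params.state_probs["control"].p_inpatient_death
          - params.state_probs["intervention"].p_inpatient_death)
    return dp * params.life_expectancy
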