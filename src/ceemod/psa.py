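"""Probabilistic sensitivity analysis: Monte-Carlo propagation of parameter
uncertainty through the decision model.

Each replication draws one realization of every uncertain input:

* discharge-state probabilities — Dirichlet with the effective multinomial
  counts (optionally a compound Dirichlet-multinomial resample);
* principal-event distributions — Dirichlet with the fitted concentrations,
  falling back to point estimates when the concentrations are numerically
  degenerate (total < 1e-6);
* lifetime state costs — Gamma with mean at the point estimate and
  coefficient of variation ``sd_fraction`` (0.2 in the base case);
* state QALEs — Normal with sd = ``sd_fraction`` x mean, truncated at zero
  by resampling;
* inpatient episode costs and event rates — Gamma moment-matched to the
  adjusted mean and its bootstrap 95% central range (sd = width / 3.92).

Health-state draws are shared between arms (the arms discharge into the same
health states); arm-specific inputs are drawn independently.  Device inputs
are fixed.  Summaries include the cost-effectiveness plane quadrant
proportions and the cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import engine
from .params import (
    ARMS,
    EVENT_CATEGORIES,
    ArmInterval,
    ArmStateProbabilities,
    EpisodeCosts,
    EventRates,
    ParameterSet,
    PrincipalEventDistribution,
)

_DEGENERATE_CONC_TOTAL = 1e-6


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 10_000
    seed: int = 0
    sd_fraction: float = 0.2
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 50_001, 1000))
    dirichlet_multinomial: bool = False  # compound-multinomial resampling
    max_failure_fraction: float = 0.01

    def validate(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.sd_fraction <= 0:
            raise ValueError("sd_fraction must be > 0")
        if list(self.wtp_grid) != sorted(self.wtp_grid):
            raise ValueError("wtp_grid must be sorted ascending")


@dataclass
class PSAResult:
    config: PSAConfig
    delta_cost: np.ndarray       # lifetime total cost difference per draw
    delta_qaly: np.ndarray
    delta_hospital_cost: np.ndarray
    delta_events: np.ndarray     # events avoided (positive = fewer events)
    n_failed: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    def means(self) -> dict[str, float]:
        return {
            "delta_cost": float(self.delta_cost.mean()),
            "delta_qaly": float(self.delta_qaly.mean()),
            "delta_hospital_cost": float(self.delta_hospital_cost.mean()),
            "delta_events_avoided": float(self.delta_events.mean()),
        }

    def central_range(self, what: str = "delta_cost") -> tuple[float, float]:
        x = getattr(self, what)
        lo, hi = np.percentile(x, [2.5, 97.5])
        return float(lo), float(hi)

    def quadrant_proportions(self) -> dict[str, float]:
        dc, dq = self.delta_cost, self.delta_qaly
        return {
            "NE": float(np.mean((dq > 0) & (dc > 0))),
            "SE": float(np.mean((dq > 0) & (dc <= 0))),
            "SW": float(np.mean((dq <= 0) & (dc <= 0))),
            "NW": float(np.mean((dq <= 0) & (dc > 0))),
        }

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> "np.ndarray":
        return ceac(self, wtp_grid)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at 0 by resampling (means here are several sd
    above zero, so rejection is cheap)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("truncated-normal rejection failed repeatedly")


def _gamma_from_mean_cv(rng: np.random.Generator, mean: float, cv: float) -> float:
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2 / 1.0))


def _gamma_from_mean_sd(rng: np.random.Generator, mean: float, sd: float) -> float:
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, mean / shape))


def _interval_sd(iv: ArmInterval) -> float:
    return (iv.high - iv.low) / 3.92


def _draw_state_probs(rng: np.random.Generator, sp: ArmStateProbabilities,
                      compound: bool) -> ArmStateProbabilities:
    counts = np.asarray(sp.dirichlet_counts, dtype=float)
    p = rng.dirichlet(counts)
    if compound:
        n = counts.sum()
        if n >= 1:
            p = rng.multinomial(int(round(n)), p) / round(n)
    return ArmStateProbabilities(
        p_no_event=float(p[0]), p_event_survive=float(p[1]),
        p_inpatient_death=float(p[2]), dirichlet_counts=sp.dirichlet_counts,
    )


def _draw_principal(rng: np.random.Generator,
                    ped: PrincipalEventDistribution) -> PrincipalEventDistribution:
    conc = np.asarray(ped.concentration_vector(), dtype=float)
    if conc.sum() < _DEGENERATE_CONC_TOTAL:
        return ped
    p = rng.dirichlet(np.maximum(conc, 1e-300))
    if not np.isfinite(p).all():  # pathological underflow: keep point estimates
        return ped
    probs = dict(zip(EVENT_CATEGORIES, (float(x) for x in p)))
    return PrincipalEventDistribution(probabilities=probs,
                                      concentrations=ped.concentrations)


def sample_parameter_draw(params: ParameterSet, cfg: PSAConfig,
                          rng: np.random.Generator) -> ParameterSet:
    """One Monte-Carlo realization of all uncertain parameters.

    Health-state cost/QALE draws are made once and shared by both arms.
    """
    f = cfg.sd_fraction
    states = {}
    for name, hs in params.health_states.items():
        cost = hs.lifetime_cost
        if cost is not None and not hs.cost_carry_forward:
            cost = _gamma_from_mean_cv(rng, cost, f)
        qale = _truncated_normal(rng, hs.qale, f * hs.qale)
        states[name] = replace(hs, lifetime_cost=cost, qale=qale)

    state_probs = {a: _draw_state_probs(rng, params.state_probs[a], cfg.dirichlet_multinomial)
                   for a in ARMS}
    principal = {a: _draw_principal(rng, params.principal_events[a]) for a in ARMS}

    episode = EpisodeCosts(by_arm={
        a: replace(iv, mean=_gamma_from_mean_sd(rng, iv.mean, _interval_sd(iv)))
        for a, iv in params.episode_costs.by_arm.items()
    })
    rates = EventRates(by_arm={
        a: replace(iv, mean=_gamma_from_mean_sd(rng, iv.mean, _interval_sd(iv)))
        for a, iv in params.event_rates.by_arm.items()
    })
    return replace(params, health_states=states, state_probs=state_probs,
                   principal_events=principal, episode_costs=episode,
                   event_rates=rates)


def run_psa(params: ParameterSet, cfg: PSAConfig) -> PSAResult:
    """Evaluate the deterministic engine on each parameter draw.

    Reproducible by seed.  A draw on which the engine fails is recorded and
    skipped; more than ``max_failure_fraction`` failures aborts the run.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dc = np.empty(cfg.n_draws)
    dq = np.empty(cfg.n_draws)
    dhc = np.empty(cfg.n_draws)
    dev = np.empty(cfg.n_draws)
    failed = 0
    kept = 0
    for _ in range(cfg.n_draws):
        draw = sample_parameter_draw(params, cfg, rng)
        try:
            arms = {a: engine.evaluate_arm(draw, a) for a in ARMS}
        except Exception:
            failed += 1
            if failed > cfg.max_failure_fraction * cfg.n_draws:
                raise RuntimeError(
                    f"{failed} engine failures out of {kept + failed} draws "
                    f"exceeds the {cfg.max_failure_fraction:.0%} cap")
            continue
        i, c = arms["intervention"], arms["control"]
        dc[kept] = i.total_cost - c.total_cost
        dq[kept] = i.qale - c.qale
        dhc[kept] = i.hospital_cost - c.hospital_cost
        dev[kept] = c.expected_events - i.expected_events
        kept += 1
    return PSAResult(config=cfg, delta_cost=dc[:kept], delta_qaly=dq[:kept],
                     delta_hospital_cost=dhc[:kept], delta_events=dev[:kept],
                     n_failed=failed)


def ceac(result: PSAResult, wtp_grid: Sequence[float] | None = None) -> np.ndarray:
    """P(cost-effective) per willingness-to-pay: fraction of draws with
    positive net monetary benefit, wtp x dQ - dC > 0."""
    if result.n_draws == 0:
        raise ValueError("PSA result contains no draws")
    grid = np.asarray(result.config.wtp_grid if wtp_grid is None else wtp_grid, dtype=float)
    nmb = grid[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    return (nmb > 0).mean(axis=1)


def ceac_at(result: PSAResult, wtp: float) -> float:
    return float(ceac(result, [wtp])[0])
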