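"""Model-input types, validation, and plain-text (YAML) configuration I/O.

The decision model compares an automated vital-signs monitoring and
notification system ("intervention") against routine spot-check monitoring
("control") on two general hospital wards.  All model inputs — discharge-state
probabilities, principal-event distributions, lifetime costs and
quality-adjusted life expectancies (QALEs) per discharge health state,
resource use, device prices, per-arm inpatient episode costs and adjusted
event rates — live in a single :class:`ParameterSet`, loadable from one
human-readable YAML file.  A base-case fixture for the study population is
bundled with the package (``vital2_basecase.yaml``).

Monetary values are stored at full precision (GBP, 2020/21 prices); rounding
happens only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

ARMS = ("intervention", "control")

#: Canonical ordering of the seven non-fatal principal serious adverse events.
EVENT_CATEGORIES = (
    "acute_myocardial_infarction",
    "pulmonary_embolism",
    "acute_pulmonary_oedema",
    "respiratory_failure",
    "severe_sepsis",
    "icu_admission",
    "cardiopulmonary_arrest",
)

#: The two "no event" component states (ward of admission).
WARD_STATES = ("ward_gastroenterology", "ward_respiratory")

_PROB_TOL = 1e-9
_GAMMA_MEAN_RTOL = 0.005  # Gamma(shape, scale) mean must match the stated cost within 0.5%


class SchemaError(ValueError):
    """A configuration file is missing a required field or section."""


class ValidationError(ValueError):
    """A ParameterSet violates one or more invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid parameters:\n  - " + "\n  - ".join(self.violations))


@dataclass(frozen=True)
class GammaSpec:
    """Gamma(shape, scale) distribution spec; mean = shape * scale."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def cv(self) -> float:
        return 1.0 / math.sqrt(self.shape)


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float


@dataclass(frozen=True)
class ArmStateProbabilities:
    """Discharge-state probabilities for one arm.

    States: no event / non-fatal principal event survived to discharge /
    inpatient death.  ``dirichlet_counts`` are the effective multinomial
    counts (events of N=3787) backing the Dirichlet draw in the PSA.
    """

    p_no_event: float
    p_event_survive: float
    p_inpatient_death: float
    dirichlet_counts: tuple[float, float, float]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_no_event, self.p_event_survive, self.p_inpatient_death)


@dataclass(frozen=True)
class PrincipalEventDistribution:
    """Distribution over the seven non-fatal principal events among survivors.

    ``concentrations`` are the Dirichlet parameters used in the PSA; they may
    be far below 1 (the adjusted multinomial-logit fit can be near-degenerate).
    """

    probabilities: Mapping[str, float]
    concentrations: Mapping[str, float]

    def prob_vector(self) -> list[float]:
        return [self.probabilities[c] for c in EVENT_CATEGORIES]

    def concentration_vector(self) -> list[float]:
        return [self.concentrations[c] for c in EVENT_CATEGORIES]


@dataclass(frozen=True)
class HealthStateOutcome:
    """Lifetime (post-discharge) cost and QALE attached to a discharge state.

    ``cost_carry_forward`` marks states whose own lifetime cost is *lower*
    than the no-event cost; for these the no-event weighted cost is carried
    forward (in the base case this is pulmonary embolism only, which has no
    published lifetime cost of its own).
    """

    name: str
    lifetime_cost: float | None
    qale: float
    cost_distribution: GammaSpec | None = None
    qale_distribution: NormalSpec | None = None
    cost_carry_forward: bool = False


@dataclass(frozen=True)
class ResourceUseInputs:
    beds: int
    mean_los: Mapping[str, float]  # days, per arm
    cableless_rate: float
    product_life: float  # years
    ward_mix_pulmonology: float
    occupancy: float = 1.0


@dataclass(frozen=True)
class DevicePrices:
    fixed_intervention: float  # IGS + 12 MP5SC spot-check monitors
    sensor_unit: float         # wireless sensor, per unit
    fixed_control: float       # 12 routine-care spot-check monitors


@dataclass(frozen=True)
class ArmInterval:
    mean: float
    low: float
    high: float


@dataclass(frozen=True)
class EpisodeCosts:
    """Adjusted mean inpatient episode cost per arm with 95% central range."""

    by_arm: Mapping[str, ArmInterval]


@dataclass(frozen=True)
class EventRates:
    """Adjusted mean serious-adverse-event count per patient, per arm."""

    by_arm: Mapping[str, ArmInterval]


@dataclass(frozen=True)
class ParameterSet:
    state_probs: Mapping[str, ArmStateProbabilities]
    principal_events: Mapping[str, PrincipalEventDistribution]
    health_states: Mapping[str, HealthStateOutcome]
    resource_use: ResourceUseInputs
    device_prices: DevicePrices
    episode_costs: EpisodeCosts
    event_rates: EventRates
    discount_rate: float = 0.035
    healthy_qale: float = 9.7732
    life_expectancy: float = 17.74
    unit_costs: Mapping[str, Mapping[str, float]] | None = None

    def with_resource_use(self, **kwargs) -> "ParameterSet":
        """Return a copy with fields of ``resource_use`` replaced."""
        return replace(self, resource_use=replace(self.resource_use, **kwargs))


# ---------------------------------------------------------------------------
# Validation

def _check_prob(v: float, what: str, out: list[str]) -> None:
    if not (0.0 <= v <= 1.0):
        out.append(f"{what} = {v!r} outside [0, 1]")


def validate_parameters(p: ParameterSet) -> list[str]:
    """Return a list of invariant violations; empty iff the set is valid.

    Never raises — callers that want a hard failure use
    :func:`ensure_valid`.
    """
    out: list[str] = []
    for arm in ARMS:
        if arm not in p.state_probs:
            out.append(f"state_probs missing arm {arm!r}")
            continue
        sp = p.state_probs[arm]
        for name, v in zip(("p_no_event", "p_event_survive", "p_inpatient_death"), sp.as_tuple()):
            _check_prob(v, f"{arm}.{name}", out)
        if abs(sum(sp.as_tuple()) - 1.0) > _PROB_TOL:
            out.append(f"{arm} discharge-state probabilities sum to {sum(sp.as_tuple())!r}, not 1")
        if any(c < 0 for c in sp.dirichlet_counts):
            out.append(f"{arm} dirichlet counts contain a negative value")
    for arm in ARMS:
        if arm not in p.principal_events:
            out.append(f"principal_events missing arm {arm!r}")
            continue
        ped = p.principal_events[arm]
        missing = [c for c in EVENT_CATEGORIES if c not in ped.probabilities]
        if missing:
            out.append(f"{arm} principal-event distribution missing categories {missing}")
            continue
        tot = sum(ped.prob_vector())
        if abs(tot - 1.0) > _PROB_TOL:
            out.append(f"{arm} principal-event probabilities sum to {tot!r}, not 1")
        if any(v < 0 for v in ped.prob_vector()):
            out.append(f"{arm} principal-event distribution has a negative probability")
        if any(ped.concentrations.get(c, 0.0) < 0 for c in EVENT_CATEGORIES):
            out.append(f"{arm} principal-event concentrations contain a negative value")
    for ws in WARD_STATES:
        if ws not in p.health_states:
            out.append(f"health state {ws!r} (no-event component) missing")
    for name, hs in p.health_states.items():
        if hs.qale < 0:
            out.append(f"health state {name}: qale {hs.qale!r} < 0")
        if hs.lifetime_cost is not None and hs.lifetime_cost < 0:
            out.append(f"health state {name}: lifetime_cost {hs.lifetime_cost!r} < 0")
        if hs.lifetime_cost is None and not hs.cost_carry_forward:
            out.append(f"health state {name}: no lifetime cost and no carry-forward flag")
        if hs.cost_distribution is not None and hs.lifetime_cost is not None:
            g = hs.cost_distribution
            if hs.lifetime_cost > 0 and abs(g.mean - hs.lifetime_cost) > _GAMMA_MEAN_RTOL * hs.lifetime_cost:
                out.append(
                    f"health state {name}: Gamma mean {g.mean:.2f} differs from "
                    f"lifetime cost {hs.lifetime_cost:.2f} by more than 0.5%"
                )
    ru = p.resource_use
    if ru.beds <= 0:
        out.append(f"beds = {ru.beds!r} must be > 0")
    for arm in ARMS:
        if ru.mean_los.get(arm, 0.0) <= 0:
            out.append(f"mean_los[{arm}] must be > 0")
    for name, v in (("cableless_rate", ru.cableless_rate),
                    ("ward_mix_pulmonology", ru.ward_mix_pulmonology),
                    ("occupancy", ru.occupancy)):
        _check_prob(v, name, out)
    if ru.product_life <= 0:
        out.append("product_life must be > 0")
    dp = p.device_prices
    if min(dp.fixed_intervention, dp.sensor_unit, dp.fixed_control) < 0:
        out.append("device prices must be non-negative")
    for label, grp in (("episode_costs", p.episode_costs), ("event_rates", p.event_rates)):
        for arm in ARMS:
            iv = grp.by_arm.get(arm)
            if iv is None:
                out.append(f"{label} missing arm {arm!r}")
                continue
            if not (iv.low <= iv.mean <= iv.high):
                out.append(f"{label}[{arm}]: range ({iv.low}, {iv.high}) does not bracket mean {iv.mean}")
            if label == "episode_costs" and iv.low <= 0:
                out.append(f"{label}[{arm}]: values must be > 0")
            if label == "event_rates" and iv.mean < 0:
                out.append(f"{label}[{arm}]: mean must be >= 0")
    if not (0.0 <= p.discount_rate < 1.0):
        out.append(f"discount_rate = {p.discount_rate!r} outside [0, 1)")
    return out


def ensure_valid(p: ParameterSet) -> ParameterSet:
    violations = validate_parameters(p)
    if violations:
        raise ValidationError(violations)
    return p


# ---------------------------------------------------------------------------
# YAML I/O

_REQUIRED_SECTIONS = (
    "probabilities", "principal_events", "lifetime", "resource_use",
    "device_prices", "episode_costs", "event_rates", "discounting",
)


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing field {key!r} in section {where!r}")
    return mapping[key]


def _parse_interval(d: Mapping, where: str) -> ArmInterval:
    mean = float(_require(d, "mean", where))
    low, high = (float(x) for x in _require(d, "range", where))
    return ArmInterval(mean=mean, low=low, high=high)


def parameters_from_dict(doc: Mapping) -> ParameterSet:
    for sec in _REQUIRED_SECTIONS:
        if sec not in doc:
            raise SchemaError(f"missing section {sec!r}")

    state_probs = {}
    for arm in ARMS:
        d = _require(doc["probabilities"], arm, "probabilities")
        state_probs[arm] = ArmStateProbabilities(
            p_no_event=float(_require(d, "no_event", f"probabilities.{arm}")),
            p_event_survive=float(_require(d, "event_survive", f"probabilities.{arm}")),
            p_inpatient_death=float(_require(d, "inpatient_death", f"probabilities.{arm}")),
            dirichlet_counts=tuple(float(x) for x in _require(d, "dirichlet_counts", f"probabilities.{arm}")),
        )

    principal = {}
    for arm in ARMS:
        d = _require(doc["principal_events"], arm, "principal_events")
        probs = {k: float(v) for k, v in _require(d, "probabilities", f"principal_events.{arm}").items()}
        conc = {k: float(v) for k, v in _require(d, "concentrations", f"principal_events.{arm}").items()}
        principal[arm] = PrincipalEventDistribution(probabilities=probs, concentrations=conc)

    lt = doc["lifetime"]
    states = {}
    for name, d in _require(lt, "states", "lifetime").items():
        cost = d.get("lifetime_cost")
        gamma = d.get("cost_gamma")
        normal = d.get("qale_normal")
        states[name] = HealthStateOutcome(
            name=name,
            lifetime_cost=None if cost is None else float(cost),
            qale=float(_require(d, "qale", f"lifetime.states.{name}")),
            cost_distribution=None if gamma is None else GammaSpec(float(gamma[0]), float(gamma[1])),
            qale_distribution=None if normal is None else NormalSpec(float(normal[0]), float(normal[1])),
            cost_carry_forward=bool(d.get("carry_forward", False)),
        )

    ru = doc["resource_use"]
    resource_use = ResourceUseInputs(
        beds=int(_require(ru, "beds", "resource_use")),
        mean_los={arm: float(_require(ru["mean_los"], arm, "resource_use.mean_los")) for arm in ARMS},
        cableless_rate=float(_require(ru, "cableless_rate", "resource_use")),
        product_life=float(_require(ru, "product_life", "resource_use")),
        ward_mix_pulmonology=float(_require(ru, "ward_mix_pulmonology", "resource_use")),
        occupancy=float(ru.get("occupancy", 1.0)),
    )

    dp = doc["device_prices"]
    device_prices = DevicePrices(
        fixed_intervention=float(_require(dp, "fixed_intervention", "device_prices")),
        sensor_unit=float(_require(dp, "sensor_unit", "device_prices")),
        fixed_control=float(_require(dp, "fixed_control", "device_prices")),
    )

    episode = EpisodeCosts(by_arm={arm: _parse_interval(_require(doc["episode_costs"], arm, "episode_costs"),
                                                        f"episode_costs.{arm}") for arm in ARMS})
    rates = EventRates(by_arm={arm: _parse_interval(_require(doc["event_rates"], arm, "event_rates"),
                                                    f"event_rates.{arm}") for arm in ARMS})

    disc = doc["discounting"]
    return ensure_valid(ParameterSet(
        state_probs=state_probs,
        principal_events=principal,
        health_states=states,
        resource_use=resource_use,
        device_prices=device_prices,
        episode_costs=episode,
        event_rates=rates,
        discount_rate=float(_require(disc, "rate", "discounting")),
        healthy_qale=float(lt.get("healthy_qale", 9.7732)),
        life_expectancy=float(lt.get("life_expectancy_years", 17.74)),
        unit_costs=doc.get("unit_costs"),
    ))


def parameters_to_dict(p: ParameterSet) -> dict:
    doc: dict = {
        "probabilities": {
            arm: {
                "no_event": sp.p_no_event,
                "event_survive": sp.p_event_survive,
                "inpatient_death": sp.p_inpatient_death,
                "dirichlet_counts": list(sp.dirichlet_counts),
            }
            for arm, sp in p.state_probs.items()
        },
        "principal_events": {
            arm: {
                "probabilities": dict(ped.probabilities),
                "concentrations": dict(ped.concentrations),
            }
            for arm, ped in p.principal_events.items()
        },
        "lifetime": {
            "healthy_qale": p.healthy_qale,
            "life_expectancy_years": p.life_expectancy,
            "states": {},
        },
        "resource_use": {
            "beds": p.resource_use.beds,
            "mean_los": dict(p.resource_use.mean_los),
            "cableless_rate": p.resource_use.cableless_rate,
            "product_life": p.resource_use.product_life,
            "ward_mix_pulmonology": p.resource_use.ward_mix_pulmonology,
            "occupancy": p.resource_use.occupancy,
        },
        "device_prices": asdict(p.device_prices),
        "episode_costs": {arm: {"mean": iv.mean, "range": [iv.low, iv.high]}
                          for arm, iv in p.episode_costs.by_arm.items()},
        "event_rates": {arm: {"mean": iv.mean, "range": [iv.low, iv.high]}
                        for arm, iv in p.event_rates.by_arm.items()},
        "discounting": {"rate": p.discount_rate},
    }
    for name, hs in p.health_states.items():
        d: dict = {"qale": hs.qale}
        if hs.lifetime_cost is not None:
            d["lifetime_cost"] = hs.lifetime_cost
        if hs.cost_distribution is not None:
            d["cost_gamma"] = [hs.cost_distribution.shape, hs.cost_distribution.scale]
        if hs.qale_distribution is not None:
            d["qale_normal"] = [hs.qale_distribution.mean, hs.qale_distribution.sd]
        if hs.cost_carry_forward:
            d["carry_forward"] = True
        doc["lifetime"]["states"][name] = d
    if p.unit_costs is not None:
        doc["unit_costs"] = {k: dict(v) for k, v in p.unit_costs.items()}
    return doc


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML config.

    With ``path=None`` the bundled base-case fixture (the study population's
    Tables of inputs) is loaded.
    """
    if path is None:
        text = resources.files("ceemod.data").joinpath("vital2_basecase.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise SchemaError("config file does not contain a mapping at top level")
    return parameters_from_dict(doc)


def write_parameters(p: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(parameters_to_dict(p), sort_keys=False))


def load_default_parameters() -> ParameterSet:
    return load_parameters(None)
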