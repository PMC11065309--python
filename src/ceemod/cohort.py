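"""Synthetic patient-level cohorts with the structure the estimation stage assumes.

The generator emulates the ward population the model inputs were estimated
from: ~3787 adult emergency admissions to a gastroenterology and a
pulmonology ward (median age 71, IQR 59-81; 52% female; 56% pulmonology;
NEWS on admission mean 3.15, sd 2.82), with overdispersed serious-adverse-
event counts that differ by arm, multinomial discharge states, gamma length
of stay, and gamma inpatient episode costs.

Event counts follow a gamma-Poisson (negative-binomial) model with a
log-linear covariate structure (arm, age, sex, ward, NEWS).  Per-arm
intercepts are normalized so the marginal mean event count hits the
configured per-arm target exactly in expectation, and the per-arm NB
dispersion is solved so that the probability of a zero count matches the
configured no-event discharge probability.  Discharge state is then derived
from the count (zero -> no event; positive -> inpatient death vs survival by
the configured conditional), which keeps counts and discharge states
mutually consistent by construction.

Episode costs follow a gamma model with log-linear covariate and event
effects, normalized per arm to the configured adjusted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ARMS, EVENT_CATEGORIES, ParameterSet

COHORT_COLUMNS = (
    "patient_id", "arm", "age", "sex", "ward", "news_admission",
    "event_count", "principal_event", "died_inpatient",
    "los_ward", "icu_days", "episode_cost",
)

#: Severity ordering used when a single discharge state must summarize
#: multiple events: ascending QALE (worst health state first).
SEVERITY_ORDER = (
    "cardiopulmonary_arrest", "severe_sepsis", "acute_pulmonary_oedema",
    "respiratory_failure", "icu_admission", "acute_myocardial_infarction",
    "pulmonary_embolism",
)


def _default_coeffs(kind: str) -> dict[str, float]:
    # Modest, plausible log-scale covariate effects; the per-arm intercept is
    # normalized away, so only the shape of the risk gradient matters.
    if kind == "events":
        return {"age": 0.012, "female": 0.10, "pulmonology": 0.08, "news": 0.16}
    return {"age": 0.004, "female": 0.02, "pulmonology": 0.05, "news": 0.04}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the study conditions: cohort of 3787, covariate
    marginals as observed, per-arm adjusted event means 0.0666/0.0933,
    discharge-state probabilities and principal-event distributions from the
    base-case inputs, and per-arm adjusted episode-cost means
    2046.99/2059.16 GBP.
    """

    n_intervention: int = 1894
    n_control: int = 1893
    seed: int = 0

    # covariates
    age_beta: tuple[float, float] = (3.8744, 2.2497)   # median 71, IQR 59-81
    age_range: tuple[float, float] = (17.0, 100.0)
    p_female: float = 0.52
    p_pulmonology: float = 0.56
    news_mean: float = 3.15
    news_sd: float = 2.82
    news_max: int = 20

    # event-count model
    event_mean: Mapping[str, float] = field(
        default_factory=lambda: {"intervention": 0.0666, "control": 0.0933})
    event_coeffs: Mapping[str, float] = field(default_factory=lambda: _default_coeffs("events"))
    #: NB dispersion per arm; "auto" solves it to match the discharge
    #: no-event probability, a float fixes it for both arms.
    dispersion: float | str = "auto"

    # discharge-state model (defaults set from the base-case inputs)
    state_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"intervention": (0.9451, 0.0064, 0.0485),
                                 "control": (0.9395, 0.0106, 0.0499)})
    principal_probs: Mapping[str, tuple[float, ...]] | None = None

    # cost model
    cost_mean: Mapping[str, float] = field(
        default_factory=lambda: {"intervention": 2046.99, "control": 2059.16})
    cost_coeffs: Mapping[str, float] = field(default_factory=lambda: _default_coeffs("cost"))
    cost_event_effect: float = 0.5   # log-scale bump for patients with any event
    cost_shape: float = 2.0          # gamma shape (CV = 1/sqrt(shape))

    # length of stay
    los_mean: Mapping[str, float] = field(
        default_factory=lambda: {"intervention": 8.62, "control": 8.90})
    los_shape: float = 1.3
    icu_los_mean: float = 3.5        # mean ICU days for ICU-admission events

    @classmethod
    def from_parameters(cls, params: ParameterSet, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Build a generator whose targets are a ParameterSet's inputs."""
        kwargs = dict(
            seed=seed,
            event_mean={a: params.event_rates.by_arm[a].mean for a in ARMS},
            state_probs={a: params.state_probs[a].as_tuple() for a in ARMS},
            principal_probs={a: tuple(params.principal_events[a].prob_vector()) for a in ARMS},
            cost_mean={a: params.episode_costs.by_arm[a].mean for a in ARMS},
            los_mean=dict(params.resource_use.mean_los),
            p_pulmonology=params.resource_use.ward_mix_pulmonology,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def validate(self) -> None:
        if self.n_intervention < 1 or self.n_control < 1:
            raise ValueError("cohort size per arm must be >= 1")
        for name in ("p_female", "p_pulmonology"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v!r} outside [0, 1]")
        if isinstance(self.dispersion, float) and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for arm in ARMS:
            if self.event_mean[arm] < 0:
                raise ValueError("event means must be >= 0")
            p = self.state_probs[arm]
            if abs(sum(p) - 1.0) > 1e-6 or min(p) < 0:
                raise ValueError(f"state probabilities for {arm} are not a distribution")
            if self.cost_mean[arm] <= 0 or self.los_mean[arm] <= 0:
                raise ValueError("cost and LOS means must be > 0")


_DEFAULT_PRINCIPAL = {
    "intervention": (0.0, 0.00006559, 0.00004368, 0.0, 0.00000001, 0.99989071, 0.00000001),
    "control": (0.00000007, 0.00012726, 0.00002508, 0.00000012, 0.19179070, 0.74615961, 0.06189716),
}


def _solve_dispersion(mu: np.ndarray, p_zero_target: float) -> float:
    """NB2 dispersion alpha such that mean_i (1 + a mu_i)^(-1/a) = target.

    Overdispersion only adds zeros relative to the Poisson floor
    mean_i exp(-mu_i); if the target is below that floor there is no root and
    the Poisson limit (alpha -> 0) is returned.
    """
    def zero_prob(alpha: float) -> float:
        return float(np.mean((1.0 + alpha * mu) ** (-1.0 / alpha)))

    poisson_floor = float(np.mean(np.exp(-mu)))
    if p_zero_target <= poisson_floor:
        return 1e-8
    lo, hi = 1e-6, 1e4
    if zero_prob(hi) < p_zero_target:
        return hi
    return float(optimize.brentq(lambda a: zero_prob(a) - p_zero_target, lo, hi, xtol=1e-10))


def _linear_predictor(coeffs: Mapping[str, float], age, female, pulmo, news,
                      centers=(71.0, 0.0, 0.0, 3.15)) -> np.ndarray:
    return (coeffs.get("age", 0.0) * (age - centers[0])
            + coeffs.get("female", 0.0) * (female - centers[1])
            + coeffs.get("pulmonology", 0.0) * (pulmo - centers[2])
            + coeffs.get("news", 0.0) * (news - centers[3]))


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw one synthetic cohort; byte-identical for identical (cfg, seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_intervention + cfg.n_control
    arm = np.array(["intervention"] * cfg.n_intervention + ["control"] * cfg.n_control)

    a, b = cfg.age_beta
    lo, hi = cfg.age_range
    age = lo + (hi - lo) * rng.beta(a, b, n)
    female = (rng.random(n) < cfg.p_female).astype(int)
    pulmo = (rng.random(n) < cfg.p_pulmonology).astype(int)

    # NEWS: discretized negative binomial matched to mean/sd, clipped to [0, max]
    var = cfg.news_sd ** 2
    if var > cfg.news_mean:
        r = cfg.news_mean ** 2 / (var - cfg.news_mean)
        news = rng.negative_binomial(r, r / (r + cfg.news_mean), n)
    else:
        news = rng.poisson(cfg.news_mean, n)
    news = np.minimum(news, cfg.news_max)

    principal_probs = cfg.principal_probs or _DEFAULT_PRINCIPAL

    event_count = np.zeros(n, dtype=int)
    died = np.zeros(n, dtype=bool)
    principal = np.array(["none"] * n, dtype=object)
    episode_cost = np.zeros(n)
    los = np.zeros(n)
    icu_days = np.zeros(n)

    eta_events = _linear_predictor(cfg.event_coeffs, age, female, pulmo, news)
    eta_cost = _linear_predictor(cfg.cost_coeffs, age, female, pulmo, news)

    for arm_name in ARMS:
        sel = arm == arm_name
        m = int(sel.sum())
        target_mean = float(cfg.event_mean[arm_name])
        p_noe, p_surv, p_death = cfg.state_probs[arm_name]

        if target_mean > 0:
            rel = np.exp(eta_events[sel])
            mu = target_mean * rel / rel.mean()
            if cfg.dispersion == "auto":
                alpha = _solve_dispersion(mu, p_noe)
            else:
                alpha = float(cfg.dispersion)
            lam = rng.gamma(1.0 / alpha, alpha * mu)  # gamma-Poisson mixture = NB
            counts = rng.poisson(lam)
        else:
            counts = np.zeros(m, dtype=int)
        event_count[sel] = counts

        pos = counts > 0
        denom = p_surv + p_death
        p_death_given_event = p_death / denom if denom > 0 else 0.0
        d = np.zeros(m, dtype=bool)
        d[pos] = rng.random(int(pos.sum())) < p_death_given_event
        died[sel] = d

        surv_event = pos & ~d
        k = int(surv_event.sum())
        if k:
            pe = np.asarray(principal_probs[arm_name], dtype=float)
            pe = pe / pe.sum()
            idx = rng.choice(len(EVENT_CATEGORIES), size=k, p=pe)
            block = principal[sel]
            block[surv_event] = [EVENT_CATEGORIES[i] for i in idx]
            principal[sel] = block

        # ward length of stay (gamma, per-arm mean)
        los_mu = cfg.los_mean[arm_name]
        los[sel] = rng.gamma(cfg.los_shape, los_mu / cfg.los_shape, m)

        # episode cost (gamma with log-link structure, normalized to target)
        rel_c = np.exp(eta_cost[sel] + cfg.cost_event_effect * pos)
        mu_c = cfg.cost_mean[arm_name] * rel_c / rel_c.mean()
        episode_cost[sel] = rng.gamma(cfg.cost_shape, mu_c / cfg.cost_shape, m)

    icu_sel = principal == "icu_admission"
    if icu_sel.any():
        icu_days[icu_sel] = rng.gamma(1.5, cfg.icu_los_mean / 1.5, int(icu_sel.sum()))

    # costs must stay strictly positive (gamma can underflow for tiny draws)
    episode_cost = np.maximum(episode_cost, 0.01)

    return pd.DataFrame({
        "patient_id": np.arange(n),
        "arm": arm,
        "age": age,
        "sex": np.where(female == 1, "female", "male"),
        "ward": np.where(pulmo == 1, "pulmonology", "gastroenterology"),
        "news_admission": news.astype(int),
        "event_count": event_count,
        "principal_event": principal.astype(str),
        "died_inpatient": died,
        "los_ward": los,
        "icu_days": icu_days,
        "episode_cost": episode_cost,
    })


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Headline marginal summaries of a cohort table."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    c = cohort
    by_arm = {}
    for arm_name, g in c.groupby("arm"):
        by_arm[arm_name] = {
            "n": int(len(g)),
            "mean_event_count": float(g.event_count.mean()),
            "var_event_count": float(g.event_count.var(ddof=0)),
            "p_no_event": float((g.event_count == 0).mean()),
            "p_event_survive": float(((g.event_count > 0) & ~g.died_inpatient).mean()),
            "p_inpatient_death": float(g.died_inpatient.mean()),
            "mean_los": float(g.los_ward.mean()),
            "mean_episode_cost": float(g.episode_cost.mean()),
        }
    return {
        "n": int(len(c)),
        "age_median": float(c.age.median()),
        "age_iqr": (float(c.age.quantile(0.25)), float(c.age.quantile(0.75))),
        "prop_female": float((c.sex == "female").mean()),
        "prop_pulmonology": float((c.ward == "pulmonology").mean()),
        "news_mean": float(c.news_admission.mean()),
        "news_sd": float(c.news_admission.std(ddof=0)),
        "arms": by_arm,
    }


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df
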