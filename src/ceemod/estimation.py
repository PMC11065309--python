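"""Recover model inputs from patient-level data.

Mirrors the adjusted analyses behind the base-case inputs: serious-adverse-
event counts by negative-binomial regression (NB2, log link), inpatient
episode costs by gamma GLM with log link, discharge states by multinomial
logit — all adjusting for arm, age, sex, ward and NEWS on admission — with
per-arm adjusted means obtained by recycled-prediction standardization
(predict every patient under each arm counterfactually and average).
Uncertainty is summarized by non-parametric bootstrap 95% central ranges
(percentile method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import (
    ARMS,
    EVENT_CATEGORIES,
    ArmStateProbabilities,
    PrincipalEventDistribution,
)

_COVARIATES = ("arm", "age", "female", "pulmonology", "news")


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitResult:
    """A fitted regression with recycled-prediction per-arm means."""

    model: str
    coefficients: pd.Series | pd.DataFrame
    adjusted_means: Mapping[str, float]
    dispersion: float | None = None


@dataclass(frozen=True)
class DischargeFit:
    state_probs: Mapping[str, ArmStateProbabilities]
    principal_events: Mapping[str, PrincipalEventDistribution]
    coefficients: pd.DataFrame | None


@dataclass(frozen=True)
class EstimationResult:
    events: FitResult
    costs: FitResult
    discharge: DischargeFit
    event_range: Mapping[str, tuple[float, float]] | None = None
    cost_range: Mapping[str, tuple[float, float]] | None = None


def _design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix (constant + arm/age/female/pulmonology/news),
    dropping zero-variance covariates with a warning."""
    X = pd.DataFrame({
        "const": 1.0,
        "arm": (cohort["arm"] == "intervention").astype(float),
        "age": cohort["age"].astype(float),
        "female": (cohort["sex"] == "female").astype(float),
        "pulmonology": (cohort["ward"] == "pulmonology").astype(float),
        "news": cohort["news_admission"].astype(float),
    }, index=cohort.index)
    for col in list(X.columns):
        if col in ("const", "arm"):
            continue
        if X[col].nunique() <= 1:
            warnings.warn(f"covariate {col!r} has zero variance; dropped", stacklevel=3)
            X = X.drop(columns=col)
    return X


def _recycled_means(predict: Callable[[pd.DataFrame], np.ndarray], X: pd.DataFrame) -> dict[str, float]:
    out = {}
    for arm_name, value in (("intervention", 1.0), ("control", 0.0)):
        Xa = X.copy()
        Xa["arm"] = value
        out[arm_name] = float(np.asarray(predict(Xa)).mean())
    return out


def fit_event_count_model(cohort: pd.DataFrame) -> FitResult:
    """NB2 negative-binomial regression of event counts with log link;
    per-arm predicted means by recycled predictions."""
    y = cohort["event_count"].astype(float)
    if (y == 0).all():
        raise EstimationError(
            "all event counts are zero: event rate 0, NB dispersion undefined")
    X = _design(cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X)
        res = model.fit(disp=0, maxiter=500)
    if not res.mle_retvals.get("converged", True):
        raise EstimationError(
            f"negative-binomial fit did not converge: {res.mle_retvals}")
    means = _recycled_means(lambda Xa: res.predict(Xa), X)
    return FitResult(
        model="negative_binomial",
        coefficients=res.params,
        adjusted_means=means,
        dispersion=float(res.params.get("alpha", np.nan)),
    )


def fit_cost_model(cohort: pd.DataFrame) -> FitResult:
    """Gamma-family, log-link GLM of episode costs; recycled per-arm means."""
    y = cohort["episode_cost"].astype(float)
    if (y <= 0).any():
        raise EstimationError("episode costs must be strictly positive")
    if float(y.max() - y.min()) == 0.0:
        # Degenerate constant-cost data: the adjusted mean is that constant.
        const = float(y.iloc[0])
        return FitResult(
            model="gamma_glm",
            coefficients=pd.Series({"const": np.log(const)}),
            adjusted_means={a: const for a in ARMS},
            dispersion=0.0,
        )
    X = _design(cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
    if not np.all(np.isfinite(res.params.to_numpy())):
        raise EstimationError("gamma GLM produced non-finite coefficients")
    means = _recycled_means(lambda Xa: res.predict(Xa), X)
    return FitResult(
        model="gamma_glm",
        coefficients=res.params,
        adjusted_means=means,
        dispersion=float(res.scale),
    )


def _discharge_labels(cohort: pd.DataFrame) -> np.ndarray:
    """0 = no event, 1 = event survived, 2 = inpatient death."""
    died = cohort["died_inpatient"].astype(bool).to_numpy()
    any_event = (cohort["event_count"].to_numpy() > 0) | died
    return np.where(died, 2, np.where(any_event, 1, 0))


def _principal_distribution(cohort: pd.DataFrame, arm_name: str) -> PrincipalEventDistribution:
    """Within-survivor principal-event distribution (empirical, normalized)."""
    g = cohort[(cohort["arm"] == arm_name)
               & (cohort["event_count"] > 0)
               & (~cohort["died_inpatient"].astype(bool))]
    counts = {c: float((g["principal_event"] == c).sum()) for c in EVENT_CATEGORIES}
    total = sum(counts.values())
    if total == 0:
        warnings.warn(f"no surviving principal events in arm {arm_name!r}; "
                      "all category probabilities set to 0", stacklevel=3)
        probs = {c: 0.0 for c in EVENT_CATEGORIES}
    else:
        probs = {c: v / total for c, v in counts.items()}
        empty = [c for c, v in counts.items() if v == 0]
        if empty:
            warnings.warn(
                f"arm {arm_name!r}: no observations for {empty}; probability 0",
                stacklevel=3)
    return PrincipalEventDistribution(probabilities=probs, concentrations=counts)


def fit_discharge_state_model(cohort: pd.DataFrame) -> DischargeFit:
    """Multinomial logit over {no event, event survived, death}; per-arm
    probabilities by recycled predictions; Dirichlet effective counts scaled
    to the cohort size."""
    y = _discharge_labels(cohort)
    X = _design(cohort)
    n = len(cohort)
    present = np.unique(y)

    if len(present) == 1:
        probs = {int(present[0]): 1.0}
        arm_probs = {a: tuple(probs.get(k, 0.0) for k in (0, 1, 2)) for a in ARMS}
        coef = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
            except Exception:  # rare-category fits can defeat Newton steps
                res = sm.MNLogit(y, X).fit(disp=0, maxiter=500, method="bfgs")
        coef = res.params
        arm_probs = {}
        for arm_name, value in (("intervention", 1.0), ("control", 0.0)):
            Xa = X.copy()
            Xa["arm"] = value
            p = np.asarray(res.predict(Xa)).mean(axis=0)
            full = dict(zip(present.tolist(), p.tolist()))
            arm_probs[arm_name] = tuple(full.get(k, 0.0) for k in (0, 1, 2))

    state_probs = {}
    for arm_name in ARMS:
        p0, p1, p2 = arm_probs[arm_name]
        state_probs[arm_name] = ArmStateProbabilities(
            p_no_event=p0, p_event_survive=p1, p_inpatient_death=p2,
            dirichlet_counts=(p0 * n, p1 * n, p2 * n),
        )
    principal = {a: _principal_distribution(cohort, a) for a in ARMS}
    return DischargeFit(state_probs=state_probs, principal_events=principal,
                        coefficients=coef)


def bootstrap_central_range(
    statistic: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    retry_cap: int = 10,
) -> tuple[float, float]:
    """95% central range (2.5th/97.5th percentile) of a statistic over
    non-parametric resamples of the cohort rows.

    A resample on which the statistic fails is redrawn up to ``retry_cap``
    times before the bootstrap errors out.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replications")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(retry_cap + 1):
            idx = rng.integers(0, n, n)
            try:
                stats[b] = float(statistic(cohort.iloc[idx]))
                break
            except Exception:
                if attempt == retry_cap:
                    raise EstimationError(
                        f"statistic failed on {retry_cap + 1} consecutive resamples")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def estimate_parameters(
    cohort: pd.DataFrame,
    n_boot: int = 0,
    seed: int = 0,
) -> EstimationResult:
    """Run all three fits; optionally bootstrap per-arm mean central ranges."""
    events = fit_event_count_model(cohort)
    costs = fit_cost_model(cohort)
    discharge = fit_discharge_state_model(cohort)
    event_range = cost_range = None
    if n_boot >= 2:
        event_range = {}
        cost_range = {}
        for arm_name in ARMS:
            event_range[arm_name] = bootstrap_central_range(
                lambda d, a=arm_name: float(d.loc[d["arm"] == a, "event_count"].mean()),
                cohort, n_boot, seed)
            cost_range[arm_name] = bootstrap_central_range(
                lambda d, a=arm_name: float(d.loc[d["arm"] == a, "episode_cost"].mean()),
                cohort, n_boot, seed + 1)
    return EstimationResult(events=events, costs=costs, discharge=discharge,
                            event_range=event_range, cost_range=cost_range)
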