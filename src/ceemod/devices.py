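"""Monitoring-device costing: annualization, throughput, and threshold analysis.

The purchase price of the monitoring equipment is annualized either by
straight-line depreciation over its product life or by the equivalent annual
cost method (dividing by the annuity factor at the discount rate).  Annual
variable cost for the intervention arm is the cableless-sensor spend:
``cableless_rate x annual_patients x sensor_unit``.  Dividing annual cost by
annual patient throughput ``(365 / mean LOS) x beds`` gives the per-patient
device cost that enters the hospital episode cost.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ARMS, DevicePrices, ParameterSet, ResourceUseInputs

METHODS = ("straight_line", "equivalent_annual_cost")


@dataclass(frozen=True)
class DeviceCostResult:
    arm: str
    method: str
    annual_total: float      # GBP per year
    per_bed_year: float      # GBP per bed per year
    per_patient: float       # GBP per patient episode
    annual_patients: float   # patients per year (unrounded)


@dataclass(frozen=True)
class ThresholdResult:
    """Per-patient intervention device cost at which the short-term
    incremental hospital cost crosses zero."""

    threshold_per_patient: float
    base_per_patient: float
    incremental_hospital_cost: float
    intervention_already_more_costly: bool


def annual_patients(beds: float, mean_los: float, occupancy: float = 1.0) -> float:
    """Annual patient throughput of a ward: (365 / mean LOS) x beds x occupancy.

    Returned unrounded; reports may display the rounded integer.
    """
    if beds <= 0 or mean_los <= 0:
        raise ValueError("beds and mean_los must be positive")
    if not (0.0 < occupancy <= 1.0):
        raise ValueError("occupancy must be in (0, 1]")
    return 365.0 / mean_los * beds * occupancy


def annuity_factor(n_years: float, rate: float) -> float:
    """Present value of 1/year for ``n_years`` at discount ``rate``.

    (1 - (1+r)^-n) / r, with the zero-rate limit n.  E.g. 5 years at 3.5%
    gives 4.515.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return float(n_years)
    return (1.0 - (1.0 + rate) ** (-n_years)) / rate


def device_cost_per_patient(
    prices: DevicePrices,
    ru: ResourceUseInputs,
    arm: str,
    method: str = "straight_line",
    discount_rate: float = 0.035,
    sensors_per_patient: float = 1.0,
) -> DeviceCostResult:
    """Per-patient and per-bed-year device cost for one arm.

    The control arm (routine spot-check monitors) has fixed cost only; the
    intervention's variable cost scales linearly in the cableless-sensor rate
    (one sensor per monitored patient episode by default).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    n_pat = annual_patients(ru.beds, ru.mean_los[arm], ru.occupancy)
    fixed = prices.fixed_intervention if arm == "intervention" else prices.fixed_control
    if method == "straight_line":
        fixed_annual = fixed / ru.product_life
    else:
        fixed_annual = fixed / annuity_factor(ru.product_life, discount_rate)
    variable_annual = 0.0
    if arm == "intervention":
        variable_annual = ru.cableless_rate * n_pat * prices.sensor_unit * sensors_per_patient
    annual_total = fixed_annual + variable_annual
    return DeviceCostResult(
        arm=arm,
        method=method,
        annual_total=annual_total,
        per_bed_year=annual_total / ru.beds,
        per_patient=annual_total / n_pat,
        annual_patients=n_pat,
    )


def threshold_device_cost(params: ParameterSet, method: str = "straight_line") -> ThresholdResult:
    """Intervention per-patient device cost at which the short-term
    incremental hospital cost is zero.

    The base incremental hospital cost is the difference of the adjusted
    per-arm episode costs (device cost included).  While the intervention
    saves money (negative incremental cost), its device cost can rise by the
    magnitude of the saving before cost-neutrality; the threshold is the base
    per-patient device cost plus that headroom.  If the intervention is
    already more costly, the (lower) break-even cost is returned with a flag.
    """
    base = device_cost_per_patient(
        params.device_prices, params.resource_use, "intervention",
        method=method, discount_rate=params.discount_rate,
    )
    inc = (params.episode_costs.by_arm["intervention"].mean
           - params.episode_costs.by_arm["control"].mean)
    return ThresholdResult(
        threshold_per_patient=base.per_patient - inc,
        base_per_patient=base.per_patient,
        incremental_hospital_cost=inc,
        intervention_already_more_costly=inc > 0,
    )
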