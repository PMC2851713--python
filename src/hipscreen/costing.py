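"""Itemised cost engine (societal perspective, 2006 euros).

Covers every cost component of the screening programme: screener and
physician wages per ten-minute exam (with evening and extra-consultation
adjustments), parents' travel and productivity losses, rent for external
locations, hospital ultrasound usage where no machine is purchased,
machine annuity/insurance/maintenance, screener training, treatment by
Graf type, and downstream costs of missed cases and false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import HipStatus
from .scenarios import Consultation, Location, MachinesLevel, ScenarioSpec, Screener, StaffingPlan

__all__ = [
    "CostParams",
    "annuity_payment",
    "reported_annuity",
    "machine_annual_cost",
    "machine_cost_per_child",
    "training_cost",
    "exam_staff_cost",
    "visit_overhead_costs",
    "downstream_cost",
    "wage_for",
    "treatment_cost_for",
]


@dataclass(frozen=True)
class CostParams:
    """Unit costs and economic constants.

    All monetary values in euros (2006 price level). ``rent_per_child_external``
    is not an established figure; the default €5 per child is a
    gap-filled assumption and should be swept in sensitivity analysis.
    """

    wage_physician: float = 75.0        # €/h, IHC physician
    wage_nurse: float = 42.0            # €/h, IHC nurse
    wage_rt: float = 70.0               # €/h, radiographic technician
    wage_specialist: float = 106.0      # €/h, radiologist / orthopedic surgeon
    hospital_us_per_hour: float = 61.0  # €/h, ultrasound at hospital
    parent_time_per_hour: float = 36.0  # €/h productivity loss
    km_rate: float = 0.20               # €/km travel
    external_distance_km: float = 10.0
    machine_price: float = 32725.0
    machine_insurance_per_year: float = 1000.0
    maintenance_fraction: float = 0.08  # of machine price, per year
    machine_life_years: int = 5
    interest_rate: float = 0.05         # per year
    exam_minutes: float = 10.0
    training_hours: float = 16.0
    training_wage: float = 73.0         # €/h average screener salary
    training_materials: float = 130.0
    training_cost_per_screener: float = 1300.0  # rounded reported figure
    evening_uplift: float = 0.35        # wage surcharge for evening sessions
    evening_flat_fee: float = 5.0       # €/child alternative to the uplift
    use_evening_flat_fee: bool = False  # uplift and flat fee are the same
                                        # quantity; never apply both
    treat_first_consult: float = 571.0  # treatment after first IHC consultation
    treat_2bc: float = 897.0
    treat_D: float = 717.0
    treat_34: float = 2043.0
    missed_case_cost: float = 1217.0
    fp_visit_cost: float = 97.0         # one hospital visit (61) + parent time (36)
    rent_per_child_external: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "wage_physician", "wage_nurse", "wage_rt", "wage_specialist",
            "hospital_us_per_hour", "parent_time_per_hour", "km_rate",
            "external_distance_km", "machine_price", "machine_insurance_per_year",
            "training_hours", "training_wage", "training_materials",
            "training_cost_per_screener", "evening_flat_fee", "treat_first_consult",
            "treat_2bc", "treat_D", "treat_34", "missed_case_cost",
            "fp_visit_cost", "rent_per_child_external",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("maintenance_fraction", "interest_rate", "evening_uplift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exam_minutes <= 0:
            raise ValueError("exam_minutes must be positive")
        if self.machine_life_years < 1:
            raise ValueError("machine_life_years must be >= 1")

    @property
    def exam_hours(self) -> float:
        return self.exam_minutes / 60.0


def annuity_payment(principal: float, rate_per_period: float, n_periods: int) -> float:
    """Constant payment amortising ``principal`` over ``n_periods``.

    Standard annuity ``P r / (1 - (1+r)^-n)``; ``P / n`` at zero interest.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if rate_per_period < 0:
        raise ValueError("rate_per_period must be >= 0")
    r = rate_per_period
    # rates below float resolution behave as zero interest
    if r == 0 or 1.0 + r == 1.0:
        return principal / n_periods
    return principal * r / (1.0 - (1.0 + r) ** -n_periods)


def reported_annuity(costs: CostParams) -> float:
    """Machine annuity rounded to the nearest €10, as conventionally reported."""
    exact = annuity_payment(costs.machine_price, costs.interest_rate, costs.machine_life_years)
    return round(exact / 10.0) * 10.0


def machine_annual_cost(costs: CostParams) -> float:
    """Annual cost of owning one machine: annuity + insurance + maintenance.

    Uses the reported (€10-rounded) annuity so that cost audits match the
    documented annual figure exactly (same convention as the rounded
    training cost).
    """
    return (
        reported_annuity(costs)
        + costs.machine_insurance_per_year
        + costs.maintenance_fraction * costs.machine_price
    )


def machine_cost_per_child(costs: CostParams, cohort_size: int, n_machines: int) -> float:
    """Machine ownership cost averaged per child of the cohort.

    One year's ownership cost is divided by the full cohort size.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if n_machines < 0:
        raise ValueError("n_machines must be >= 0")
    return n_machines * machine_annual_cost(costs) / cohort_size


def training_cost(n_screeners: int, costs: CostParams) -> float:
    """Total training cost for ``n_screeners`` (two 8-hour days plus materials).

    The per-screener default €1,300 is the rounded value of
    16 h x €73 + €130 = €1,298.
    """
    if n_screeners < 1:
        raise ValueError("n_screeners must be >= 1")
    return n_screeners * costs.training_cost_per_screener


def wage_for(screener: Screener, costs: CostParams) -> float:
    return {
        Screener.IHC_PHYSICIAN: costs.wage_physician,
        Screener.IHC_NURSE: costs.wage_nurse,
        Screener.RADIOGRAPHIC_TECHNICIAN: costs.wage_rt,
        Screener.MEDICAL_SPECIALIST: costs.wage_specialist,
    }[screener]


def exam_staff_cost(plan: StaffingPlan, spec: ScenarioSpec, costs: CostParams) -> float:
    """Staff cost of one examination.

    Screener wage for the exam duration, plus the physician's time when
    an integrated consultation requires physician presence (technician
    or specialist screening). An extra consultation doubles the salary
    cost; evening sessions carry a wage surcharge (unless the flat-fee
    variant is configured, which bills a fixed amount per child via
    :func:`visit_overhead_costs` instead). Nurse delegation adds
    nothing: the nurse's exam time replaces the physician's.
    """
    c = wage_for(spec.screener, costs) * costs.exam_hours
    if plan.physician_present_at_exam:
        c += costs.wage_physician * costs.exam_hours
    if spec.consultation is Consultation.EXTRA:
        c *= 2.0
    if spec.location is Location.IHC_EVENING and not costs.use_evening_flat_fee:
        c *= 1.0 + costs.evening_uplift
    return c


def visit_overhead_costs(
    distance_km_ihc: float | np.ndarray,
    spec: ScenarioSpec,
    costs: CostParams,
) -> dict[str, float | np.ndarray]:
    """Non-staff costs per screened child: travel, parent time, rent, machine use.

    Travel is charged at the km rate over the child's IHC distance (or
    the fixed external distance), parents lose one hour of productivity
    per consultation — both doubled for an extra consultation. External
    locations add rent per child; scenarios that purchase no machine
    bill hospital ultrasound usage pro-rated to the exam duration.
    Accepts a scalar or an array of distances.
    """
    extra = spec.consultation is Consultation.EXTRA
    visits = 2.0 if extra else 1.0
    if spec.location is Location.EXTERNAL:
        dist = np.broadcast_to(costs.external_distance_km, np.shape(distance_km_ihc)) \
            if np.ndim(distance_km_ihc) else costs.external_distance_km
    else:
        dist = distance_km_ihc
    travel = np.multiply(dist, costs.km_rate) * visits
    parent = costs.parent_time_per_hour * visits
    rent = costs.rent_per_child_external if spec.location is Location.EXTERNAL else 0.0
    machine_use = (
        costs.hospital_us_per_hour * costs.exam_hours
        if spec.machines_level is MachinesLevel.NONE
        else 0.0
    )
    flat_evening = (
        costs.evening_flat_fee
        if (spec.location is Location.IHC_EVENING and costs.use_evening_flat_fee)
        else 0.0
    )
    shape = np.shape(travel)
    return {
        "travel": travel,
        "parent_time": np.broadcast_to(parent + flat_evening, shape).copy() if shape else parent + flat_evening,
        "rent": np.broadcast_to(rent, shape).copy() if shape else rent,
        "machine_use": np.broadcast_to(machine_use, shape).copy() if shape else machine_use,
    }


def treatment_cost_for(status: HipStatus, costs: CostParams) -> float:
    try:
        return {
            HipStatus.TYPE_2BC: costs.treat_2bc,
            HipStatus.TYPE_D: costs.treat_D,
            HipStatus.TYPE_34: costs.treat_34,
        }[status]
    except KeyError:
        raise ValueError(f"no treatment cost for status {status!r}") from None


def downstream_cost(classification: str, graf_type: HipStatus | None, costs: CostParams) -> float:
    """Referral and treatment cost following one screening result.

    True positives are treated according to Graf type; false negatives
    (missed cases) incur the later, costlier average treatment; false
    positives cost one hospital visit including parents' absence from
    work; true negatives cost nothing further.
    """
    if classification == "TP":
        if graf_type is None or graf_type == HipStatus.HEALTHY:
            raise ValueError("a true positive requires an affected Graf type")
        return treatment_cost_for(graf_type, costs)
    if classification == "FN":
        return costs.missed_case_cost
    if classification == "FP":
        return costs.fp_visit_cost
    if classification == "TN":
        return 0.0
    raise ValueError(f"unknown classification {classification!r}")
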