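"""Screening pathway simulation and its closed-form expectation oracle.

Each child of a synthetic cohort is invited to the three-month
ultrasound screen, attends with the region's attendance rate (one
reminder is sent to non-attenders), is examined by the scenario's
screener, and is classified true/false positive/negative against the
latent hip status. Costs are itemised per child (staff, travel, parent
time, rent, machine use, downstream referral/treatment) and fixed costs
(screener training, machine ownership) are added once per replication.

Children are independent and no capacity constraints are modelled, so
scenario totals are sums of per-stratum expectations;
:func:`expected_scenario` evaluates those expectations in closed form
and serves as the deterministic oracle for the Monte-Carlo estimates.

A comparator for the current physical-examination screening applies
published whole-cohort rates (2.8% true positive, 16.5% false positive,
0.9% missed) directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_QUALITY,
    Cohort,
    HipStatus,
    PopulationParams,
    Region,
    ScreenerProfile,
    conditional_rates,
    generate_cohort,
)
from .costing import (
    CostParams,
    exam_staff_cost,
    machine_annual_cost,
    training_cost,
    visit_overhead_costs,
)
from .scenarios import ScenarioSpec, StaffingPlan, staffing_plan

__all__ = [
    "Classification",
    "ComparatorParams",
    "Replication",
    "ScenarioResult",
    "DegenerateParametersError",
    "COMPONENTS",
    "attendance_draw",
    "classify",
    "run_replication",
    "simulate_scenario",
    "expected_scenario",
    "simulate_current",
    "expected_current",
    "CURRENT_STREAM",
]

#: Sub-stream id reserved for the current-screening comparator
#: (scenario streams use their canonical ids 1..72).
CURRENT_STREAM = 100

#: Itemised cost components; their sum is the scenario total.
COMPONENTS = (
    "staff",
    "travel",
    "parent_time",
    "rent",
    "machine_use",
    "downstream",
    "prescreen",
    "training_fixed",
    "machines_fixed",
)


class Classification(enum.IntEnum):
    TN = 0
    TP = 1
    FP = 2
    FN = 3
    NOT_SCREENED = 4


class DegenerateParametersError(ValueError):
    """No children can be detected: the cost-effectiveness ratio is undefined."""


@dataclass(frozen=True)
class ComparatorParams:
    """Whole-cohort operating characteristics of current screening."""

    missed_rate: float = 0.009
    fp_rate: float = 0.165
    tp_rate: float = 0.028

    def __post_init__(self) -> None:
        for name in ("missed_rate", "fp_rate", "tp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.missed_rate + self.fp_rate + self.tp_rate > 1.0:
            raise ValueError("rates sum beyond 1")


@dataclass
class Replication:
    """Counts and itemised costs of one simulated cohort pass."""

    n_screened: int
    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int
    n_not_screened: int
    components: dict[str, float]
    total_cost: float
    children: pd.DataFrame | None = None


@dataclass
class ScenarioResult:
    """Replication summary for one scenario (or the comparator)."""

    spec: ScenarioSpec | None
    n_reps: int
    seed: int
    mean_total_cost: float
    mean_detected: float
    mean_fp: float
    mean_missed: float
    mean_tn: float
    mean_screened: float
    ce_ratio: float
    ce_ratio_ci: tuple[float, float]
    mean_components: dict[str, float]
    rep_totals: np.ndarray = field(repr=False, default=None)
    rep_tp: np.ndarray = field(repr=False, default=None)
    rep_fp: np.ndarray = field(repr=False, default=None)
    rep_fn: np.ndarray = field(repr=False, default=None)

    @property
    def canonical_id(self) -> int | None:
        return None if self.spec is None else self.spec.canonical_id


def _rep_rng(seed: int, stream: int, rep: int) -> np.random.Generator:
    """Deterministic per-(stream, replication) generator from one root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, rep)))


def attendance_draw(
    region: np.ndarray, pop: PopulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised attendance: first invitation, then one reminder.

    Returns boolean arrays ``(attended, attended_after_reminder)`` where
    ``attended`` covers both routes.
    """
    urban = np.asarray(region) == Region.URBAN
    p_first = np.where(urban, pop.attendance_urban, pop.attendance_rural)
    first = rng.random(urban.size) < p_first
    p_re = np.where(urban, pop.reattendance_urban, pop.reattendance_rural)
    after = ~first & (rng.random(urban.size) < p_re)
    return first | after, after


def classify(affected: np.ndarray, screened: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Per-child outcome codes (affected & positive -> TP, etc.)."""
    out = np.full(np.shape(affected), Classification.NOT_SCREENED, dtype=np.int8)
    out[screened & affected & positive] = Classification.TP
    out[screened & affected & ~positive] = Classification.FN
    out[screened & ~affected & positive] = Classification.FP
    out[screened & ~affected & ~positive] = Classification.TN
    return out


def _error_rates(profile: ScreenerProfile, prevalence: float) -> tuple[float, float]:
    # Degenerate prevalence 0 is allowed in simulation (all-healthy cohort).
    if prevalence == 0.0:
        return 0.0, profile.fp_rate
    return conditional_rates(profile, prevalence)


def _fixed_costs(plan: StaffingPlan, costs: CostParams) -> tuple[float, float]:
    training = training_cost(plan.screeners_trained, costs)
    machines = plan.machines_purchased * machine_annual_cost(costs)
    return training, machines


def run_replication(
    spec: ScenarioSpec,
    pop: PopulationParams,
    costs: CostParams,
    rng: np.random.Generator,
    *,
    profiles: dict | None = None,
    n_sites: int = 7,
    return_children: bool = False,
) -> Replication:
    """Simulate one cohort through one scenario."""
    profiles = DEFAULT_QUALITY if profiles is None else profiles
    plan = staffing_plan(spec, n_sites)
    coh = generate_cohort(pop, rng)
    n = coh.n

    attended, after_reminder = attendance_draw(coh.region, pop, rng)
    affected = coh.affected
    miss_g, fp_g = _error_rates(profiles[spec.screener], pop.prevalence)
    u = rng.random(n)
    positive = np.where(affected, u < 1.0 - miss_g, u < fp_g) & attended
    cls = classify(affected, attended, positive)

    staff_per_exam = exam_staff_cost(plan, spec, costs)
    staff = np.where(attended, staff_per_exam, 0.0)
    over = visit_overhead_costs(coh.distance_km_ihc, spec, costs)
    travel = np.where(attended, over["travel"], 0.0)
    parent = np.where(attended, over["parent_time"], 0.0)
    rent = np.where(attended, over["rent"], 0.0)
    machine_use = np.where(attended, over["machine_use"], 0.0)

    treat_by_status = np.array(
        [0.0, costs.treat_2bc, costs.treat_D, costs.treat_34]
    )
    downstream = np.zeros(n)
    downstream[cls == Classification.TP] = treat_by_status[
        coh.true_status[cls == Classification.TP]
    ]
    downstream[cls == Classification.FN] = costs.missed_case_cost
    downstream[cls == Classification.FP] = costs.fp_visit_cost

    prescreen = (
        coh.prescreen.n_treated * costs.treat_first_consult
        + coh.prescreen.n_referred_untreated * costs.fp_visit_cost
    )
    training_fixed, machines_fixed = _fixed_costs(plan, costs)

    components = {
        "staff": float(staff.sum()),
        "travel": float(travel.sum()),
        "parent_time": float(parent.sum()),
        "rent": float(rent.sum()),
        "machine_use": float(machine_use.sum()),
        "downstream": float(downstream.sum()),
        "prescreen": float(prescreen),
        "training_fixed": float(training_fixed),
        "machines_fixed": float(machines_fixed),
    }
    total = sum(components.values())

    children = None
    if return_children:
        children = coh.to_frame()
        children["attended"] = attended
        children["attended_after_reminder"] = after_reminder
        children["test_positive"] = np.where(attended, positive, pd.NA)
        children["classification"] = pd.Categorical.from_codes(
            cls, [c.name for c in Classification]
        )
        children["staff"] = staff
        children["travel"] = travel
        children["parent_time"] = parent
        children["rent"] = rent
        children["machine_use"] = machine_use
        children["downstream"] = downstream
        children["total"] = staff + travel + parent + rent + machine_use + downstream

    return Replication(
        n_screened=int(attended.sum()),
        n_tp=int((cls == Classification.TP).sum()),
        n_fp=int((cls == Classification.FP).sum()),
        n_fn=int((cls == Classification.FN).sum()),
        n_tn=int((cls == Classification.TN).sum()),
        n_not_screened=int((~attended).sum()),
        components=components,
        total_cost=total,
        children=children,
    )


def _summarise(
    spec: ScenarioSpec | None,
    reps: list[Replication],
    seed: int,
) -> ScenarioResult:
    totals = np.array([r.total_cost for r in reps])
    tp = np.array([r.n_tp for r in reps], dtype=float)
    fp = np.array([r.n_fp for r in reps], dtype=float)
    fn = np.array([r.n_fn for r in reps], dtype=float)
    tn = np.array([r.n_tn for r in reps], dtype=float)
    scr = np.array([r.n_screened for r in reps], dtype=float)
    mean_tp = tp.mean()
    if mean_tp == 0:
        raise DegenerateParametersError(
            "no detected children in any replication; CE ratio undefined"
        )
    ce = totals.mean() / mean_tp
    n = len(reps)
    if n > 1:
        # Delta-method CI for the ratio of means.
        cov = np.cov(totals, tp, ddof=1)
        var = (cov[0, 0] - 2 * ce * cov[0, 1] + ce**2 * cov[1, 1]) / (mean_tp**2 * n)
        half = 1.96 * np.sqrt(max(var, 0.0))
    else:
        half = 0.0
    comp_means = {
        k: float(np.mean([r.components[k] for r in reps])) for k in COMPONENTS
    }
    return ScenarioResult(
        spec=spec,
        n_reps=n,
        seed=seed,
        mean_total_cost=float(totals.mean()),
        mean_detected=float(mean_tp),
        mean_fp=float(fp.mean()),
        mean_missed=float(fn.mean()),
        mean_tn=float(tn.mean()),
        mean_screened=float(scr.mean()),
        ce_ratio=float(ce),
        ce_ratio_ci=(float(ce - half), float(ce + half)),
        mean_components=comp_means,
        rep_totals=totals,
        rep_tp=tp,
        rep_fp=fp,
        rep_fn=fn,
    )


def simulate_scenario(
    spec: ScenarioSpec,
    pop: PopulationParams,
    costs: CostParams,
    n_reps: int = 100,
    seed: int = 0,
    *,
    profiles: dict | None = None,
    n_sites: int = 7,
) -> ScenarioResult:
    """Monte-Carlo evaluation of one scenario over ``n_reps`` fresh cohorts.

    All randomness derives from ``seed`` split per (scenario,
    replication), so results do not depend on execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reps = [
        run_replication(
            spec,
            pop,
            costs,
            _rep_rng(seed, spec.canonical_id, r),
            profiles=profiles,
            n_sites=n_sites,
        )
        for r in range(n_reps)
    ]
    return _summarise(spec, reps, seed)


def expected_scenario(
    spec: ScenarioSpec,
    pop: PopulationParams,
    costs: CostParams,
    *,
    profiles: dict | None = None,
    n_sites: int = 7,
) -> ScenarioResult:
    """Closed-form expected counts and costs for one scenario.

    Children are independent, so every total is a sum of per-stratum
    expectations; no randomness is involved and the confidence interval
    is degenerate. ``n_reps`` is reported as 0.
    """
    profiles = DEFAULT_QUALITY if profiles is None else profiles
    plan = staffing_plan(spec, n_sites)
    n = pop.cohort_size

    p_scr = pop.p_screened_marginal
    e_screened = n * p_scr
    e_affected_scr = n * pop.prevalence * p_scr
    e_healthy_scr = n * (1.0 - pop.prevalence) * p_scr

    miss_g, fp_g = _error_rates(profiles[spec.screener], pop.prevalence)
    e_tp = e_affected_scr * (1.0 - miss_g)
    e_fn = e_affected_scr * miss_g
    e_fp = e_healthy_scr * fp_g
    e_tn = e_healthy_scr - e_fp
    if e_tp == 0:
        raise DegenerateParametersError("expected number detected is zero; CE undefined")

    staff = exam_staff_cost(plan, spec, costs) * e_screened
    mean_dist = 0.5 * (pop.distance_km_min + pop.distance_km_max)
    over = visit_overhead_costs(mean_dist, spec, costs)
    travel = float(over["travel"]) * e_screened
    parent = float(over["parent_time"]) * e_screened
    rent = float(over["rent"]) * e_screened
    machine_use = float(over["machine_use"]) * e_screened

    mix = pop.graf_mix_conditional
    mean_treat = float(
        mix @ np.array([costs.treat_2bc, costs.treat_D, costs.treat_34])
    )
    downstream = e_tp * mean_treat + e_fn * costs.missed_case_cost + e_fp * costs.fp_visit_cost
    prescreen = n * (
        pop.prescreen_treated * costs.treat_first_consult
        + (pop.prescreen_referral - pop.prescreen_treated) * costs.fp_visit_cost
    )
    training_fixed, machines_fixed = _fixed_costs(plan, costs)

    components = {
        "staff": staff,
        "travel": travel,
        "parent_time": parent,
        "rent": rent,
        "machine_use": machine_use,
        "downstream": downstream,
        "prescreen": prescreen,
        "training_fixed": training_fixed,
        "machines_fixed": machines_fixed,
    }
    total = float(sum(components.values()))
    ce = total / e_tp
    return ScenarioResult(
        spec=spec,
        n_reps=0,
        seed=0,
        mean_total_cost=total,
        mean_detected=float(e_tp),
        mean_fp=float(e_fp),
        mean_missed=float(e_fn),
        mean_tn=float(e_tn),
        mean_screened=float(e_screened),
        ce_ratio=float(ce),
        ce_ratio_ci=(float(ce), float(ce)),
        mean_components=components,
    )


def _current_replication(
    pop: PopulationParams,
    costs: CostParams,
    comp: ComparatorParams,
    rng: np.random.Generator,
) -> Replication:
    """One cohort pass under current physical-examination screening.

    The published whole-cohort rates are applied directly per screened
    child; the physical exam itself happens within routine
    consultations and adds no programme cost beyond downstream care.
    """
    coh = generate_cohort(pop, rng)
    attended, _ = attendance_draw(coh.region, pop, rng)
    n_scr = int(attended.sum())
    p = np.array(
        [comp.tp_rate, comp.fp_rate, comp.missed_rate,
         1.0 - comp.tp_rate - comp.fp_rate - comp.missed_rate]
    )
    draws = rng.choice(4, size=n_scr, p=p)  # 0 TP, 1 FP, 2 FN, 3 TN
    n_tp = int((draws == 0).sum())
    n_fp = int((draws == 1).sum())
    n_fn = int((draws == 2).sum())
    n_tn = n_scr - n_tp - n_fp - n_fn
    graf = rng.choice(3, size=n_tp, p=pop.graf_mix_conditional)
    treat = np.array([costs.treat_2bc, costs.treat_D, costs.treat_34])
    downstream = (
        float(treat[graf].sum()) + n_fn * costs.missed_case_cost + n_fp * costs.fp_visit_cost
    )
    prescreen = (
        coh.prescreen.n_treated * costs.treat_first_consult
        + coh.prescreen.n_referred_untreated * costs.fp_visit_cost
    )
    components = {k: 0.0 for k in COMPONENTS}
    components["downstream"] = downstream
    components["prescreen"] = float(prescreen)
    total = downstream + prescreen
    return Replication(
        n_screened=n_scr,
        n_tp=n_tp,
        n_fp=n_fp,
        n_fn=n_fn,
        n_tn=n_tn,
        n_not_screened=coh.n - n_scr,
        components=components,
        total_cost=total,
    )


def simulate_current(
    pop: PopulationParams,
    costs: CostParams,
    n_reps: int = 100,
    seed: int = 0,
    comparator: ComparatorParams | None = None,
) -> ScenarioResult:
    """Monte-Carlo comparator: current screening by physical examination."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    comp = ComparatorParams() if comparator is None else comparator
    if comp.tp_rate == 0 and comp.fp_rate == 0:
        raise DegenerateParametersError("comparator rates yield no detections")
    reps = [
        _current_replication(pop, costs, comp, _rep_rng(seed, CURRENT_STREAM, r))
        for r in range(n_reps)
    ]
    return _summarise(None, reps, seed)


def expected_current(
    pop: PopulationParams,
    costs: CostParams,
    comparator: ComparatorParams | None = None,
) -> ScenarioResult:
    """Closed-form expectation of the current-screening comparator."""
    comp = ComparatorParams() if comparator is None else comparator
    e_screened = pop.cohort_size * pop.p_screened_marginal
    e_tp = e_screened * comp.tp_rate
    e_fp = e_screened * comp.fp_rate
    e_fn = e_screened * comp.missed_rate
    e_tn = e_screened - e_tp - e_fp - e_fn
    if e_tp == 0:
        raise DegenerateParametersError("expected number detected is zero; CE undefined")
    mix = pop.graf_mix_conditional
    mean_treat = float(mix @ np.array([costs.treat_2bc, costs.treat_D, costs.treat_34]))
    downstream = e_tp * mean_treat + e_fn * costs.missed_case_cost + e_fp * costs.fp_visit_cost
    prescreen = pop.cohort_size * (
        pop.prescreen_treated * costs.treat_first_consult
        + (pop.prescreen_referral - pop.prescreen_treated) * costs.fp_visit_cost
    )
    components = {k: 0.0 for k in COMPONENTS}
    components["downstream"] = downstream
    components["prescreen"] = prescreen
    total = downstream + prescreen
    ce = total / e_tp
    return ScenarioResult(
        spec=None,
        n_reps=0,
        seed=0,
        mean_total_cost=float(total),
        mean_detected=float(e_tp),
        mean_fp=float(e_fp),
        mean_missed=float(e_fn),
        mean_tn=float(e_tn),
        mean_screened=float(e_screened),
        ce_ratio=float(ce),
        ce_ratio_ci=(float(ce), float(ce)),
        mean_components=components,
    )
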