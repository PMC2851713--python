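"""Itemised cost engine: annuity, machines, training, exams, downstream."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipscreen import (
    Consultation,
    CostParams,
    HipStatus,
    Location,
    MachinesLevel,
    ScenarioSpec,
    Screener,
    annuity_payment,
    downstream_cost,
    exam_staff_cost,
    machine_annual_cost,
    machine_cost_per_child,
    staffing_plan,
    training_cost,
    visit_overhead_costs,
)
from hipscreen.costing import reported_annuity


def amortization_balance(principal, rate, n, payment):
    """Independent oracle: remaining balance after n level payments."""
    balance = principal
    for _ in range(n):
        balance = balance * (1 + rate) - payment
    return balance


class TestAnnuity:
    def test_machine_annuity_matches_documented_figure(self, costs):
        exact = annuity_payment(costs.machine_price, costs.interest_rate, costs.machine_life_years)
        assert exact == pytest.approx(7558.65, abs=0.01)
        assert reported_annuity(costs) == 7560.0

    def test_zero_interest_is_straight_line(self):
        assert annuity_payment(1000, 0.0, 4) == pytest.approx(250.0)

    def test_hand_computed_two_period_case(self):
        assert annuity_payment(1000, 0.10, 2) == pytest.approx(576.19, abs=0.005)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            annuity_payment(1000, 0.05, 0)
        with pytest.raises(ValueError):
            annuity_payment(1000, -0.05, 5)

    @settings(max_examples=60, derandomize=True)
    @given(
        principal=st.floats(100, 1e6),
        rate=st.floats(0.0, 0.3),
        n=st.integers(1, 40),
    )
    def test_payment_amortises_to_zero_balance(self, principal, rate, n):
        payment = annuity_payment(principal, rate, n)
        assert abs(amortization_balance(principal, rate, n, payment)) < 1e-5 * principal


class TestMachineAndTraining:
    def test_annual_ownership_cost(self, costs):
        # 7560 annuity + 1000 insurance + 2618 maintenance
        assert machine_annual_cost(costs) == pytest.approx(11178.0)

    def test_cost_per_child(self, costs):
        assert machine_cost_per_child(costs, 2300, 1) == pytest.approx(4.86, abs=0.001)
        assert machine_cost_per_child(costs, 2300, 0) == 0.0
        assert machine_cost_per_child(costs, 2300, 7) == pytest.approx(34.02, abs=0.005)

    def test_training_cost_is_rounded_per_screener_figure(self, costs):
        assert training_cost(1, costs) == 1300.0
        assert training_cost(7, costs) == 9100.0
        # rounded from the 16 h x 73 euro + 130 euro components
        unrounded = costs.training_hours * costs.training_wage + costs.training_materials
        assert unrounded == 1298.0
        assert round(unrounded, -2) == costs.training_cost_per_screener

    def test_invalid_counts_rejected(self, costs):
        with pytest.raises(ValueError):
            training_cost(0, costs)
        with pytest.raises(ValueError):
            machine_cost_per_child(costs, 0, 1)


def _spec(machines, consult, screener, location):
    return ScenarioSpec(machines, consult, screener, location)


class TestExamStaffCost:
    @pytest.mark.parametrize(
        "screener, consult, location, expected",
        [
            # ten-minute wage share of the physician
            (Screener.IHC_PHYSICIAN, Consultation.INTEGRATED, Location.IHC_DAYTIME, 75 / 6),
            # technician screens, physician must be present for the regular consult
            (
                Screener.RADIOGRAPHIC_TECHNICIAN,
                Consultation.INTEGRATED,
                Location.IHC_DAYTIME,
                70 / 6 + 75 / 6,
            ),
            # extra consultation doubles salary cost, evening adds 35%
            (Screener.IHC_NURSE, Consultation.EXTRA, Location.IHC_EVENING, 2 * (42 / 6) * 1.35),
            # delegation: nurse time replaces the physician's
            (Screener.IHC_NURSE, Consultation.INTEGRATED, Location.IHC_DAYTIME, 42 / 6),
        ],
    )
    def test_exam_cost_cases(self, costs, screener, consult, location, expected):
        spec = _spec(MachinesLevel.LIMITED, consult, screener, location)
        plan = staffing_plan(spec)
        assert exam_staff_cost(plan, spec, costs) == pytest.approx(expected, abs=0.005)

    @settings(max_examples=40, derandomize=True)
    @given(
        extra_wage=st.floats(0.0, 100.0),
        scenario_index=st.integers(0, 71),
    )
    def test_monotone_in_every_wage(self, costs, specs, extra_wage, scenario_index):
        spec = specs[scenario_index]
        plan = staffing_plan(spec)
        base = exam_staff_cost(plan, spec, costs)
        for wage_field in ("wage_physician", "wage_nurse", "wage_rt", "wage_specialist"):
            raised = dataclasses.replace(
                costs, **{wage_field: getattr(costs, wage_field) + extra_wage}
            )
            assert exam_staff_cost(plan, spec, raised) >= base

    def test_flat_fee_variant_disables_uplift(self, costs):
        spec = _spec(
            MachinesLevel.LIMITED, Consultation.INTEGRATED, Screener.IHC_NURSE,
            Location.IHC_EVENING,
        )
        plan = staffing_plan(spec)
        flat = dataclasses.replace(costs, use_evening_flat_fee=True)
        assert exam_staff_cost(plan, spec, flat) == pytest.approx(42 / 6)
        over = visit_overhead_costs(5.0, spec, flat)
        assert over["parent_time"] == pytest.approx(36.0 + 5.0)


class TestVisitOverhead:
    def test_integrated_daytime_visit(self, costs):
        spec = _spec(
            MachinesLevel.LIMITED, Consultation.INTEGRATED, Screener.IHC_NURSE,
            Location.IHC_DAYTIME,
        )
        over = visit_overhead_costs(5.0, spec, costs)
        assert over["travel"] == pytest.approx(1.0)
        assert over["parent_time"] == pytest.approx(36.0)
        assert over["rent"] == 0.0
        assert over["machine_use"] == 0.0

    def test_extra_consultation_doubles_travel_and_parent_time(self, costs):
        spec = _spec(
            MachinesLevel.LIMITED, Consultation.EXTRA, Screener.IHC_NURSE, Location.IHC_DAYTIME
        )
        over = visit_overhead_costs(5.0, spec, costs)
        assert over["travel"] + over["parent_time"] == pytest.approx(2.0 + 72.0)

    def test_external_location_with_no_machines(self, costs):
        spec = _spec(
            MachinesLevel.NONE, Consultation.INTEGRATED, Screener.IHC_NURSE, Location.EXTERNAL
        )
        over = visit_overhead_costs(5.0, spec, costs)
        # fixed 10 km distance, rent, and hospital ultrasound per 10-min exam
        assert over["travel"] == pytest.approx(2.0)
        assert over["rent"] == pytest.approx(5.0)
        assert over["machine_use"] == pytest.approx(61 / 6, abs=0.005)
        total = sum(float(v) for v in over.values())
        assert total == pytest.approx(2.0 + 36.0 + 5.0 + 61 / 6, abs=0.005)

    @settings(max_examples=40, derandomize=True)
    @given(distance=st.floats(4.0, 7.0), scenario_index=st.integers(0, 71))
    def test_extra_never_cheaper_than_integrated(self, costs, specs, distance, scenario_index):
        spec = specs[scenario_index]
        integrated = dataclasses.replace(spec, consultation=Consultation.INTEGRATED)
        extra = dataclasses.replace(spec, consultation=Consultation.EXTRA)
        cost_of = lambda s: sum(
            float(v) for v in visit_overhead_costs(distance, s, costs).values()
        ) + exam_staff_cost(staffing_plan(s), s, costs)
        assert cost_of(extra) >= cost_of(integrated)


class TestDownstream:
    @pytest.mark.parametrize(
        "classification, graf, expected",
        [
            ("TP", HipStatus.TYPE_2BC, 897.0),
            ("TP", HipStatus.TYPE_D, 717.0),
            ("TP", HipStatus.TYPE_34, 2043.0),
            ("FN", HipStatus.TYPE_D, 1217.0),
            ("FP", None, 97.0),
            ("TN", None, 0.0),
        ],
    )
    def test_costs_by_outcome(self, costs, classification, graf, expected):
        assert downstream_cost(classification, graf, costs) == expected

    def test_true_positive_without_graf_type_is_inconsistent(self, costs):
        with pytest.raises(ValueError):
            downstream_cost("TP", None, costs)
        with pytest.raises(ValueError):
            downstream_cost("TP", HipStatus.HEALTHY, costs)
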