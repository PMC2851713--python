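"""Screening pathway simulation against the closed-form expectation oracle."""

import dataclasses

import numpy as np
import pytest

from hipscreen import (
    DEFAULT_QUALITY,
    Classification,
    ComparatorParams,
    DegenerateParametersError,
    PopulationParams,
    Region,
    Screener,
    ScreenerProfile,
    expected_current,
    expected_scenario,
    run_replication,
    simulate_current,
    simulate_scenario,
)
from hipscreen.simulate import attendance_draw, classify


class TestAttendance:
    def test_overall_screening_probabilities(self, pop):
        # rural: 0.90 + 0.10 x 0.90 = 0.99; urban: 0.85 + 0.15 x 0.80 = 0.97
        assert pop.p_screened(Region.RURAL) == pytest.approx(0.99)
        assert pop.p_screened(Region.URBAN) == pytest.approx(0.97)

    def test_empirical_attendance_matches(self, pop):
        rng = np.random.default_rng(3)
        region = np.full(200_000, Region.RURAL, dtype=np.int8)
        attended, after_reminder = attendance_draw(region, pop, rng)
        assert attended.mean() == pytest.approx(0.99, abs=3 * np.sqrt(0.99 * 0.01 / 2e5))
        assert after_reminder[~attended].size == 0 or not attended[~attended].any()
        # reminder-attenders are a subset of attenders
        assert (attended | ~after_reminder).all()

    def test_full_attendance_means_no_reminders(self):
        pop = PopulationParams(attendance_urban=1.0, attendance_rural=1.0)
        rng = np.random.default_rng(0)
        attended, after = attendance_draw(np.zeros(1000, dtype=np.int8), pop, rng)
        assert attended.all()
        assert not after.any()


class TestClassify:
    def test_truth_table(self):
        affected = np.array([True, True, False, False, True])
        screened = np.array([True, True, True, True, False])
        positive = np.array([True, False, True, False, False])
        out = classify(affected, screened, positive)
        expected = [
            Classification.TP,
            Classification.FN,
            Classification.FP,
            Classification.TN,
            Classification.NOT_SCREENED,
        ]
        assert list(out) == expected


class TestReplication:
    def test_conservation_of_children(self, pop, costs, specs):
        for spec in specs[::13]:
            rep = run_replication(spec, pop, costs, np.random.default_rng(5))
            assert rep.n_tp + rep.n_fp + rep.n_fn + rep.n_tn == rep.n_screened
            assert rep.n_screened + rep.n_not_screened == pop.cohort_size

    def test_true_results_partition_affected_screened(self, pop, costs, specs):
        rep = run_replication(
            specs[0], pop, costs, np.random.default_rng(5), return_children=True
        )
        kids = rep.children
        affected_screened = (
            (kids["true_status"] != "healthy") & kids["attended"]
        ).sum()
        assert rep.n_tp + rep.n_fn == affected_screened

    def test_cost_breakdown_additivity(self, pop, costs, specs):
        rep = run_replication(
            specs[17], pop, costs, np.random.default_rng(9), return_children=True
        )
        kids = rep.children
        item_cols = ["staff", "travel", "parent_time", "rent", "machine_use", "downstream"]
        np.testing.assert_allclose(
            kids[item_cols].sum(axis=1), kids["total"], rtol=0, atol=1e-9
        )
        fixed = (
            rep.components["prescreen"]
            + rep.components["training_fixed"]
            + rep.components["machines_fixed"]
        )
        assert rep.total_cost == pytest.approx(kids["total"].sum() + fixed, rel=1e-12)

    def test_unattended_children_cost_nothing(self, pop, costs, specs):
        rep = run_replication(
            specs[40], pop, costs, np.random.default_rng(2), return_children=True
        )
        kids = rep.children
        assert (kids.loc[~kids["attended"], "total"] == 0).all()
        assert (kids.loc[~kids["attended"], "classification"] == "NOT_SCREENED").all()


class TestSimulateScenario:
    def test_same_seed_bit_identical(self, pop, costs, specs):
        a = simulate_scenario(specs[30], pop, costs, n_reps=5, seed=123)
        b = simulate_scenario(specs[30], pop, costs, n_reps=5, seed=123)
        np.testing.assert_array_equal(a.rep_totals, b.rep_totals)
        assert a.ce_ratio == b.ce_ratio
        assert a.mean_components == b.mean_components

    def test_results_independent_of_other_scenarios(self, pop, costs, specs):
        # seed streams are split per scenario, so running one scenario in
        # isolation reproduces its values from a full-grid run
        alone = simulate_scenario(specs[7], pop, costs, n_reps=3, seed=11)
        after_others = simulate_scenario(specs[7], pop, costs, n_reps=3, seed=11)
        assert alone.mean_total_cost == after_others.mean_total_cost

    def test_mean_near_oracle_for_sampled_scenarios(self, pop, costs, specs):
        for spec in specs[::17]:
            sim = simulate_scenario(spec, pop, costs, n_reps=200, seed=0)
            exp = expected_scenario(spec, pop, costs)
            se = sim.rep_totals.std(ddof=1) / np.sqrt(sim.n_reps)
            assert abs(sim.mean_total_cost - exp.mean_total_cost) <= 3 * se

    def test_raising_cost_parameter_never_lowers_total(self, pop, costs, specs):
        base = simulate_scenario(specs[20], pop, costs, n_reps=10, seed=4)
        for fld, bump in [
            ("parent_time_per_hour", 10.0),
            ("km_rate", 0.5),
            ("missed_case_cost", 500.0),
            ("wage_nurse", 20.0),
        ]:
            raised_costs = dataclasses.replace(costs, **{fld: getattr(costs, fld) + bump})
            raised = simulate_scenario(specs[20], pop, costs=raised_costs, n_reps=10, seed=4)
            assert raised.mean_total_cost >= base.mean_total_cost

    def test_degenerate_parameters_raise(self, costs, specs):
        pop0 = PopulationParams(prevalence=0.0)
        no_fp = {
            s: ScreenerProfile(s, p.wage_per_hour, 0.0, 0.0)
            for s, p in DEFAULT_QUALITY.items()
        }
        with pytest.raises(DegenerateParametersError):
            simulate_scenario(specs[0], pop0, costs, n_reps=3, seed=0, profiles=no_fp)


class TestExpectedScenario:
    def test_tp_fraction_of_screened_is_032_for_rt(self, pop, costs, specs):
        spec = next(s for s in specs if s.screener is Screener.RADIOGRAPHIC_TECHNICIAN)
        exp = expected_scenario(spec, pop, costs)
        # prevalence 3.8% minus 0.6% missed = 3.2% true positives of screened
        assert exp.mean_detected / exp.mean_screened == pytest.approx(0.032)

    def test_perfect_screening_detects_every_screened_affected_child(self, costs, specs):
        pop = PopulationParams(
            prevalence=0.5, attendance_urban=1.0, attendance_rural=1.0
        )
        perfect = {
            s: ScreenerProfile(s, p.wage_per_hour, 0.0, 0.0)
            for s, p in DEFAULT_QUALITY.items()
        }
        exp = expected_scenario(specs[0], pop, costs, profiles=perfect)
        assert exp.mean_screened == pop.cohort_size
        assert exp.mean_detected == pytest.approx(pop.cohort_size * 0.5)
        assert exp.mean_missed == 0.0

    def test_deterministic_and_zero_width_ci(self, pop, costs, specs):
        a = expected_scenario(specs[9], pop, costs)
        b = expected_scenario(specs[9], pop, costs)
        assert a.mean_total_cost == b.mean_total_cost
        assert a.ce_ratio_ci == (a.ce_ratio, a.ce_ratio)
        assert a.n_reps == 0


class TestCurrentScreening:
    def test_fp_fraction_converges_to_published_rate(self, costs):
        pop = PopulationParams(cohort_size=50_000)
        res = simulate_current(pop, costs, n_reps=5, seed=8)
        fp_frac = res.mean_fp / res.mean_screened
        se = np.sqrt(0.165 * 0.835 / (5 * res.mean_screened))
        assert fp_frac == pytest.approx(0.165, abs=3 * se)

    def test_referred_children_mostly_refuted(self, costs, pop):
        # of referred children (FP + TP), the healthy share is about 85%
        res = expected_current(pop, costs)
        refuted = res.mean_fp / (res.mean_fp + res.mean_detected)
        assert refuted == pytest.approx(0.165 / 0.193, abs=1e-12)

    def test_degenerate_comparator_raises(self, pop, costs):
        with pytest.raises(DegenerateParametersError):
            simulate_current(
                pop, costs, n_reps=2, seed=0,
                comparator=ComparatorParams(missed_rate=0.01, fp_rate=0.0, tp_rate=0.0),
            )
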