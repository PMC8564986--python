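"""Markov engine: matrices, cohort traces, discounting, life-years."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screencea import (build_transition_matrix, deaths_averted, discounted_sum,
                       life_years_gained, run_cohort)
from screencea.config import AgeGroupParams, DiscountRates, StageTransitionRates
from screencea.markov import CANCER_DEATH, InfeasibleMatrixError
from screencea.synthetic import ScenarioSampler, random_scenario


class TestBuildTransitionMatrix:
    def test_stage_one_remission_row(self):
        rates = StageTransitionRates(stage_group="I", age_group="40-49",
                                     p_rem_to_local=0.01, p_rem_to_dist=0.000016,
                                     p_local_to_dist=0.062, p_local_to_death=0.013,
                                     p_dist_to_death=0.555)
        P = build_transition_matrix(rates).matrix
        assert P[0] == pytest.approx([0.989984, 0.01, 0.000016, 0, 0])

    def test_stage_four_distant_row(self):
        rates = StageTransitionRates(stage_group="IV", age_group="50-59",
                                     p_dist_to_death=0.423)
        P = build_transition_matrix(rates).matrix
        assert P[2] == pytest.approx([0, 0, 0.577, 0.423, 0])

    def test_death_rows_absorbing(self):
        rates = StageTransitionRates(stage_group="I", age_group="x",
                                     p_rem_to_local=0.3)
        P = build_transition_matrix(rates, other_cause_mortality=0.1).matrix
        assert P[3] == pytest.approx([0, 0, 0, 1, 0])
        assert P[4] == pytest.approx([0, 0, 0, 0, 1])

    def test_infeasible_row_rejected(self):
        rates = StageTransitionRates(stage_group="I", age_group="x",
                                     p_rem_to_local=0.6, p_rem_to_dist=0.5)
        with pytest.raises(InfeasibleMatrixError, match="remission"):
            build_transition_matrix(rates)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_row_stochastic_and_progression_only(self, data):
        """Every feasible matrix is row-stochastic and never returns to remission."""
        probs = [data.draw(st.floats(0, 0.3)) for _ in range(5)]
        rates = StageTransitionRates(stage_group="II_III", age_group="x",
                                     p_rem_to_local=probs[0], p_rem_to_dist=probs[1],
                                     p_local_to_dist=probs[2], p_local_to_death=probs[3],
                                     p_dist_to_death=probs[4])
        m = data.draw(st.floats(0, 0.3))  # every row stays feasible: 0.3+0.3+0.3 < 1
        P = build_transition_matrix(rates, other_cause_mortality=m).matrix
        assert P.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-12)
        assert np.all((P >= 0) & (P <= 1))
        assert P[1, 0] == P[2, 0] == P[2, 1] == 0.0


class TestRunCohort:
    def test_no_disease_only_screening_and_workup_costs(self, baseline):
        cfg = baseline.model_copy(deep=True)
        cfg.horizon_cycles = 1
        cfg.age_groups["40-49"].annual_incidence = 0.0
        trace = run_cohort(cfg, "screened", "40-49")
        assert np.all(trace.occupancy == 0)
        c = trace.cost_stream[0]
        assert c.treatment == 0.0
        # false positives still get confirmatory FNAC: 100,000 x (1-0.859) x 22
        assert c.diagnostics == pytest.approx(100_000 * 0.141 * 22)
        assert c.screening == pytest.approx(100_000 * 4.5)

    def test_identity_transitions_no_deaths(self, toy):
        cfg = toy.model_copy(deep=True)
        for t in cfg.transitions:
            t.p_rem_to_dist = t.p_dist_to_death = 0.0
        trace = run_cohort(cfg, "screened", "toy")
        assert np.all(trace.deaths_cancer_cum == 0)

    def test_mass_conservation_per_stage_cohort(self, baseline):
        trace = run_cohort(baseline, "screened", "40-49")
        for t in range(trace.horizon):
            occupied = trace.occupancy[t].sum(axis=1)
            assert occupied == pytest.approx(trace.enrolled_cum[t], rel=1e-9)

    def test_deaths_cumulative_nondecreasing(self, baseline):
        for arm in ("screened", "non_screened"):
            trace = run_cohort(baseline, arm, "50-59")
            assert np.all(np.diff(trace.deaths_cancer_cum) >= -1e-12)

    def test_death_probability_monotonicity(self, baseline):
        """Raising a ->death probability never decreases cumulative deaths."""
        base_deaths = run_cohort(baseline, "non_screened", "40-49").cumulative_cancer_deaths
        bumped = baseline.model_copy(deep=True)
        bumped.transition("II_III", "40-49").p_dist_to_death = 0.5
        assert run_cohort(bumped, "non_screened", "40-49").cumulative_cancer_deaths \
            >= base_deaths

    def test_perfect_sensitivity_no_clinical_presenters(self, baseline):
        cfg = baseline.model_copy(deep=True)
        cfg.age_groups["40-49"].sensitivity = 1.0
        trace = run_cohort(cfg, "screened", "40-49")
        assert all(d.false_negatives == 0 for d in trace.detections)

    def test_at_risk_pool_depletion_flag(self, baseline):
        fixed = baseline.model_copy(update={"deplete_at_risk_pool": False})
        t_dep = run_cohort(baseline, "screened", "40-49")
        t_fix = run_cohort(fixed, "screened", "40-49")
        assert np.all(t_fix.at_risk == 100_000)
        assert t_fix.at_risk[-1] > t_dep.at_risk[-1]


class TestDiscountedSum:
    def test_annuity_closed_form(self):
        """10 x 1,050,000 at 5%, paid at cycle start, matches the annuity factor."""
        stream = [1_050_000] * 10
        factor = (1 - 1.05 ** -10) / 0.05 * 1.05
        assert discounted_sum(stream, 0.05) == pytest.approx(1_050_000 * factor)

    def test_zero_rate_plain_sum(self):
        assert discounted_sum([1, 2, 3], 0.0) == 6.0

    def test_single_payment_at_cycle_start_undiscounted(self):
        assert discounted_sum([123.4], 0.05, "begin_of_cycle") == 123.4

    def test_end_of_cycle_shifts_one_period(self):
        assert discounted_sum([100], 0.05, "end_of_cycle") == pytest.approx(100 / 1.05)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=30),
           st.floats(0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_discounting_bounds(self, stream, rate):
        """Discounted <= undiscounted for non-negative streams; equal iff rate 0."""
        d = discounted_sum(stream, rate)
        # allow last-ulp summation-order differences at rate 0
        assert d <= sum(stream) * (1 + 1e-12) + 1e-9
        if rate == 0:
            assert d == pytest.approx(sum(stream))


class TestDeathsAverted:
    def test_identical_traces_zero(self, baseline):
        t = run_cohort(baseline, "non_screened", "40-49")
        assert deaths_averted(t, t) == 0.0

    def test_definition(self, baseline):
        ts = run_cohort(baseline, "screened", "40-49")
        tn = run_cohort(baseline, "non_screened", "40-49")
        expected = tn.cumulative_cancer_deaths - ts.cumulative_cancer_deaths
        assert deaths_averted(ts, tn) == pytest.approx(expected)
        assert deaths_averted(ts, tn) > 0

    def test_mismatched_horizons_rejected(self, baseline):
        short = baseline.model_copy(update={"horizon_cycles": 5})
        with pytest.raises(ValueError, match="horizon"):
            deaths_averted(run_cohort(short, "screened", "40-49"),
                           run_cohort(baseline, "non_screened", "40-49"))


class TestLifeYearsGained:
    AG = AgeGroupParams(label="40-49", annual_incidence=0.000878,
                        remaining_life_years={"40-44": 36.10367697,
                                              "45-49": 31.72113989},
                        lyg_per_death_averted=31.3958)
    DISC = DiscountRates()

    def test_zero_deaths_zero_lyg(self):
        for mode in ("calibrated_multiplier", "life_table"):
            assert life_years_gained(0.0, self.AG, self.DISC, mode) == 0.0

    def test_calibrated_multiplier(self):
        assert life_years_gained(78.55, self.AG, self.DISC) == \
            pytest.approx(2466.14, rel=1e-4)

    def test_life_table_one_year_zero_rate(self):
        ag = AgeGroupParams(label="x", annual_incidence=0.0,
                            remaining_life_years={"x": 1.0})
        disc = DiscountRates(cost_rate=0.0, effect_rate=0.0)
        assert life_years_gained(10.0, ag, disc, "life_table") == pytest.approx(10.0)

    def test_life_table_discounts_below_undiscounted(self):
        lt = life_years_gained(10.0, self.AG, self.DISC, "life_table")
        L = (36.10367697 + 31.72113989) / 2
        assert 0 < lt < 10.0 * L

    def test_missing_multiplier_rejected(self):
        ag = AgeGroupParams(label="x", annual_incidence=0.0)
        with pytest.raises(ValueError, match="multiplier"):
            life_years_gained(1.0, ag, self.DISC, "calibrated_multiplier")
        with pytest.raises(ValueError, match="life_table"):
            life_years_gained(1.0, ag, self.DISC, "life_table")


class TestRandomScenarioInvariants:
    def test_matrices_row_stochastic_across_scenarios(self, sampler):
        for k in range(10):
            cfg = random_scenario(sampler, k)
            for t in cfg.transitions:
                P = build_transition_matrix(t, cfg.other_cause_mortality).matrix
                assert P.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-12)

    def test_mass_conservation_across_scenarios(self, sampler):
        for k in range(5):
            cfg = random_scenario(sampler, 100 + k)
            trace = run_cohort(cfg, "screened", "50-59")
            for t in range(trace.horizon):
                assert trace.occupancy[t].sum(axis=1) == \
                    pytest.approx(trace.enrolled_cum[t], rel=1e-9, abs=1e-9)
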