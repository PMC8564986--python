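"""ICER/INMB arithmetic, policy blending and the verdict rule."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screencea import (DOMINANT, DOMINATED, UNDEFINED, Policy, blend_policies,
                       classify, death_aversion_metrics, evaluate_policy, icer,
                       inmb, policy_table, results_frame)


class TestIcer:
    def test_published_government_ratio(self):
        assert icer(8_656_833, 2466.14) == pytest.approx(3510.28, rel=1e-4)

    def test_published_private_ratio(self):
        assert icer(38_585_063, 2566.93) == pytest.approx(15_031.6, rel=1e-4)

    def test_zero_cost_positive_effect(self):
        assert icer(0.0, 10.0) == 0.0

    @pytest.mark.parametrize("cost,effect,flag", [
        (-100.0, 10.0, DOMINANT),
        (100.0, 0.0, DOMINATED),
        (100.0, -10.0, DOMINATED),
        (0.0, 0.0, UNDEFINED),
    ])
    def test_quadrant_flags(self, cost, effect, flag):
        assert icer(cost, effect) == flag


class TestInmb:
    def test_published_fifty_to_fiftynine_value(self):
        assert inmb(2808.5, 2566.93, 8_278_038) == pytest.approx(-1_068_815.1, rel=1e-6)

    def test_zero_wtp_is_negative_cost(self):
        assert inmb(0.0, 100.0, 500.0) == -500.0

    def test_zero_everything(self):
        assert inmb(2808.5, 0.0, 0.0) == 0.0

    @given(wtp=st.floats(1, 1e5), effect=st.floats(0.1, 1e4), cost=st.floats(0, 1e8))
    @settings(max_examples=100, deadline=None)
    def test_sign_change_exactly_at_wtp_equal_icer(self, wtp, effect, cost):
        from hypothesis import assume

        ratio = icer(cost, effect)
        value = inmb(wtp, effect, cost)
        assume(abs(wtp - ratio) * effect > 1e-6)  # away from the knife edge
        assert (value > 0) == (wtp > ratio)

    def test_zero_at_wtp_equal_icer(self):
        assert inmb(50.0, 10.0, 500.0) == pytest.approx(0.0, abs=1e-9)


class TestDeathAversionMetrics:
    def test_published_government_forty_to_fortynine(self):
        cpda, nspda = death_aversion_metrics(100_000, 78.55, 8_656_833)
        assert cpda == pytest.approx(110_208.6, rel=1e-4)
        assert nspda == pytest.approx(1273.07, rel=1e-4)

    def test_no_deaths_averted_flags(self):
        cpda, nspda = death_aversion_metrics(100_000, 0.0, 1000.0)
        assert math.isnan(cpda) and math.isnan(nspda)

    def test_exact_arithmetic(self):
        assert death_aversion_metrics(100, 10, 1000) == (100.0, 10.0)


class TestClassify:
    def test_above_threshold_not_cost_effective(self):
        assert classify(3510.275, 2808.5) == "not_cost_effective"

    def test_strict_inequality_at_threshold(self):
        assert classify(2808.5, 2808.5) == "not_cost_effective"
        assert classify(0.0, 2808.5) == "cost_effective"

    def test_flags(self):
        assert classify(DOMINANT, 100) == "cost_effective"
        assert classify(DOMINATED, 100) == "not_cost_effective"

    @given(icer_value=st.floats(0, 1e5), wtp_lo=st.floats(1, 1e5),
           wtp_hi=st.floats(1, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_wtp(self, icer_value, wtp_lo, wtp_hi):
        """Raising the threshold never flips cost-effective to not."""
        lo, hi = sorted((wtp_lo, wtp_hi))
        if classify(icer_value, lo) == "cost_effective":
            assert classify(icer_value, hi) == "cost_effective"


class TestBlendPolicies:
    def test_ninety_ten_blend_reproduces_published_icer(self, baseline, model):
        gov = model.evaluate(Policy(name="government", private_share=0.0), "40-49")
        priv = model.evaluate(Policy(name="private", private_share=1.0), "40-49")
        mixed = blend_policies(gov, priv, 0.1)
        expected = 0.9 * gov.incremental_cost + 0.1 * priv.incremental_cost
        assert mixed.incremental_cost == pytest.approx(expected)
        assert mixed.lyg == gov.lyg

    @pytest.mark.parametrize("share,attr", [(0.0, "gov"), (1.0, "priv")])
    def test_degenerate_shares(self, model, share, attr):
        gov = model.evaluate(Policy(name="government", private_share=0.0), "50-59")
        priv = model.evaluate(Policy(name="private", private_share=1.0), "50-59")
        blended = blend_policies(gov, priv, share)
        ref = {"gov": gov, "priv": priv}[attr]
        assert blended.incremental_cost == pytest.approx(ref.incremental_cost)
        assert blended.icer == pytest.approx(ref.icer)

    def test_blend_affine_in_share(self, model):
        """Blended cost and ICER are affine in the private share (fixed LYG)."""
        gov = model.evaluate(Policy(name="government", private_share=0.0), "40-49")
        priv = model.evaluate(Policy(name="private", private_share=1.0), "40-49")
        shares = [0.0, 0.25, 0.5, 0.75, 1.0]
        costs = [blend_policies(gov, priv, s).incremental_cost for s in shares]
        icers = [blend_policies(gov, priv, s).icer for s in shares]
        for seq in (costs, icers):
            diffs = [b - a for a, b in zip(seq, seq[1:])]
            assert diffs == pytest.approx([diffs[0]] * len(diffs))

    def test_mismatched_age_groups_rejected(self, model):
        gov = model.evaluate(Policy(name="government", private_share=0.0), "40-49")
        priv = model.evaluate(Policy(name="private", private_share=1.0), "50-59")
        with pytest.raises(ValueError, match="age group"):
            blend_policies(gov, priv, 0.5)


class TestPolicyTable:
    def test_eight_rows_two_age_bands(self, baseline):
        results = policy_table(baseline)
        assert len(results) == 8
        assert {r.age_group for r in results} == {"40-49", "50-59"}
        assert len({(r.policy.name, r.age_group) for r in results}) == 8

    def test_equal_prices_collapse_policies(self, baseline):
        cfg = baseline.model_copy(deep=True)
        cfg.costs.mammography_private = cfg.costs.mammography_gov
        results = policy_table(cfg)
        for age in ("40-49", "50-59"):
            icers = {r.icer for r in results if r.age_group == age}
            assert len(icers) == 1

    def test_icer_nondecreasing_in_private_share(self, sampler):
        """Dearer private screening can only raise the ICER (property across
        random scenarios)."""
        from screencea.synthetic import random_scenario

        for k in range(3):
            cfg = random_scenario(sampler, 200 + k)
            if cfg.costs.mammography_private < cfg.costs.mammography_gov:
                cfg.costs.mammography_gov, cfg.costs.mammography_private = \
                    cfg.costs.mammography_private, cfg.costs.mammography_gov
            results = policy_table(cfg, age_groups=["40-49"])
            by_share = sorted(results, key=lambda r: r.policy.private_share)
            icers = [r.icer for r in by_share if isinstance(r.icer, float)]
            assert icers == sorted(icers)

    def test_icer_times_lyg_recovers_cost(self, baseline):
        for r in policy_table(baseline):
            assert r.icer * r.lyg == pytest.approx(r.incremental_cost, rel=1e-9)

    def test_export_schema(self, baseline):
        frame = results_frame(policy_table(baseline))
        assert list(frame.columns) == [
            "policy", "age_group", "incremental_cost_usd", "lyg",
            "icer_usd_per_lyg", "inmb_usd", "cost_per_death_averted_usd",
            "number_screened_per_death_averted", "verdict",
        ]

    def test_baseline_verdicts_not_cost_effective(self, baseline):
        assert all(r.verdict == "not_cost_effective" for r in policy_table(baseline))
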