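"""Cost-effectiveness metrics: ICER, INMB, death-aversion ratios, policy blends.

The comparator is "no screening"; incremental cost is the screened arm's
discounted total minus the non-screened arm's.  Because the mammography
price does not affect health outcomes, intermediate provider-mix policies
are computed by blending the costs of the two pure-price runs — the blend is
algebraically identical to re-running with a blended unit price.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .config import STAGES, Policy, ScenarioConfig
from .markov import CohortTrace, deaths_averted, discounted_sum, life_years_gained, run_cohort

__all__ = [
    "DOMINANT", "DOMINATED", "UNDEFINED", "ArmResult", "CEAResult",
    "icer", "inmb", "death_aversion_metrics", "blend_policies", "classify",
    "evaluate_policy", "policy_table", "results_frame",
    "CANONICAL_POLICIES", "arm_result",
]

#: ICER flags for the non-ratio quadrants of the cost-effectiveness plane.
DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and no more effective
UNDEFINED = "undefined"    # no cost and no effect difference

ICERValue = Union[float, str]

#: The four provider-mix policies analysed in the baseline study.
CANONICAL_POLICIES = (
    Policy(name="government", private_share=0.0),
    Policy(name="ninety_ten", private_share=0.1),
    Policy(name="fifty_fifty", private_share=0.5),
    Policy(name="private", private_share=1.0),
)

_EPS = 1e-12


@dataclass
class ArmResult:
    """Discounted totals for one arm of one age band."""

    arm: str
    age_group: str
    total_cost_discounted: float
    cancer_deaths: float
    diagnoses_by_stage: dict[str, float]
    cost_components: dict[str, float]
    trace: Optional[CohortTrace] = None


@dataclass
class CEAResult:
    """One row of the policy table."""

    policy: Policy
    age_group: str
    incremental_cost: float
    lyg: float
    deaths_averted: float
    icer: ICERValue
    inmb: float
    cost_per_death_averted: float
    number_screened_per_death_averted: float
    verdict: str
    wtp: float
    cohort_size: float
    arm_results: dict[str, ArmResult] = field(default_factory=dict)


def icer(incremental_cost: float, incremental_effect: float) -> ICERValue:
    """Incremental cost-effectiveness ratio, or a dominance flag.

    Returns USD per life-year when the ratio is meaningful; ``DOMINANT`` when
    the intervention saves money and health, ``DOMINATED`` when it costs
    money for no (or negative) health gain, ``UNDEFINED`` when both
    differences are ~0.
    """
    if abs(incremental_cost) < _EPS and abs(incremental_effect) < _EPS:
        return UNDEFINED
    if incremental_effect > 0:
        return DOMINANT if incremental_cost < 0 else incremental_cost / incremental_effect
    # incremental_effect <= 0
    if incremental_cost > 0:
        return DOMINATED
    if incremental_effect < 0:
        return incremental_cost / incremental_effect  # south-west quadrant
    return DOMINATED


def inmb(wtp: float, incremental_effect: float, incremental_cost: float) -> float:
    """Incremental net monetary benefit: wtp x dE − dC."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * incremental_effect - incremental_cost


def death_aversion_metrics(
    cohort_size: float, deaths_averted_value: float, incremental_cost: float
) -> tuple[float, float]:
    """(cost per death averted, number screened per death averted).

    Both are NaN flags when no deaths are averted.
    """
    if cohort_size <= 0:
        raise ValueError(f"cohort_size must be positive, got {cohort_size}")
    if deaths_averted_value <= 0:
        return (math.nan, math.nan)
    return (incremental_cost / deaths_averted_value, cohort_size / deaths_averted_value)


def classify(icer_value: ICERValue, wtp: float) -> str:
    """WTP verdict: strict inequality, ICER < wtp is cost-effective."""
    if wtp <= 0:
        raise ValueError(f"wtp must be positive, got {wtp}")
    if icer_value == DOMINANT:
        return "cost_effective"
    if icer_value in (DOMINATED, UNDEFINED):
        return "not_cost_effective"
    return "cost_effective" if icer_value < wtp else "not_cost_effective"


def arm_result(
    config: ScenarioConfig,
    arm: str,
    age_group: str,
    mammography_unit_cost: Optional[float] = None,
) -> ArmResult:
    """Run one arm and discount its cost stream."""
    trace = run_cohort(config, arm, age_group, mammography_unit_cost)
    rate, timing = config.discounts.cost_rate, config.discount_timing
    components = {
        name: discounted_sum([getattr(c, name) for c in trace.cost_stream], rate, timing)
        for name in ("screening", "doctor_visits", "diagnostics", "treatment")
    }
    return ArmResult(
        arm=arm,
        age_group=age_group,
        total_cost_discounted=sum(components.values()),
        cancer_deaths=trace.cumulative_cancer_deaths,
        diagnoses_by_stage=trace.total_diagnoses_by_stage(),
        cost_components=components,
        trace=trace,
    )


def _assemble(
    policy: Policy,
    age_group: str,
    incremental_cost: float,
    lyg: float,
    da: float,
    wtp: float,
    cohort_size: float,
    arm_results: Optional[dict[str, ArmResult]] = None,
) -> CEAResult:
    icer_value = icer(incremental_cost, lyg)
    cpda, nspda = death_aversion_metrics(cohort_size, da, incremental_cost)
    if icer_value in (DOMINANT, DOMINATED):
        verdict = icer_value
    else:
        verdict = classify(icer_value, wtp)
    return CEAResult(
        policy=policy, age_group=age_group, incremental_cost=incremental_cost,
        lyg=lyg, deaths_averted=da, icer=icer_value,
        inmb=inmb(wtp, lyg, incremental_cost),
        cost_per_death_averted=cpda, number_screened_per_death_averted=nspda,
        verdict=verdict, wtp=wtp, cohort_size=cohort_size,
        arm_results=arm_results or {},
    )


def evaluate_policy(
    config: ScenarioConfig,
    policy: Policy,
    age_group: str,
    _non_screened: Optional[ArmResult] = None,
) -> CEAResult:
    """Full pipeline for one policy × age band.

    Pure policies run the screened arm at the corresponding unit price;
    intermediate shares blend the two pure runs (see :func:`blend_policies`).
    """
    if not 0.0 <= policy.private_share <= 1.0:
        raise ValueError(f"private_share {policy.private_share} not in [0, 1]")
    if policy.private_share in (0.0, 1.0):
        unit = (config.costs.mammography_gov if policy.private_share == 0.0
                else config.costs.mammography_private)
        screened = arm_result(config, "screened", age_group, unit)
        non_screened = _non_screened or arm_result(config, "non_screened", age_group)
        da = deaths_averted(screened.trace, non_screened.trace)
        lyg = life_years_gained(max(da, 0.0), config.age_groups[age_group],
                                config.discounts, config.lyg_mode)
        if da < 0:  # screening harmful: count negative effect directly
            lyg = -life_years_gained(-da, config.age_groups[age_group],
                                     config.discounts, config.lyg_mode)
        return _assemble(
            policy, age_group,
            screened.total_cost_discounted - non_screened.total_cost_discounted,
            lyg, da, config.wtp_threshold, config.cohort_size,
            {"screened": screened, "non_screened": non_screened},
        )
    non_screened = _non_screened or arm_result(config, "non_screened", age_group)
    gov = evaluate_policy(config, Policy(name="government", private_share=0.0),
                          age_group, non_screened)
    priv = evaluate_policy(config, Policy(name="private", private_share=1.0),
                           age_group, non_screened)
    return blend_policies(gov, priv, policy.private_share, name=policy.name)


def blend_policies(
    result_gov: CEAResult,
    result_private: CEAResult,
    private_share: float,
    name: Optional[str] = None,
) -> CEAResult:
    """Mix the two pure-price results for a provider share in [0, 1].

    Cost is blended linearly; life-years gained and deaths averted are
    price-independent and must agree between the inputs.  All ratios are
    recomputed from the blended cost.
    """
    if not 0.0 <= private_share <= 1.0:
        raise ValueError(f"private_share {private_share} not in [0, 1]")
    if result_gov.age_group != result_private.age_group:
        raise ValueError("cannot blend results for different age groups")
    if not math.isclose(result_gov.lyg, result_private.lyg, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("pure-policy results disagree on life-years gained; "
                         "they were not computed from the same scenario")
    cost = ((1.0 - private_share) * result_gov.incremental_cost
            + private_share * result_private.incremental_cost)
    return _assemble(
        Policy(name=name or f"private_share_{private_share:g}",
               private_share=private_share),
        result_gov.age_group, cost, result_gov.lyg, result_gov.deaths_averted,
        result_gov.wtp, result_gov.cohort_size,
    )


def policy_table(
    config: ScenarioConfig,
    policies: Sequence[Policy] = CANONICAL_POLICIES,
    age_groups: Sequence[str] = ("40-49", "50-59"),
) -> list[CEAResult]:
    """One CEAResult per policy × age band (the headline results table)."""
    out: list[CEAResult] = []
    for age_group in age_groups:
        non_screened = arm_result(config, "non_screened", age_group)
        gov = evaluate_policy(config, Policy(name="government", private_share=0.0),
                              age_group, non_screened)
        priv = evaluate_policy(config, Policy(name="private", private_share=1.0),
                               age_group, non_screened)
        for policy in policies:
            if policy.private_share == 0.0:
                r = _assemble(policy, age_group, gov.incremental_cost, gov.lyg,
                              gov.deaths_averted, gov.wtp, gov.cohort_size,
                              gov.arm_results)
            elif policy.private_share == 1.0:
                r = _assemble(policy, age_group, priv.incremental_cost, priv.lyg,
                              priv.deaths_averted, priv.wtp, priv.cohort_size,
                              priv.arm_results)
            else:
                r = blend_policies(gov, priv, policy.private_share, name=policy.name)
            out.append(r)
    return out


def results_frame(results: Sequence[CEAResult]):
    """Tidy table of CEA results with the stable export column set."""
    import pandas as pd

    return pd.DataFrame([
        {
            "policy": r.policy.name,
            "age_group": r.age_group,
            "incremental_cost_usd": r.incremental_cost,
            "lyg": r.lyg,
            "icer_usd_per_lyg": r.icer if isinstance(r.icer, float) else math.nan,
            "inmb_usd": r.inmb,
            "cost_per_death_averted_usd": r.cost_per_death_averted,
            "number_screened_per_death_averted": r.number_screened_per_death_averted,
            "verdict": r.verdict,
        }
        for r in results
    ])
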