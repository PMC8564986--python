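"""Synthetic scenarios and an individual-level microsimulation oracle.

The :class:`ScenarioSampler` draws random valid scenarios around the
packaged baseline for property tests.  :func:`microsim_cohort` simulates
individual women through the same decision tree and Markov chain with
Bernoulli/categorical draws: its empirical aggregates converge to the
cohort engine's expected values, so disagreement beyond Monte Carlo noise
isolates an engine bug rather than a modelling difference.  Random streams
are split per cycle and per decision point with counter-style seed
sequences, so results do not depend on loop order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (STAGES, AgeGroupParams, CostSchedule, DiscountRates, Policy,
                     ScenarioConfig, StageDistribution, StageTransitionRates,
                     stage_to_group, validate_scenario)
from .markov import CANCER_DEATH, ENTRY_STATE, build_transition_matrix

__all__ = ["ScenarioSampler", "MicrosimResult", "random_scenario",
           "microsim_cohort", "toy_fixture", "oracle_z_scores"]


@dataclass
class ScenarioSampler:
    """Random valid scenarios: baseline values scaled by U(lo, hi).

    Probabilities are truncated to [0, 1]; stage distributions are rescaled
    back onto the simplex; infeasible transition rows are rejection-sampled.
    """

    seed: int
    scale_range: tuple[float, float] = (0.5, 1.5)
    base: ScenarioConfig | None = None
    max_retries: int = 100

    def __post_init__(self):
        if self.base is None:
            from .config import baseline_scenario

            self.base = baseline_scenario()


def _scaled_prob(rng, base: float, lo: float, hi: float) -> float:
    return float(np.clip(base * rng.uniform(lo, hi), 0.0, 1.0))


def random_scenario(sampler: ScenarioSampler, draw_index: int) -> ScenarioConfig:
    """Draw one valid scenario; deterministic given (seed, draw_index)."""
    lo, hi = sampler.scale_range
    base = sampler.base
    for attempt in range(sampler.max_retries):
        rng = np.random.default_rng([sampler.seed, draw_index, attempt])
        age_groups = {}
        for label, ag in base.age_groups.items():
            age_groups[label] = AgeGroupParams(
                label=label,
                annual_incidence=_scaled_prob(rng, ag.annual_incidence, lo, hi),
                sensitivity=_scaled_prob(rng, ag.sensitivity, lo, hi),
                specificity=_scaled_prob(rng, ag.specificity, lo, hi),
                remaining_life_years={
                    k: v * rng.uniform(lo, hi) for k, v in ag.remaining_life_years.items()
                },
                lyg_per_death_averted=(None if ag.lyg_per_death_averted is None
                                       else ag.lyg_per_death_averted * rng.uniform(lo, hi)),
            )
        transitions = [
            StageTransitionRates(
                stage_group=t.stage_group, age_group=t.age_group,
                p_rem_to_local=_scaled_prob(rng, t.p_rem_to_local, lo, hi),
                p_rem_to_dist=_scaled_prob(rng, t.p_rem_to_dist, lo, hi),
                p_local_to_dist=_scaled_prob(rng, t.p_local_to_dist, lo, hi),
                p_local_to_death=_scaled_prob(rng, t.p_local_to_death, lo, hi),
                p_dist_to_death=_scaled_prob(rng, t.p_dist_to_death, lo, hi),
            )
            for t in base.transitions
        ]
        dists = {}
        for arm, d in base.stage_distributions.items():
            w = np.array(d.p_stage) * rng.uniform(lo, hi, size=len(STAGES))
            w = w / w.sum()
            dists[arm] = StageDistribution(arm=d.arm, p_stage=tuple(float(x) for x in w))
        costs = CostSchedule(
            mammography_gov=base.costs.mammography_gov * rng.uniform(lo, hi),
            mammography_private=base.costs.mammography_private * rng.uniform(lo, hi),
            doctor_visit=base.costs.doctor_visit * rng.uniform(lo, hi),
            fnac=base.costs.fnac * rng.uniform(lo, hi),
            treatment_by_stage={s: c * rng.uniform(lo, hi)
                                for s, c in base.costs.treatment_by_stage.items()},
        )
        config = base.model_copy(update=dict(
            age_groups=age_groups, transitions=transitions,
            stage_distributions=dists, costs=costs,
        ))
        if not validate_scenario(config):
            return config
    raise RuntimeError(
        f"could not draw a feasible scenario after {sampler.max_retries} attempts"
    )


@dataclass
class MicrosimResult:
    """Empirical aggregates from an individual-level simulation.

    Counts are raw (per ``n_individuals``); ``scale`` converts to the
    scenario's cohort size.  Standard errors are on the scaled quantities.
    """

    n_individuals: int
    cohort_size: float
    #: integer occupancy counts, shape (horizon, 4 stages, 5 states)
    occupancy_counts: np.ndarray
    deaths_cancer_cum: np.ndarray
    total_cost_undiscounted: float
    se_cost: float
    diagnoses_total: float = 0.0

    @property
    def scale(self) -> float:
        return self.cohort_size / self.n_individuals

    def occupancy_scaled(self) -> np.ndarray:
        return self.occupancy_counts * self.scale

    def occupancy_se(self) -> np.ndarray:
        p = self.occupancy_counts / self.n_individuals
        return self.scale * np.sqrt(self.n_individuals * p * (1.0 - p))

    def deaths_scaled(self) -> np.ndarray:
        return self.deaths_cancer_cum * self.scale

    def deaths_se(self) -> np.ndarray:
        p = self.deaths_cancer_cum / self.n_individuals
        return self.scale * np.sqrt(self.n_individuals * p * (1.0 - p))


def microsim_cohort(
    config: ScenarioConfig,
    arm: str,
    age_group: str,
    n_individuals: int,
    seed: int,
    mammography_unit_cost: float | None = None,
) -> MicrosimResult:
    """Simulate individual women through screening/diagnosis and progression.

    Applies the same stage distributions, one-time costing rules and cycle
    ordering (enrol, then transition, then record) as the cohort engine.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if arm not in ("screened", "non_screened"):
        raise ValueError(f"unknown arm {arm!r}")
    ag = config.age_groups[age_group]
    if mammography_unit_cost is None:
        mammography_unit_cost = config.mammography_unit_cost()
    matrices = np.stack([
        build_transition_matrix(config.transition(stage_to_group(s), age_group),
                                config.other_cause_mortality).matrix
        for s in STAGES
    ])
    screened_w = np.array(config.stage_distributions["screened"].p_stage)
    clinical_w = np.array(config.stage_distributions["non_screened"].p_stage)
    costs = config.costs
    treat = np.array([costs.treatment_by_stage[s] for s in STAGES])
    entry = np.array([ENTRY_STATE[s] for s in STAGES])

    n = n_individuals
    T = config.horizon_cycles
    at_risk = np.ones(n, dtype=bool)
    state = np.full(n, -1, dtype=np.int64)   # -1 = not yet diagnosed
    stage = np.full(n, -1, dtype=np.int64)
    cost_i = np.zeros(n)

    occupancy = np.zeros((T, 4, 5), dtype=np.int64)
    deaths_cum = np.zeros(T)
    diagnoses = 0

    for t in range(T):
        rng = np.random.default_rng([seed, t])
        u_cancer = rng.random(n)
        u_test = rng.random(n)
        u_stage = rng.random(n)
        u_trans = rng.random(n)
        u_part = rng.random(n)

        cancer = at_risk & (u_cancer < ag.annual_incidence)
        if arm == "screened":
            participates = at_risk & (u_part < config.participation_rate)
            tp = cancer & participates & (u_test < ag.sensitivity)
            fn = cancer & ~tp
            fp = participates & ~cancer & (u_test >= ag.specificity)
            # screening encounter costs
            cost_i[participates] += mammography_unit_cost
            if config.doctor_visit_attachment == "per_screen":
                cost_i[participates] += costs.doctor_visit
            else:
                cost_i[tp | fp] += costs.doctor_visit
            cost_i[tp] += costs.fnac
            if config.include_false_positive_workup:
                cost_i[fp] += costs.fnac
        else:
            tp = np.zeros(n, dtype=bool)
            fn = cancer
            cost_i[cancer] += costs.doctor_visit + costs.fnac

        # stage at diagnosis by detection mode
        stage[tp] = np.searchsorted(np.cumsum(screened_w), u_stage[tp], side="right")
        stage[fn] = np.searchsorted(np.cumsum(clinical_w), u_stage[fn], side="right")
        stage[cancer] = np.clip(stage[cancer], 0, 3)
        cost_i[cancer] += treat[stage[cancer]]
        state[cancer] = entry[stage[cancer]]
        at_risk &= ~cancer
        diagnoses += int(cancer.sum())

        # advance every diagnosed woman by one transition
        diag = state >= 0
        if diag.any():
            rows = matrices[stage[diag], state[diag]]   # (k, 5)
            cum = np.cumsum(rows, axis=1)
            # next state = number of cumulative masses <= u, clipped for
            # floating rounding at the top of the distribution
            state[diag] = np.minimum((u_trans[diag, None] >= cum).sum(axis=1), 4)
            idx_stage = stage[diag]
            idx_state = state[diag]
            np.add.at(occupancy[t], (idx_stage, idx_state), 1)
        deaths_cum[t] = np.count_nonzero(state == CANCER_DEATH)

    scale = config.cohort_size / n
    total_cost = float(cost_i.sum()) * scale
    se_cost = float(cost_i.std(ddof=1)) * np.sqrt(n) * scale if n > 1 else 0.0
    return MicrosimResult(
        n_individuals=n, cohort_size=config.cohort_size,
        occupancy_counts=occupancy, deaths_cancer_cum=deaths_cum,
        total_cost_undiscounted=total_cost, se_cost=se_cost,
        diagnoses_total=diagnoses * scale,
    )


def oracle_z_scores(ms: MicrosimResult, trace) -> dict[str, float]:
    """Standardised deviations of the microsim from the cohort expectation.

    Binomial standard errors are evaluated under the null hypothesis (the
    cohort engine's expected proportions), which stays calibrated for
    rare-event cells where the empirical proportion may be zero; the cost
    comparison uses the empirical Monte Carlo standard error.  Occupancy is
    compared per state at the final cycle, aggregated over stage cohorts.
    A cell that is structurally empty in the cohort model must be empty in
    the microsim (z forced to inf otherwise).
    """
    n, scale = ms.n_individuals, ms.scale

    def z_binom(observed_scaled: float, expected_scaled: float) -> float:
        p = expected_scaled / ms.cohort_size
        se = scale * np.sqrt(n * p * (1.0 - p))
        diff = observed_scaled - expected_scaled
        if se == 0.0:
            return 0.0 if diff == 0.0 else math.inf
        return diff / se

    out = {
        "deaths": z_binom(float(ms.deaths_scaled()[-1]),
                          trace.cumulative_cancer_deaths),
        "cost": ((ms.total_cost_undiscounted - float(trace.cost_totals.sum()))
                 / ms.se_cost if ms.se_cost > 0 else 0.0),
    }
    occ_exp = trace.occupancy[-1].sum(axis=0)
    occ_obs = ms.occupancy_scaled()[-1].sum(axis=0)
    from .markov import STATES

    for j, state in enumerate(STATES):
        out[f"occupancy.{state}"] = z_binom(float(occ_obs[j]), float(occ_exp[j]))
    return out


def toy_fixture() -> ScenarioConfig:
    """A deliberately tiny scenario with closed-form expectations.

    Cohort of 100, incidence 0.1, sensitivity 0.5, perfect specificity, all
    cases stage I, two cycles, no discounting, zero costs.  The stage-I chain
    is remission -> distant recurrence with probability 0.5 per cycle and
    distant recurrence -> cancer death with probability 1.  Closed forms:

    * cycle-0 true positives: 100 x 0.1 x 0.5 = 5
    * a case diagnosed at cycle 0 dies by the end of cycle 1 with
      probability 0.5 x 1 = 0.5; a case diagnosed at cycle 1 cannot die
      within the horizon, so expected deaths = 10 x 0.5 = 5 per arm
    * both arms share one stage distribution, so deaths averted = 0.
    """
    zero_costs = CostSchedule(mammography_gov=0.0, mammography_private=0.0,
                              doctor_visit=0.0, fnac=0.0,
                              treatment_by_stage={s: 0.0 for s in STAGES})
    point_mass = (1.0, 0.0, 0.0, 0.0)
    return ScenarioConfig(
        age_groups={"toy": AgeGroupParams(
            label="toy", annual_incidence=0.1, sensitivity=0.5, specificity=1.0,
            remaining_life_years={"toy": 2.0}, lyg_per_death_averted=1.0,
        )},
        transitions=[
            StageTransitionRates(stage_group="I", age_group="toy",
                                 p_rem_to_dist=0.5, p_dist_to_death=1.0),
            StageTransitionRates(stage_group="II_III", age_group="toy"),
            StageTransitionRates(stage_group="IV", age_group="toy"),
        ],
        stage_distributions={
            "screened": StageDistribution(arm="screened", p_stage=point_mass),
            "non_screened": StageDistribution(arm="non_screened", p_stage=point_mass),
        },
        costs=zero_costs,
        discounts=DiscountRates(cost_rate=0.0, effect_rate=0.0),
        policy=Policy(name="government", private_share=0.0),
        cohort_size=100, horizon_cycles=2, wtp_threshold=100.0,
    )
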