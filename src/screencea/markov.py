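"""Five-state Markov cohort engine, stratified by stage at diagnosis.

Diagnosed women enter a progression-only chain over the states
(remission, local recurrence, distant recurrence, cancer death,
other-cause death).  Stages I–III enter in remission; stage IV enters
directly in distant recurrence.  Stages II and III share one transition-rate
set but are tracked as separate cohorts because their treatment costs
differ.  Each annual cycle the decision tree enrols that cycle's expected
diagnoses and every existing cohort is advanced by one row-stochastic matrix
multiplication; the at-risk pool is depleted by cumulative diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (STAGES, AgeGroupParams, DiscountRates, ScenarioConfig,
                     StageTransitionRates, stage_to_group)
from .decision_tree import (CycleCosts, CycleDetection, allocate_diagnosis_stages,
                            cycle_costs, screening_cycle_outcomes)

__all__ = [
    "STATES", "TransitionMatrix", "CohortTrace", "build_transition_matrix",
    "run_cohort", "discounted_sum", "deaths_averted", "life_years_gained",
]

#: Markov state order used by every 5-vector / 5x5 matrix in the package.
STATES = ("remission", "local_recurrence", "distant_recurrence",
          "cancer_death", "other_death")
REMISSION, LOCAL, DISTANT, CANCER_DEATH, OTHER_DEATH = range(5)
ALIVE = (REMISSION, LOCAL, DISTANT)

#: Initial Markov state by stage at diagnosis.
ENTRY_STATE = {"I": REMISSION, "II": REMISSION, "III": REMISSION, "IV": DISTANT}


class InfeasibleMatrixError(ValueError):
    """Transition rates plus other-cause mortality exceed 1 in some row."""


@dataclass
class TransitionMatrix:
    stage_group: str
    age_group: str
    matrix: np.ndarray  # 5x5, row-stochastic


@dataclass
class CohortTrace:
    """Per-cycle expected occupancies and cost/life-year streams for one arm."""

    arm: str
    age_group: str
    #: shape (horizon, 4 stages, 5 states); occupancy recorded after each
    #: cycle's transition step
    occupancy: np.ndarray
    #: cumulative expected enrolment per stage cohort, shape (horizon, 4)
    enrolled_cum: np.ndarray
    #: undiscounted USD per cycle, by component
    cost_stream: list[CycleCosts]
    #: cumulative expected breast-cancer deaths after each cycle
    deaths_cancer_cum: np.ndarray
    #: expected life-years lived per cycle by diagnosed cohorts
    life_year_stream: np.ndarray
    #: expected size of the undiagnosed at-risk pool at the start of each cycle
    at_risk: np.ndarray
    detections: list[CycleDetection] = field(default_factory=list)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    @property
    def cost_totals(self) -> np.ndarray:
        return np.array([c.total for c in self.cost_stream])

    @property
    def cumulative_cancer_deaths(self) -> float:
        return float(self.deaths_cancer_cum[-1])

    def total_diagnoses_by_stage(self) -> dict[str, float]:
        return {s: float(self.enrolled_cum[-1, i]) for i, s in enumerate(STAGES)}

    def to_frame(self):
        """Tidy per-cycle occupancy table (cycle, stage, state, expected_count)."""
        import pandas as pd

        records = [
            (t, stage, state, float(self.occupancy[t, i, j]))
            for t in range(self.horizon)
            for i, stage in enumerate(STAGES)
            for j, state in enumerate(STATES)
        ]
        return pd.DataFrame(records, columns=["cycle", "stage", "state", "expected_count"])


def build_transition_matrix(
    rates: StageTransitionRates, other_cause_mortality: float = 0.0
) -> TransitionMatrix:
    """Assemble the 5x5 row-stochastic matrix for one stage group × age band.

    Other-cause mortality is applied additively to every alive state; the
    diagonal takes the residual.  A negative residual (rates plus mortality
    exceeding 1) raises :class:`InfeasibleMatrixError` naming the row.
    """
    if not 0.0 <= other_cause_mortality < 1.0:
        raise ValueError(f"other_cause_mortality {other_cause_mortality} not in [0, 1)")
    m = other_cause_mortality
    P = np.zeros((5, 5))
    rows = {
        REMISSION: {LOCAL: rates.p_rem_to_local, DISTANT: rates.p_rem_to_dist,
                    OTHER_DEATH: m},
        LOCAL: {DISTANT: rates.p_local_to_dist, CANCER_DEATH: rates.p_local_to_death,
                OTHER_DEATH: m},
        DISTANT: {CANCER_DEATH: rates.p_dist_to_death, OTHER_DEATH: m},
    }
    for i, out in rows.items():
        residual = 1.0 - sum(out.values())
        if residual < -1e-12:
            raise InfeasibleMatrixError(
                f"{rates.stage_group}/{rates.age_group}: outgoing probabilities from "
                f"state {STATES[i]!r} sum to {1.0 - residual:.6g} > 1"
            )
        P[i, i] = max(residual, 0.0)
        for j, p in out.items():
            P[i, j] = p
    P[CANCER_DEATH, CANCER_DEATH] = 1.0
    P[OTHER_DEATH, OTHER_DEATH] = 1.0
    return TransitionMatrix(rates.stage_group, rates.age_group, P)


def discounted_sum(stream, rate: float, timing: str = "begin_of_cycle") -> float:
    """Present value of a per-cycle stream at an annual discount rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate {rate} not in [0, 1)")
    stream = np.asarray(stream, dtype=float)
    t = np.arange(len(stream), dtype=float)
    if timing == "end_of_cycle":
        t = t + 1.0
    elif timing != "begin_of_cycle":
        raise ValueError(f"unknown discount timing {timing!r}")
    return float(np.sum(stream / (1.0 + rate) ** t))


def _non_screening_detection(at_risk: float, incidence: float, cycle_index: int) -> CycleDetection:
    """All incident cancers present clinically; nobody is screened."""
    nc = at_risk * incidence
    return CycleDetection(
        cycle_index=cycle_index, n_screened=0.0, new_cancers=nc,
        true_positives=0.0, false_negatives=nc, false_positives=0.0,
    )


def run_cohort(
    config: ScenarioConfig,
    arm: str,
    age_group: str,
    mammography_unit_cost: float | None = None,
) -> CohortTrace:
    """Run one arm of the model for one age band over the full horizon.

    Each cycle: (a) the decision tree yields that cycle's expected diagnoses
    (screened arm) or incidence × clinical stage distribution (non-screened),
    (b) new diagnoses enter their stage cohort's initial state, (c) every
    cohort advances by one transition-matrix multiplication, (d) costs and
    life-years accrue.  ``mammography_unit_cost`` overrides the policy's
    blended price (used for pure government/private runs).
    """
    if arm not in ("screened", "non_screened"):
        raise ValueError(f"unknown arm {arm!r}")
    ag = config.age_groups[age_group]
    if mammography_unit_cost is None:
        mammography_unit_cost = config.mammography_unit_cost()

    matrices = {
        g: build_transition_matrix(config.transition(g, age_group),
                                   config.other_cause_mortality).matrix
        for g in ("I", "II_III", "IV")
    }
    stage_matrix = [matrices[stage_to_group(s)] for s in STAGES]
    screened_dist = config.stage_distributions["screened"]
    clinical_dist = config.stage_distributions["non_screened"]

    T = config.horizon_cycles
    occupancy = np.zeros((T, 4, 5))
    enrolled_cum = np.zeros((T, 4))
    deaths_cum = np.zeros(T)
    life_years = np.zeros(T)
    at_risk_trace = np.zeros(T)
    cost_stream: list[CycleCosts] = []
    detections: list[CycleDetection] = []

    occ = np.zeros((4, 5))
    enrolled = np.zeros(4)
    at_risk = float(config.cohort_size)

    for t in range(T):
        at_risk_trace[t] = at_risk
        if arm == "screened":
            pr = config.participation_rate
            det = screening_cycle_outcomes(
                at_risk * pr, ag.annual_incidence, ag.sensitivity, ag.specificity, t
            )
            det = allocate_diagnosis_stages(det, screened_dist, clinical_dist)
            if pr < 1.0:
                # non-participants present clinically, as in the comparator arm
                extra = at_risk * (1.0 - pr) * ag.annual_incidence
                det.new_cancers += extra
                det.false_negatives += extra
                for s, w in zip(STAGES, clinical_dist.p_stage):
                    det.clinically_detected_by_stage[s] += extra * w
        else:
            det = _non_screening_detection(at_risk, ag.annual_incidence, t)
            det = allocate_diagnosis_stages(det, screened_dist, clinical_dist)
        detections.append(det)

        cost_stream.append(cycle_costs(
            det, config.costs, arm, mammography_unit_cost,
            include_fp_workup=config.include_false_positive_workup,
            doctor_visit_attachment=config.doctor_visit_attachment,
        ))

        # (b) enrol this cycle's diagnoses, (c) advance every cohort
        by_stage = det.diagnoses_by_stage
        for i, s in enumerate(STAGES):
            occ[i, ENTRY_STATE[s]] += by_stage[s]
            enrolled[i] += by_stage[s]
            occ[i] = occ[i] @ stage_matrix[i]

        occupancy[t] = occ
        enrolled_cum[t] = enrolled
        deaths_cum[t] = occ[:, CANCER_DEATH].sum()
        life_years[t] = occ[:, list(ALIVE)].sum() * config.cycle_length_years

        if config.deplete_at_risk_pool:
            at_risk -= det.new_cancers

    return CohortTrace(
        arm=arm, age_group=age_group, occupancy=occupancy, enrolled_cum=enrolled_cum,
        cost_stream=cost_stream, deaths_cancer_cum=deaths_cum,
        life_year_stream=life_years, at_risk=at_risk_trace, detections=detections,
    )


def deaths_averted(trace_screened: CohortTrace, trace_non_screened: CohortTrace) -> float:
    """Cumulative cancer deaths avoided by screening at the final cycle."""
    if trace_screened.horizon != trace_non_screened.horizon:
        raise ValueError("traces have mismatched horizons")
    return (trace_non_screened.cumulative_cancer_deaths
            - trace_screened.cumulative_cancer_deaths)


def life_years_gained(
    deaths_averted_value: float,
    age_params: AgeGroupParams,
    discounts: DiscountRates,
    mode: str = "calibrated_multiplier",
) -> float:
    """Convert deaths averted into life-years gained.

    ``calibrated_multiplier`` multiplies by the band's calibrated
    years-per-death-averted constant.  ``life_table`` values each death
    averted at the discounted annuity of the band's mean remaining life
    expectancy L: sum over whole years t of min(1, L − t) / (1+r)^t.
    """
    if deaths_averted_value < 0:
        raise ValueError("deaths_averted_value must be non-negative")
    if mode == "calibrated_multiplier":
        if age_params.lyg_per_death_averted is None:
            raise ValueError(
                f"age group {age_params.label!r} has no calibrated "
                "lyg_per_death_averted multiplier"
            )
        return deaths_averted_value * age_params.lyg_per_death_averted
    if mode == "life_table":
        if not age_params.remaining_life_years:
            raise ValueError(
                f"age group {age_params.label!r} has no remaining-life-expectancy "
                "entries; life_table mode unavailable"
            )
        L = float(np.mean(list(age_params.remaining_life_years.values())))
        r = discounts.effect_rate
        years = np.arange(int(np.ceil(L)))
        annuity = float(np.sum(np.minimum(1.0, L - years) / (1.0 + r) ** years))
        return deaths_averted_value * annuity
    raise ValueError(f"unknown LYG mode {mode!r}")
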