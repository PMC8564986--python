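"""Expected-value screening/diagnosis decision tree for one annual cycle.

Each cycle the at-risk pool is partitioned into true positives, false
negatives, false positives and true negatives by the age-specific incidence
and the mammography sensitivity/specificity.  Screen-detected cases draw
their stage at diagnosis from the (favourable) screened distribution, while
false negatives present clinically in the same cycle and draw from the
non-screened distribution — the stage shift is the entire health benefit of
screening in this model.

All arithmetic is deterministic expected-value cohort accounting: fractional
women are allowed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import STAGES, CostSchedule, StageDistribution

__all__ = ["CycleDetection", "CycleCosts", "screening_cycle_outcomes",
           "allocate_diagnosis_stages", "cycle_costs"]


@dataclass
class CycleDetection:
    """Expected screening/diagnosis flows for one cycle."""

    cycle_index: int
    n_screened: float
    new_cancers: float
    true_positives: float
    false_negatives: float
    false_positives: float
    #: expected counts by stage, split by detection mode
    screen_detected_by_stage: dict[str, float] = field(default_factory=dict)
    clinically_detected_by_stage: dict[str, float] = field(default_factory=dict)

    @property
    def diagnoses_by_stage(self) -> dict[str, float]:
        return {
            s: self.screen_detected_by_stage.get(s, 0.0)
            + self.clinically_detected_by_stage.get(s, 0.0)
            for s in STAGES
        }


@dataclass
class CycleCosts:
    """Undiscounted cost components (USD) for one cycle of one arm."""

    screening: float = 0.0
    doctor_visits: float = 0.0
    diagnostics: float = 0.0
    treatment: float = 0.0

    @property
    def total(self) -> float:
        return self.screening + self.doctor_visits + self.diagnostics + self.treatment


def screening_cycle_outcomes(
    at_risk: float,
    incidence: float,
    sensitivity: float,
    specificity: float,
    cycle_index: int = 0,
) -> CycleDetection:
    """Partition the at-risk pool into TP / FN / FP (TN is the remainder)."""
    if at_risk < 0:
        raise ValueError(f"at_risk must be non-negative, got {at_risk}")
    for name, p in (("incidence", incidence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    new_cancers = at_risk * incidence
    return CycleDetection(
        cycle_index=cycle_index,
        n_screened=at_risk,
        new_cancers=new_cancers,
        true_positives=new_cancers * sensitivity,
        false_negatives=new_cancers * (1.0 - sensitivity),
        false_positives=(at_risk - new_cancers) * (1.0 - specificity),
    )


def allocate_diagnosis_stages(
    detection: CycleDetection,
    screened_dist: StageDistribution,
    clinical_dist: StageDistribution,
) -> CycleDetection:
    """Distribute diagnosed cases over stages I–IV by detection mode.

    True positives follow the screened stage distribution; false negatives
    (clinical presenters) follow the non-screened one.  Totals are preserved
    because both distributions sum to 1.
    """
    for dist in (screened_dist, clinical_dist):
        if abs(sum(dist.p_stage) - 1.0) > 1e-9:
            raise ValueError(
                f"stage distribution for arm {dist.arm!r} is not normalized "
                f"(sum={sum(dist.p_stage)!r})"
            )
    detection.screen_detected_by_stage = {
        s: detection.true_positives * w for s, w in zip(STAGES, screened_dist.p_stage)
    }
    detection.clinically_detected_by_stage = {
        s: detection.false_negatives * w for s, w in zip(STAGES, clinical_dist.p_stage)
    }
    return detection


def cycle_costs(
    detection: CycleDetection,
    costs: CostSchedule,
    arm: str,
    mammography_unit_cost: float,
    include_fp_workup: bool = True,
    doctor_visit_attachment: str = "per_screen",
) -> CycleCosts:
    """Undiscounted cost components of one cycle.

    Screened arm: every screening encounter costs the mammography price plus
    (by default) a doctor visit; every positive screen (true and, when
    ``include_fp_workup``, false) is confirmed with FNAC; each diagnosed case
    incurs its stage's one-time treatment cost.  Non-screened arm: each
    clinically diagnosed case costs a doctor visit, FNAC and treatment.
    """
    for name in ("n_screened", "new_cancers", "true_positives",
                 "false_negatives", "false_positives"):
        if getattr(detection, name) < 0:
            raise ValueError(f"negative count {name}={getattr(detection, name)}")
    by_stage = detection.diagnoses_by_stage
    treatment = sum(by_stage[s] * costs.treatment_by_stage[s] for s in STAGES)

    if arm == "screened":
        workup = detection.true_positives
        if include_fp_workup:
            workup += detection.false_positives
        if doctor_visit_attachment == "per_screen":
            visits = detection.n_screened
        else:  # per_positive: only women with a positive screen see the doctor
            visits = detection.true_positives + detection.false_positives
        return CycleCosts(
            screening=detection.n_screened * mammography_unit_cost,
            doctor_visits=visits * costs.doctor_visit,
            diagnostics=workup * costs.fnac,
            treatment=treatment,
        )
    if arm == "non_screened":
        diagnosed = detection.new_cancers
        return CycleCosts(
            screening=0.0,
            doctor_visits=diagnosed * costs.doctor_visit,
            diagnostics=diagnosed * costs.fnac,
            treatment=treatment,
        )
    raise ValueError(f"unknown arm {arm!r}")
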