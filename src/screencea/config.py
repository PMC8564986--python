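"""Scenario configuration: every input of the screening-mammography model.

A :class:`ScenarioConfig` bundles the epidemiology (age-specific incidence),
mammography test characteristics, per-cycle stage-progression probabilities,
stage-at-diagnosis distributions for screen-detected and clinically detected
cancers, unit costs, discount rates, the provider-mix policy and the run
horizon.  Configurations are read from YAML or JSON documents; the packaged
Ethiopian baseline is available through :func:`baseline_scenario`.

Validation is two-layered: the pydantic models enforce *types* (and reject
unknown keys, because a silently misspelled probability name would corrupt
the analysis), while :func:`validate_scenario` collects every *range* and
cross-field violation as data instead of stopping at the first.
"""

from __future__ import annotations

import copy
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "SCHEMA_VERSION",
    "STAGES",
    "STAGE_GROUPS",
    "AgeGroupParams",
    "StageTransitionRates",
    "StageDistribution",
    "CostSchedule",
    "DiscountRates",
    "Policy",
    "ScenarioConfig",
    "SchemaError",
    "load_scenario",
    "validate_scenario",
    "normalize_stage_distribution",
    "baseline_scenario",
    "serialize_scenario",
    "stage_to_group",
]

SCHEMA_VERSION = 1

#: Cancer stages at diagnosis, in the order used by every stage-indexed array.
STAGES = ("I", "II", "III", "IV")

#: Transition-rate groups: stages II and III share one printed rate set.
STAGE_GROUPS = ("I", "II_III", "IV")

_NORMALIZATION_TOL = 1e-9


class SchemaError(ValueError):
    """A scenario document failed schema or invariant validation.

    Carries the full list of violations in :attr:`violations`; the message
    names the first offending field path.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            f"invalid scenario document ({len(self.violations)} problem(s)); "
            f"first: {self.violations[0]}"
        )


def stage_to_group(stage: str) -> str:
    """Map a diagnosis stage ("I".."IV") to its transition-rate group."""
    if stage in ("II", "III"):
        return "II_III"
    if stage in ("I", "IV"):
        return stage
    raise ValueError(f"unknown stage {stage!r}")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AgeGroupParams(_StrictModel):
    """Age-band-specific epidemiology and test characteristics.

    ``remaining_life_years`` maps five-year sub-bands (e.g. "40-44") to
    undiscounted remaining life expectancy; ``lyg_per_death_averted`` is the
    calibrated life-years-gained multiplier used by the default LYG mode.
    """

    label: str
    annual_incidence: float
    sensitivity: float = 1.0
    specificity: float = 1.0
    remaining_life_years: dict[str, float] = {}
    lyg_per_death_averted: Optional[float] = None


class StageTransitionRates(_StrictModel):
    """Per-cycle progression probabilities for one stage group × age band.

    Unprinted transitions default to 0; recurrence states never return to
    remission (progression-only chain).
    """

    stage_group: Literal["I", "II_III", "IV"]
    age_group: str
    p_rem_to_local: float = 0.0
    p_rem_to_dist: float = 0.0
    p_local_to_dist: float = 0.0
    p_local_to_death: float = 0.0
    p_dist_to_death: float = 0.0


class StageDistribution(_StrictModel):
    """Stage-at-diagnosis probabilities over stages I–IV for one arm."""

    arm: Literal["screened", "non_screened"]
    p_stage: tuple[float, float, float, float]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STAGES, self.p_stage))


class CostSchedule(_StrictModel):
    """Unit costs in USD."""

    mammography_gov: float
    mammography_private: float
    doctor_visit: float
    fnac: float
    treatment_by_stage: dict[str, float]


class DiscountRates(_StrictModel):
    """Annual discount rates (proportions) for costs and health effects."""

    cost_rate: float = 0.05
    effect_rate: float = 0.03


class Policy(_StrictModel):
    """Provider-mix policy: share of screens performed at private prices."""

    name: str
    private_share: float


class ScenarioConfig(_StrictModel):
    """The complete parameter bundle for one model run."""

    schema_version: int = SCHEMA_VERSION
    age_groups: dict[str, AgeGroupParams]
    transitions: list[StageTransitionRates]
    stage_distributions: dict[str, StageDistribution]
    costs: CostSchedule
    discounts: DiscountRates = DiscountRates()
    policy: Policy = Policy(name="government", private_share=0.0)
    cohort_size: float = 100_000
    horizon_cycles: int = 10
    cycle_length_years: float = 1.0
    wtp_threshold: float = 2808.5
    include_false_positive_workup: bool = True
    discount_timing: Literal["begin_of_cycle", "end_of_cycle"] = "begin_of_cycle"
    lyg_mode: Literal["life_table", "calibrated_multiplier"] = "calibrated_multiplier"
    participation_rate: float = 1.0
    doctor_visit_attachment: Literal["per_screen", "per_positive"] = "per_screen"
    deplete_at_risk_pool: bool = True
    other_cause_mortality: float = 0.0

    def transition(self, stage_group: str, age_group: str) -> StageTransitionRates:
        """Return the transition-rate set for ``stage_group`` × ``age_group``."""
        for t in self.transitions:
            if t.stage_group == stage_group and t.age_group == age_group:
                return t
        raise KeyError(f"no transition rates for {stage_group!r} × {age_group!r}")

    def mammography_unit_cost(self, private_share: Optional[float] = None) -> float:
        """Blended per-exam mammography price for a private share."""
        s = self.policy.private_share if private_share is None else private_share
        return (1.0 - s) * self.costs.mammography_gov + s * self.costs.mammography_private


# --------------------------------------------------------------------------
# operations


def normalize_stage_distribution(
    raw: Sequence[float], tolerance: float = 0.05
) -> tuple[float, ...]:
    """Proportionally rescale four non-negative stage weights to sum to 1.

    Printed stage distributions often carry rounding error (the packaged
    baseline's sum to 1.001 in both arms); proportional rescaling is the
    minimal correction.  A deviation of the raw sum from 1 beyond
    ``tolerance`` is treated as a data error, not rounding, and raises.
    """
    if len(raw) != len(STAGES):
        raise ValueError(f"expected {len(STAGES)} stage weights, got {len(raw)}")
    if any(w < 0 for w in raw):
        raise ValueError(f"stage weights must be non-negative, got {tuple(raw)}")
    total = float(sum(raw))
    if total == 0.0:
        raise ValueError("degenerate stage distribution: all weights are zero")
    if abs(total - 1.0) > tolerance:
        raise ValueError(
            f"stage weights sum to {total!r}, deviating from 1 by more than "
            f"the tolerance {tolerance}; refusing to normalize silently"
        )
    if abs(total - 1.0) < 1e-12:  # already normalized; keep round-trips exact
        return tuple(float(w) for w in raw)
    return tuple(w / total for w in raw)


def validate_scenario(config: ScenarioConfig) -> list[str]:
    """Collect every invariant violation of ``config``; empty list iff valid."""
    v: list[str] = []

    def chk(cond: bool, msg: str) -> None:
        if not cond:
            v.append(msg)

    for label, ag in config.age_groups.items():
        p = f"age_groups.{label}"
        chk(label == ag.label, f"{p}.label: key {label!r} != label {ag.label!r}")
        chk(0.0 <= ag.annual_incidence <= 1.0, f"{p}.annual_incidence: {ag.annual_incidence} not in [0, 1]")
        chk(0.0 <= ag.sensitivity <= 1.0, f"{p}.sensitivity: {ag.sensitivity} not in [0, 1]")
        chk(0.0 <= ag.specificity <= 1.0, f"{p}.specificity: {ag.specificity} not in [0, 1]")
        for band, yrs in ag.remaining_life_years.items():
            chk(yrs > 0.0, f"{p}.remaining_life_years.{band}: {yrs} not strictly positive")
        if ag.lyg_per_death_averted is not None:
            chk(ag.lyg_per_death_averted > 0.0, f"{p}.lyg_per_death_averted: {ag.lyg_per_death_averted} not positive")

    for i, t in enumerate(config.transitions):
        p = f"transitions[{i}]({t.stage_group},{t.age_group})"
        for name in ("p_rem_to_local", "p_rem_to_dist", "p_local_to_dist", "p_local_to_death", "p_dist_to_death"):
            val = getattr(t, name)
            chk(0.0 <= val <= 1.0, f"{p}.{name}: {val} not in [0, 1]")
        chk(
            t.p_rem_to_local + t.p_rem_to_dist <= 1.0 + 1e-12,
            f"{p}: p_rem_to_local + p_rem_to_dist = {t.p_rem_to_local + t.p_rem_to_dist} exceeds 1",
        )
        chk(
            t.p_local_to_dist + t.p_local_to_death <= 1.0 + 1e-12,
            f"{p}: p_local_to_dist + p_local_to_death = {t.p_local_to_dist + t.p_local_to_death} exceeds 1",
        )
        chk(t.age_group in config.age_groups, f"{p}: age group {t.age_group!r} not defined in age_groups")

    for arm in ("screened", "non_screened"):
        if arm not in config.stage_distributions:
            v.append(f"stage_distributions: missing arm {arm!r}")
            continue
        d = config.stage_distributions[arm]
        chk(d.arm == arm, f"stage_distributions.{arm}.arm: {d.arm!r} != key")
        for stage, w in zip(STAGES, d.p_stage):
            chk(0.0 <= w <= 1.0, f"stage_distributions.{arm}.p_stage[{stage}]: {w} not in [0, 1]")
        chk(
            abs(sum(d.p_stage) - 1.0) <= _NORMALIZATION_TOL,
            f"stage_distributions.{arm}: entries sum to {sum(d.p_stage)!r}, not 1 within {_NORMALIZATION_TOL}",
        )

    c = config.costs
    for name in ("mammography_gov", "mammography_private", "doctor_visit", "fnac"):
        val = getattr(c, name)
        chk(val >= 0.0, f"costs.{name}: {val} is negative (CostSchedule requires non-negative costs)")
    for stage in STAGES:
        if stage not in c.treatment_by_stage:
            v.append(f"costs.treatment_by_stage: missing stage {stage!r}")
        else:
            chk(
                c.treatment_by_stage[stage] >= 0.0,
                f"costs.treatment_by_stage.{stage}: {c.treatment_by_stage[stage]} is negative "
                "(CostSchedule requires non-negative costs)",
            )

    chk(0.0 <= config.discounts.cost_rate < 1.0, f"discounts.cost_rate: {config.discounts.cost_rate} not in [0, 1)")
    chk(0.0 <= config.discounts.effect_rate < 1.0, f"discounts.effect_rate: {config.discounts.effect_rate} not in [0, 1)")
    chk(0.0 <= config.policy.private_share <= 1.0, f"policy.private_share: {config.policy.private_share} not in [0, 1]")
    chk(config.cohort_size >= 1, f"cohort_size: {config.cohort_size} < 1")
    chk(config.horizon_cycles >= 1, f"horizon_cycles: {config.horizon_cycles} < 1")
    chk(config.cycle_length_years > 0, f"cycle_length_years: {config.cycle_length_years} not positive")
    chk(config.wtp_threshold > 0, f"wtp_threshold: {config.wtp_threshold} not positive")
    chk(0.0 <= config.participation_rate <= 1.0, f"participation_rate: {config.participation_rate} not in [0, 1]")
    chk(0.0 <= config.other_cause_mortality < 1.0, f"other_cause_mortality: {config.other_cause_mortality} not in [0, 1)")
    return v


def _prune_unknown_keys(data: dict, errors: list[dict]) -> list[str]:
    """Remove keys flagged as extra_forbidden from a nested dict, in place."""
    pruned = []
    for err in errors:
        if err["type"] != "extra_forbidden":
            continue
        loc = err["loc"]
        node: Any = data
        try:
            for part in loc[:-1]:
                node = node[part]
            del node[loc[-1]]
            pruned.append(".".join(str(p) for p in loc))
        except (KeyError, IndexError, TypeError):  # pragma: no cover
            pass
    return pruned


def load_scenario(
    document: str | Path | Mapping[str, Any],
    *,
    strict: bool = True,
    normalize_distributions: bool = True,
) -> ScenarioConfig:
    """Load and validate a scenario from YAML/JSON text, a path, or a mapping.

    Stage-at-diagnosis distributions are proportionally renormalized at load
    time (raw sums within 5% of 1).  Unknown keys are rejected in strict mode
    and dropped with a warning when ``strict=False``.

    Raises :class:`SchemaError` carrying every violation found.
    """
    if isinstance(document, Mapping):
        data: Any = copy.deepcopy(dict(document))
    else:
        if isinstance(document, Path):
            text = document.read_text()
        elif "\n" not in document and Path(document).is_file():
            text = Path(document).read_text()
        else:
            text = document
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(["document root: expected a mapping of scenario fields"])

    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError([f"schema_version: {version!r} is not supported (expected {SCHEMA_VERSION})"])

    if normalize_distributions:
        for arm, dist in (data.get("stage_distributions") or {}).items():
            raw = dist.get("p_stage") if isinstance(dist, dict) else None
            if raw is not None:
                try:
                    dist["p_stage"] = list(normalize_stage_distribution(raw))
                except ValueError as exc:
                    raise SchemaError([f"stage_distributions.{arm}.p_stage: {exc}"]) from exc

    for _ in range(2):
        try:
            config = ScenarioConfig(**data)
            break
        except ValidationError as exc:
            errors = exc.errors()
            extra = [e for e in errors if e["type"] == "extra_forbidden"]
            if extra and not strict:
                for path in _prune_unknown_keys(data, errors):
                    warnings.warn(f"ignoring unknown scenario key {path!r}", stacklevel=2)
                continue
            raise SchemaError(
                [".".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in errors]
            ) from exc
    violations = validate_scenario(config)
    if violations:
        raise SchemaError(violations)
    return config


def serialize_scenario(config: ScenarioConfig) -> str:
    """Render a scenario back to YAML; re-loading yields an equal config."""
    data = config.model_dump(mode="json")
    data["transitions"] = [
        {k: v for k, v in t.items()} for t in data["transitions"]
    ]
    return yaml.safe_dump(data, sort_keys=False)


def baseline_scenario() -> ScenarioConfig:
    """The packaged Ethiopian annual-screening baseline scenario.

    100,000 women per age band, 10 annual cycles, government policy,
    willingness-to-pay 2808.5 USD per life-year gained.
    """
    text = resources.files("screencea").joinpath("fixtures/ethiopia_baseline.yaml").read_text()
    return load_scenario(text)
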