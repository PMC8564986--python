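"""One-way (tornado) and probabilistic sensitivity analysis.

OWSA re-runs the full pipeline with one parameter at a time moved to ±20%
of its base value (probabilities capped at 1; discount rates swept over
0–6%).  PSA is second-order Monte Carlo: every uncertain parameter is drawn
from its assigned family — Beta for probabilities, Gamma for costs and
life-expectancy quantities, Dirichlet for the stage-at-diagnosis simplexes —
parameterised by method of moments around the base value with a
configurable coefficient of variation (the dispersion is an assumption of
this package, not an input of the source data; see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import STAGES, Policy, ScenarioConfig, validate_scenario
from .metrics import CEAResult, evaluate_policy

__all__ = [
    "OWSAEntry", "PSAConfig", "PSASummary", "owsa_range", "parameter_registry",
    "get_param", "set_param", "run_owsa", "draw_parameters", "run_psa",
    "owsa_frame",
]

log = logging.getLogger(__name__)

_TRANSITION_FIELDS = ("p_rem_to_local", "p_rem_to_dist", "p_local_to_dist",
                      "p_local_to_death", "p_dist_to_death")


# --------------------------------------------------------------------------
# dotted-path access


def get_param(config: ScenarioConfig, path: str):
    """Read a scalar parameter by dotted path.

    Transition rates are addressed as
    ``transitions.<stage_group>.<age_group>.<field>``; everything else by
    plain attribute / mapping traversal.
    """
    parts = path.split(".")
    if parts[0] == "transitions":
        return getattr(config.transition(parts[1], parts[2]), parts[3])
    obj = config
    for part in parts:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj


def _set_inplace(config: ScenarioConfig, path: str, value) -> None:
    parts = path.split(".")
    if parts[0] == "transitions":
        setattr(config.transition(parts[1], parts[2]), parts[3], value)
        return
    obj = config
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    if isinstance(obj, dict):
        obj[parts[-1]] = value
    else:
        setattr(obj, parts[-1], value)


def set_param(config: ScenarioConfig, path: str, value) -> ScenarioConfig:
    """Return a deep copy of ``config`` with one parameter replaced."""
    new = config.model_copy(deep=True)
    _set_inplace(new, path, value)
    return new


# --------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass
class OWSAEntry:
    parameter: str
    kind: str
    base_value: float
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def owsa_range(base_value: float, kind: str) -> tuple[float, float]:
    """Low/high perturbation bounds for one parameter.

    ±20% of base for probabilities (capped at 1) and costs; the fixed sweep
    0%–6% for discount rates.
    """
    if kind == "discount_rate":
        return (0.0, 0.06)
    if kind == "probability":
        return (0.8 * base_value, min(1.2 * base_value, 1.0))
    if kind == "cost":
        return (0.8 * base_value, 1.2 * base_value)
    raise ValueError(f"unknown parameter kind {kind!r}")


def parameter_registry(config: ScenarioConfig, age_group: str) -> list[tuple[str, str]]:
    """(path, kind) for every scalar parameter relevant to one age band.

    Stage-at-diagnosis distributions are excluded: perturbing a single
    simplex coordinate forces a renormalisation that is no longer one-way.
    They are varied jointly in the PSA instead.
    """
    reg: list[tuple[str, str]] = [
        (f"age_groups.{age_group}.annual_incidence", "probability"),
        (f"age_groups.{age_group}.sensitivity", "probability"),
        (f"age_groups.{age_group}.specificity", "probability"),
        ("costs.mammography_gov", "cost"),
        ("costs.mammography_private", "cost"),
        ("costs.doctor_visit", "cost"),
        ("costs.fnac", "cost"),
        ("discounts.cost_rate", "discount_rate"),
        ("discounts.effect_rate", "discount_rate"),
    ]
    reg += [(f"costs.treatment_by_stage.{s}", "cost") for s in STAGES]
    if config.age_groups[age_group].lyg_per_death_averted is not None:
        reg.append((f"age_groups.{age_group}.lyg_per_death_averted", "cost"))
    for t in config.transitions:
        if t.age_group != age_group:
            continue
        for f in _TRANSITION_FIELDS:
            reg.append((f"transitions.{t.stage_group}.{t.age_group}.{f}", "probability"))
    return reg


def _icer_float(result: CEAResult) -> float:
    return result.icer if isinstance(result.icer, float) else math.nan


def run_owsa(
    config: ScenarioConfig,
    policy: Policy,
    age_group: str,
    parameters: Optional[Sequence[tuple[str, str]]] = None,
) -> list[OWSAEntry]:
    """Tornado table: ICER at the low/high value of each parameter in turn,
    all other parameters held at base; sorted by span, largest first."""
    if parameters is None:
        parameters = parameter_registry(config, age_group)
    entries = []
    for path, kind in parameters:
        base = get_param(config, path)
        low, high = owsa_range(base, kind)
        icer_lo = _icer_float(evaluate_policy(set_param(config, path, low), policy, age_group))
        icer_hi = _icer_float(evaluate_policy(set_param(config, path, high), policy, age_group))
        entries.append(OWSAEntry(path, kind, base, low, high, icer_lo, icer_hi))
    entries.sort(key=lambda e: (-(e.span if not math.isnan(e.span) else -math.inf), e.parameter))
    return entries


def owsa_frame(entries: Sequence[OWSAEntry]):
    import pandas as pd

    return pd.DataFrame([
        {"parameter": e.parameter, "kind": e.kind, "base_value": e.base_value,
         "low_value": e.low_value, "high_value": e.high_value,
         "icer_at_low": e.icer_at_low, "icer_at_high": e.icer_at_high,
         "span": e.span}
        for e in entries
    ])


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAConfig:
    """Second-order Monte Carlo settings.

    ``distribution_overrides`` maps a parameter path to a family in
    {"beta", "gamma", "fixed"}; unlisted parameters use their defaults
    (probabilities Beta, treatment costs / life-expectancy Gamma, unit
    prices and discount rates fixed, stage distributions Dirichlet).
    """

    iterations: int = 10_000
    seed: int = 0
    coefficient_of_variation: float = 0.1
    #: Dirichlet total concentration; None derives it from the CV as
    #: 1/cv**2 - 1, which matches the component-wise dispersion of the
    #: Beta draws (~100 at the default cv=0.1) and degenerates as cv -> 0.
    dirichlet_concentration: Optional[float] = None
    distribution_overrides: dict[str, str] = field(default_factory=dict)
    max_redraws: int = 50

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.coefficient_of_variation <= 0:
            raise ValueError("coefficient of variation must be > 0")

    @property
    def effective_dirichlet_concentration(self) -> float:
        if self.dirichlet_concentration is not None:
            return self.dirichlet_concentration
        return 1.0 / self.coefficient_of_variation**2 - 1.0


@dataclass
class PSASummary:
    """Moments, percentiles and the CE probability over the PSA draws."""

    iterations: int
    seed: int
    outputs: dict[str, dict[str, float]]
    probability_cost_effective: float
    wtp: float
    n_redraws: int
    draws: dict[str, np.ndarray]

    def probability_cost_effective_at(self, wtp: float) -> float:
        """P(cost-effective) at an arbitrary willingness-to-pay."""
        return float(np.mean(wtp * self.draws["lyg"] - self.draws["incremental_cost"] > 0))


def _psa_families(config: ScenarioConfig, age_group: str,
                  psa: PSAConfig) -> list[tuple[str, str]]:
    defaults = {
        f"age_groups.{age_group}.annual_incidence": "beta",
        f"age_groups.{age_group}.sensitivity": "beta",
        f"age_groups.{age_group}.specificity": "beta",
        "costs.mammography_gov": "fixed",
        "costs.mammography_private": "fixed",
        "costs.doctor_visit": "fixed",
        "costs.fnac": "fixed",
        "discounts.cost_rate": "fixed",
        "discounts.effect_rate": "fixed",
    }
    for s in STAGES:
        defaults[f"costs.treatment_by_stage.{s}"] = "gamma"
    if config.age_groups[age_group].lyg_per_death_averted is not None:
        defaults[f"age_groups.{age_group}.lyg_per_death_averted"] = "gamma"
    for t in config.transitions:
        if t.age_group != age_group:
            continue
        for f in _TRANSITION_FIELDS:
            if getattr(t, f) > 0:
                defaults[f"transitions.{t.stage_group}.{t.age_group}.{f}"] = "beta"
    out = []
    for path, family in defaults.items():
        out.append((path, psa.distribution_overrides.get(path, family)))
    return out


def _draw_beta(rng, mean: float, cv: float) -> float:
    if mean <= 0.0 or mean >= 1.0:
        return mean
    var = (cv * mean) ** 2
    cap = 0.99 * mean * (1.0 - mean)
    if var > cap:  # moment match infeasible for this mean: clamp dispersion
        log.warning("beta CV clamped for mean %.4g", mean)
        var = cap
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_gamma(rng, mean: float, cv: float) -> float:
    if mean <= 0.0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def draw_parameters(
    config: ScenarioConfig,
    psa: PSAConfig,
    draw_index: int,
    age_group: str,
    attempt: int = 0,
) -> ScenarioConfig:
    """One joint parameter draw; reproducible given (seed, draw_index)."""
    rng = np.random.default_rng([psa.seed, draw_index, attempt])
    new = config.model_copy(deep=True)
    for path, family in _psa_families(config, age_group, psa):
        base = get_param(config, path)
        if family == "fixed" or base is None:
            continue
        cv = psa.coefficient_of_variation
        if family == "beta":
            value = _draw_beta(rng, float(base), cv)
        elif family == "gamma":
            value = _draw_gamma(rng, float(base), cv)
        else:
            raise ValueError(f"unknown distribution family {family!r} for {path}")
        _set_inplace(new, path, value)
    for arm, dist in config.stage_distributions.items():
        p = np.array(dist.p_stage)
        pos = p > 0
        alpha = psa.effective_dirichlet_concentration * p[pos]
        drawn = np.zeros_like(p)
        drawn[pos] = rng.dirichlet(alpha)
        new.stage_distributions[arm].p_stage = tuple(float(x) for x in drawn)
    return new


def run_psa(
    config: ScenarioConfig,
    psa: PSAConfig,
    policy: Policy,
    age_group: str,
) -> PSASummary:
    """Evaluate the full pipeline on each parameter draw and summarise.

    Draws producing an invalid scenario are rejected and redrawn (counted in
    ``n_redraws``).  Identical (seed, iterations) give identical output.
    """
    cost = np.empty(psa.iterations)
    lyg = np.empty(psa.iterations)
    icer_draws = np.empty(psa.iterations)
    inmb_draws = np.empty(psa.iterations)
    n_redraws = 0
    for i in range(psa.iterations):
        for attempt in range(psa.max_redraws):
            drawn = draw_parameters(config, psa, i, age_group, attempt)
            if validate_scenario(drawn):
                n_redraws += 1
                continue
            try:
                res = evaluate_policy(drawn, policy, age_group)
            except ValueError:
                n_redraws += 1
                continue
            break
        else:
            raise RuntimeError(f"draw {i}: no feasible parameter set "
                               f"after {psa.max_redraws} attempts")
        cost[i] = res.incremental_cost
        lyg[i] = res.lyg
        icer_draws[i] = _icer_float(res)
        inmb_draws[i] = res.inmb

    def summarise(x: np.ndarray) -> dict[str, float]:
        x = x[~np.isnan(x)]
        if len(x) == 0:
            return {k: math.nan for k in
                    ("mean", "sem", "sd", "p2.5", "p50", "p97.5")}
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        lo, med, hi = np.percentile(x, [2.5, 50, 97.5])
        return {"mean": float(np.mean(x)), "sem": sd / math.sqrt(len(x)),
                "sd": sd, "p2.5": float(lo), "p50": float(med), "p97.5": float(hi)}

    draws = {"incremental_cost": cost, "lyg": lyg, "icer": icer_draws,
             "inmb": inmb_draws}
    return PSASummary(
        iterations=psa.iterations, seed=psa.seed,
        outputs={k: summarise(v) for k, v in draws.items()},
        probability_cost_effective=float(np.mean(inmb_draws > 0)),
        wtp=config.wtp_threshold, n_redraws=n_redraws, draws=draws,
    )
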