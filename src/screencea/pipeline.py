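"""High-level facade tying the modules into one object.

``ScreeningCEA`` wraps a scenario and exposes the analyses as methods; it
holds no state beyond the configuration, so every call is a fresh run.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .config import Policy, ScenarioConfig, baseline_scenario
from .markov import CohortTrace, run_cohort
from .metrics import CANONICAL_POLICIES, CEAResult, evaluate_policy, policy_table
from .sensitivity import OWSAEntry, PSAConfig, PSASummary, run_owsa, run_psa

__all__ = ["ScreeningCEA"]


class ScreeningCEA:
    """Cost-effectiveness analysis of annual screening mammography.

    Parameters
    ----------
    config:
        A validated :class:`ScenarioConfig`; defaults to the packaged
        Ethiopian baseline.
    """

    def __init__(self, config: Optional[ScenarioConfig] = None):
        self.config = config if config is not None else baseline_scenario()

    def run_arm(self, arm: str, age_group: str,
                mammography_unit_cost: Optional[float] = None) -> CohortTrace:
        return run_cohort(self.config, arm, age_group, mammography_unit_cost)

    def evaluate(self, policy: Optional[Policy] = None,
                 age_group: str = "40-49") -> CEAResult:
        return evaluate_policy(self.config, policy or self.config.policy, age_group)

    def policy_table(self, policies: Sequence[Policy] = CANONICAL_POLICIES,
                     age_groups: Sequence[str] = ("40-49", "50-59")) -> list[CEAResult]:
        return policy_table(self.config, policies, age_groups)

    def owsa(self, policy: Optional[Policy] = None,
             age_group: str = "40-49") -> list[OWSAEntry]:
        return run_owsa(self.config, policy or self.config.policy, age_group)

    def psa(self, psa_config: Optional[PSAConfig] = None,
            policy: Optional[Policy] = None, age_group: str = "40-49") -> PSASummary:
        return run_psa(self.config, psa_config or PSAConfig(),
                       policy or self.config.policy, age_group)
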