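"""Scenario definitions: the primary analysis and sensitivity analyses SA1-SA5.

A scenario bundles the structural switches of the model — which baseline
survival form to use for the first eight years, how long the relative
effect of BNP-guided care lasts, and any declarative overrides of registry
parameters (e.g. the BNP test cost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["ScenarioConfig", "build_scenario", "SCENARIO_NAMES"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Structural configuration of one analysis scenario.

    ``effect_window_cycles`` is the number of 3-month cycles over which the
    BNP-guided hazard ratios apply (``None`` = lifetime);
    ``cost_clip_cycles`` truncates the BNP-specific cost streams (testing,
    medication uptitration, incremental visits) at the given cycle
    (``None`` = their natural durations). ``overrides`` are applied to the
    parameter registry, pinning the named parameters at new fixed values.
    """

    name: str
    survival_form: str = "exponential"  # or "weibull"
    effect_window_cycles: int | None = 16  # 4 years at 3-month cycles
    cost_clip_cycles: int | None = None
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.survival_form not in ("exponential", "weibull"):
            raise ValueError(f"unknown survival form {self.survival_form!r}")
        if self.effect_window_cycles is not None and self.effect_window_cycles < 0:
            raise ValueError("effect window must be >= 0 cycles")

    def in_effect_window(self, cycle: int) -> bool:
        return self.effect_window_cycles is None or cycle < self.effect_window_cycles


_SCENARIOS: dict[str, ScenarioConfig] = {
    # base case: exponential baseline, 4-year treatment effect, £25 test
    "primary": ScenarioConfig("primary"),
    # Weibull (decreasing-hazard) baseline survival for the under-75 cohort
    "SA1": ScenarioConfig("SA1", survival_form="weibull"),
    # effect and BNP-specific costs cease at 2 years
    "SA2": ScenarioConfig("SA2", effect_window_cycles=8, cost_clip_cycles=8),
    # effect sustained for the lifetime of patients
    "SA3": ScenarioConfig("SA3", effect_window_cycles=None),
    # halved / increased-by-half BNP test cost
    "SA4": ScenarioConfig("SA4", overrides={"bnp_test_cost": 12.5}),
    "SA5": ScenarioConfig("SA5", overrides={"bnp_test_cost": 37.5}),
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def build_scenario(name: str) -> ScenarioConfig:
    """Look up a scenario by name (``primary`` or ``SA1`` … ``SA5``)."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(_SCENARIOS)}"
        ) from None
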