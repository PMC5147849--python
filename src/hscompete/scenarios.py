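"""Scenario presets: normal wound healing and the tumor-inflow variants.

Wound healing is a one-shot release of all three classes at t=0 with no
further inflow.  The tumor scenarios add a continuous per-step inflow of
(mostly) low- and medium-affinity factors, emulating tumor or hypoxic
stromal secretion; the preset names follow the panel lettering of the
published figure family (B through F, plus the supplementary S8 variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ConfigError, SimulationConfig, validate_affinity_ordering

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "wound_healing_scenario",
    "tumor_scenario",
    "apply_scenario",
    "get_scenario",
    "list_scenarios",
    "validate_affinity_ordering",
]

_TUMOR_INFLOWS: dict[str, tuple[int, int, int]] = {
    "B": (1, 0, 0),  # 1 additional LA per step
    "C": (1, 1, 0),  # 1 LA + 1 MA
    "D": (2, 1, 0),  # 2 LA + 1 MA
    "E": (5, 1, 0),  # 5 LA + 1 MA
    "F": (5, 1, 1),  # 5 LA + 1 MA + 1 HA
    "S8": (5, 1, 2),  # 5 LA + 1 MA + 2 HA
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named preset: an inflow triple plus optional config field deltas."""

    name: str
    inflow_per_step: tuple[int, int, int]
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.inflow_per_step):
            raise ConfigError(
                f"scenario {self.name!r}: inflow_per_step must be non-negative"
            )


def wound_healing_scenario() -> ScenarioSpec:
    """The baseline scenario: one-shot release at t=0, no inflow."""
    return ScenarioSpec("wound_healing", (0, 0, 0))


def tumor_scenario(name: str) -> ScenarioSpec:
    """A tumor-inflow preset by panel name (B, C, D, E, F, or S8)."""
    key = name.upper()
    if key not in _TUMOR_INFLOWS:
        raise ConfigError(
            f"unknown tumor scenario {name!r}; valid names: "
            + ", ".join(sorted(_TUMOR_INFLOWS))
        )
    return ScenarioSpec(f"tumor_{key}", _TUMOR_INFLOWS[key])


#: The complete preset registry: wound healing plus the six tumor variants.
SCENARIOS: dict[str, ScenarioSpec] = {
    "wound_healing": wound_healing_scenario(),
    **{spec.name: spec for spec in (tumor_scenario(k) for k in _TUMOR_INFLOWS)},
}


def list_scenarios() -> list[str]:
    return list(SCENARIOS)


def get_scenario(name: str) -> ScenarioSpec:
    """Look up a preset by registry name or bare tumor panel letter."""
    if name in SCENARIOS:
        return SCENARIOS[name]
    key = f"tumor_{name.upper()}"
    if key in SCENARIOS:
        return SCENARIOS[key]
    raise ConfigError(
        f"unknown scenario {name!r}; valid names: " + ", ".join(SCENARIOS)
    )


def apply_scenario(config: SimulationConfig, scenario: ScenarioSpec) -> SimulationConfig:
    """Return the config with the scenario's inflow and overrides applied."""
    return config.with_overrides(
        inflow_per_step=scenario.inflow_per_step, **scenario.overrides
    )
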