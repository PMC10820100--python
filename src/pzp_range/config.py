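"""YAML run configuration.

One file drives every pipeline stage; each CLI flag overrides its key.

Recognised top-level keys (all optional)::

    window:          {start_year: 2019, start_month: 1, n_months: 48}
    excluded_areas:  [edge]           # dropped outright from the analysis
    scenarios:       [permanent, 18, 12, 6]
    seed:            0
    simulation:      {...}            # SimulationConfig field overrides
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .data_model import StudyWindow
from .decay import DEFAULT_SCENARIOS, EfficacyScenario
from .simulate import SimulationConfig

__all__ = ["RunConfig", "load_config"]

DEFAULT_EXCLUDED_AREAS = frozenset({"edge"})


@dataclass
class RunConfig:
    window: StudyWindow = field(default_factory=StudyWindow)
    excluded_areas: frozenset[str] = DEFAULT_EXCLUDED_AREAS
    scenarios: tuple[EfficacyScenario, ...] = DEFAULT_SCENARIOS
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")


def _simulation_config(mapping: dict, seed: int, window: StudyWindow) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown simulation option(s): {', '.join(sorted(unknown))}")
    kwargs = dict(mapping)
    if "monthly_conception_hazard" in kwargs:
        kwargs["monthly_conception_hazard"] = tuple(kwargs["monthly_conception_hazard"])
    kwargs.setdefault("seed", seed)
    kwargs["window"] = window
    return SimulationConfig(**kwargs)


def load_config(path: str | Path | None = None, *, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``seed`` (e.g. a CLI flag) wins over the file."""
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    window = StudyWindow(**raw.get("window", {}))
    eff_seed = seed if seed is not None else int(raw.get("seed", 0))
    scenarios = tuple(
        EfficacyScenario.parse(s) for s in raw.get("scenarios", [])
    ) or DEFAULT_SCENARIOS
    return RunConfig(
        window=window,
        excluded_areas=frozenset(raw.get("excluded_areas", DEFAULT_EXCLUDED_AREAS)),
        scenarios=scenarios,
        seed=eff_seed,
        simulation=_simulation_config(raw.get("simulation", {}), eff_seed, window),
    )
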