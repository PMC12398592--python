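"""Run configuration: YAML round-trip and named presets.

A :class:`RunConfig` captures everything needed to reproduce a run: the
problem (and scenario), the data source (a synthetic density/noise setting
or a measurement file), the number of starts and master seed, the sampling
ranges, solver choice and tolerances, the epoch budgets and the evaluation
options.  Presets ship the published multi-start settings per problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .training import (
    Budget,
    HyperRanges,
    GLYCOLYSIS_RANGES,
    STAT5_SCENARIO123_RANGES,
    STAT5_SCENARIO4_RANGES,
)
from .models import PROBLEM_REGISTRY

__all__ = ["RunConfig", "PRESETS", "load_config", "save_config"]


@dataclass
class RunConfig:
    problem: str = "glycolysis_ude"
    #: synthetic data setting (glycolysis) ...
    n_points: int = 46
    noise_percent: float = 5.0
    data_seed: int = 0
    #: ... or a measurement table path (takes precedence when set)
    measurement_file: Optional[str] = None
    n_starts: int = 100
    seed: int = 1
    ranges: HyperRanges = field(default_factory=HyperRanges)
    solver: Optional[str] = None  # nonstiff | stiff | None (problem default)
    rtol: float = 1e-6
    atol: float = 1e-8
    budget: Budget = field(default_factory=Budget)
    dt_max: Optional[float] = None
    success_threshold: float = 0.15
    bound_factor: float = 5.0

    def __post_init__(self):
        if self.problem not in PROBLEM_REGISTRY:
            raise ValueError(
                f"unknown problem {self.problem!r}; choose from {PROBLEM_REGISTRY}"
            )
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ranges" in d and isinstance(d["ranges"], dict):
            r = dict(d["ranges"])
            for key in ("hidden_layers", "widths", "activations", "input_normalisation"):
                if key in r and r[key] is not None:
                    r[key] = tuple(r[key])
            for key in ("learning_rate_range", "lam_range"):
                if key in r and r[key] is not None:
                    r[key] = tuple(r[key])
            d["ranges"] = HyperRanges(**r)
        if "budget" in d and isinstance(d["budget"], dict):
            d["budget"] = Budget(**d["budget"])
        return cls(**d)


PRESETS = {
    "glycolysis": RunConfig(problem="glycolysis_ude", ranges=GLYCOLYSIS_RANGES),
    "stat5_scenario1": RunConfig(
        problem="stat5_scenario1", ranges=STAT5_SCENARIO123_RANGES, n_starts=3000
    ),
    "stat5_scenario2": RunConfig(
        problem="stat5_scenario2", ranges=STAT5_SCENARIO123_RANGES, n_starts=3000
    ),
    "stat5_scenario3": RunConfig(
        problem="stat5_scenario3", ranges=STAT5_SCENARIO123_RANGES, n_starts=3000
    ),
    "stat5_scenario4": RunConfig(
        problem="stat5_scenario4", ranges=STAT5_SCENARIO4_RANGES, n_starts=30000
    ),
}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
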