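"""Built-in model definitions and the problem registry."""

from __future__ import annotations

from ..nn import ANNSpec
from .base import UDEProblem
from .glycolysis import (
    GlycolysisConstants,
    REFERENCE_CONSTANTS,
    REFERENCE_X0,
    build_glycolysis_ode,
    build_glycolysis_ude,
    glycolysis_parameter_set,
    glycolysis_rhs,
)
from .stat5 import (
    STAT5Constants,
    REFERENCE_PARAMETERS,
    REFERENCE_SIGMA,
    build_stat5_ode,
    build_stat5_scenario,
    epo_input,
    stat5_observables,
    stat5_rhs,
    stat5_x0,
)

__all__ = [
    "UDEProblem",
    "GlycolysisConstants",
    "STAT5Constants",
    "REFERENCE_CONSTANTS",
    "REFERENCE_X0",
    "REFERENCE_PARAMETERS",
    "REFERENCE_SIGMA",
    "glycolysis_rhs",
    "glycolysis_parameter_set",
    "build_glycolysis_ode",
    "build_glycolysis_ude",
    "build_stat5_ode",
    "build_stat5_scenario",
    "epo_input",
    "stat5_observables",
    "stat5_rhs",
    "stat5_x0",
    "get_problem",
    "PROBLEM_REGISTRY",
]


def get_problem(name: str, ann_spec: ANNSpec | None = None, **kwargs) -> UDEProblem:
    """Build a registered problem by name.

    Names: ``glycolysis``, ``glycolysis_ude``, ``stat5``,
    ``stat5_scenario1`` .. ``stat5_scenario4``.  Hybrid problems require an
    ``ann_spec``.
    """
    if name == "glycolysis":
        return build_glycolysis_ode(**kwargs)
    if name == "glycolysis_ude":
        if ann_spec is None:
            raise ValueError("glycolysis_ude requires an ann_spec")
        return build_glycolysis_ude(ann_spec, **kwargs)
    if name == "stat5":
        return build_stat5_ode(**kwargs)
    if name.startswith("stat5_scenario"):
        n = int(name.removeprefix("stat5_scenario"))
        if ann_spec is None:
            raise ValueError(f"{name} requires an ann_spec")
        return build_stat5_scenario(n, ann_spec, **kwargs)
    raise KeyError(f"unknown problem {name!r}")


PROBLEM_REGISTRY = [
    "glycolysis",
    "glycolysis_ude",
    "stat5",
    "stat5_scenario1",
    "stat5_scenario2",
    "stat5_scenario3",
    "stat5_scenario4",
]
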