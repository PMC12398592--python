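"""Yeast glycolysis oscillator and its hybrid variant.

The mechanistic model is the seven-species description of glycolytic
oscillations by Ruoff and co-workers: glucose influx J0 feeds a chain
S1 -> S2 -> S3 -> S4 with NADH (N2) and ATP (A3) cycling, an allosterically
inhibited first step (Hill factor ``A3 / (1 + (A3/K1)^4)``), exchange of S4
with the extracellular pool S4_ex, and a first-order ATP drain ``k5 * A3``.
With the published parameterisation the system settles on a stable limit
cycle with period ~1.17 time units; species N2 and A3 are directly observed.

The hybrid variant treats the ATP drain as unknown: the term ``-k5 * A3`` is
removed from dA3/dt and replaced by a neural network that receives all seven
states, so recovering the truth requires the network to learn a dependency
on a single input.  Twelve parameters are free in the mechanistic model
(the eleven printed rate symbols plus the conserved adenine total A; the
NAD(H) total N is fixed at 1); the hybrid model estimates eleven, k5 having
been replaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import ANNSpec
from ..parameters import MechanisticParameterSet
from .base import UDEProblem

__all__ = [
    "GlycolysisConstants",
    "REFERENCE_CONSTANTS",
    "REFERENCE_X0",
    "glycolysis_rhs",
    "glycolysis_parameter_set",
    "build_glycolysis_ode",
    "build_glycolysis_ude",
]

STATE_NAMES = ["S1", "S2", "S3", "S4", "N2", "A3", "S4_ex"]
OBSERVABLE_NAMES = ["N2", "A3"]
OBSERVABLE_INDICES = np.array([4, 5])

#: NAD(H) conservation total, held fixed.
N_TOTAL = 1.0

ODE_PARAMETER_NAMES = [
    "J0", "k1", "k2", "k3", "k4", "k5", "k6", "K1", "kappa", "phi", "k_ex", "A",
]
UDE_PARAMETER_NAMES = [n for n in ODE_PARAMETER_NAMES if n != "k5"]


@dataclass(frozen=True)
class GlycolysisConstants:
    """Rate constants and conserved totals of the glycolysis model."""

    J0: float = 2.5
    k1: float = 100.0
    k2: float = 6.0
    k3: float = 16.0
    k4: float = 100.0
    k5: float = 1.28
    k6: float = 12.0
    K1: float = 0.52
    kappa: float = 13.0
    phi: float = 0.1
    k_ex: float = 1.8
    N: float = N_TOTAL
    A: float = 4.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")


#: Published reference parameterisation (oscillatory regime).
REFERENCE_CONSTANTS = GlycolysisConstants()

#: Known initial state: a point on the limit cycle of the reference
#: parameterisation, frozen from a converged long simulation.
REFERENCE_X0 = np.array(
    [1.4094771, 0.21893153, 0.04151773, 0.09867744, 0.0855288, 2.1988729, 0.06600546]
)


def glycolysis_rhs(t, x, c: GlycolysisConstants):
    """Right-hand side of the full mechanistic model (dataclass constants)."""
    theta = np.array([getattr(c, n) for n in ODE_PARAMETER_NAMES])
    return _rhs(t, x, theta, include_k5=True, N=c.N)


def _index(names, include_k5):
    return {n: i for i, n in enumerate(names)}


def _rhs(t, x, theta, include_k5: bool, N: float = N_TOTAL):
    names = ODE_PARAMETER_NAMES if include_k5 else UDE_PARAMETER_NAMES
    p = dict(zip(names, theta))
    S1, S2, S3, S4, N2, A3, S4e = x
    u = (A3 / p["K1"]) ** 4
    hill = A3 / (1.0 + u)
    v1 = p["k1"] * S1 * hill
    v2 = p["k2"] * S2 * (N - N2)
    v3 = p["k3"] * S3 * (p["A"] - A3)
    v4 = p["k4"] * S4 * N2
    v6 = p["k6"] * S2 * N2
    ex = p["kappa"] * (S4 - S4e)
    dA3 = -2.0 * v1 + 2.0 * v3
    if include_k5:
        dA3 -= p["k5"] * A3
    return np.array(
        [
            p["J0"] - v1,
            2.0 * v1 - v2 - v6,
            v2 - v3,
            v3 - v4 - ex,
            v2 - v4 - v6,
            dA3,
            p["phi"] * ex - p["k_ex"] * S4e,
        ]
    )


def _jac_x(t, x, theta, include_k5: bool, N: float = N_TOTAL):
    names = ODE_PARAMETER_NAMES if include_k5 else UDE_PARAMETER_NAMES
    p = dict(zip(names, theta))
    S1, S2, S3, S4, N2, A3, S4e = x
    u = (A3 / p["K1"]) ** 4
    denom = (1.0 + u) ** 2
    hill = A3 / (1.0 + u)
    dhill = (1.0 - 3.0 * u) / denom
    k1, k2, k3, k4, k6 = p["k1"], p["k2"], p["k3"], p["k4"], p["k6"]
    kap = p["kappa"]
    J = np.zeros((7, 7))
    # dS1/dt
    J[0, 0] = -k1 * hill
    J[0, 5] = -k1 * S1 * dhill
    # dS2/dt
    J[1, 0] = 2.0 * k1 * hill
    J[1, 1] = -k2 * (N - N2) - k6 * N2
    J[1, 4] = k2 * S2 - k6 * S2
    J[1, 5] = 2.0 * k1 * S1 * dhill
    # dS3/dt
    J[2, 1] = k2 * (N - N2)
    J[2, 2] = -k3 * (p["A"] - A3)
    J[2, 4] = -k2 * S2
    J[2, 5] = k3 * S3
    # dS4/dt
    J[3, 2] = k3 * (p["A"] - A3)
    J[3, 3] = -k4 * N2 - kap
    J[3, 4] = -k4 * S4
    J[3, 5] = -k3 * S3
    J[3, 6] = kap
    # dN2/dt
    J[4, 1] = k2 * (N - N2) - k6 * N2
    J[4, 3] = -k4 * N2
    J[4, 4] = -k2 * S2 - k4 * S4 - k6 * S2
    # dA3/dt
    J[5, 0] = -2.0 * k1 * hill
    J[5, 2] = 2.0 * k3 * (p["A"] - A3)
    J[5, 5] = -2.0 * k1 * S1 * dhill - 2.0 * k3 * S3
    if include_k5:
        J[5, 5] -= p["k5"]
    # dS4_ex/dt
    J[6, 3] = p["phi"] * kap
    J[6, 6] = -p["phi"] * kap - p["k_ex"]
    return J


def _jac_theta(t, x, theta, include_k5: bool, N: float = N_TOTAL):
    names = ODE_PARAMETER_NAMES if include_k5 else UDE_PARAMETER_NAMES
    p = dict(zip(names, theta))
    idx = {n: i for i, n in enumerate(names)}
    S1, S2, S3, S4, N2, A3, S4e = x
    K1 = p["K1"]
    u = (A3 / K1) ** 4
    denom = (1.0 + u) ** 2
    hill = A3 / (1.0 + u)
    dhill_dK1 = A3 * 4.0 * u / (K1 * denom)
    J = np.zeros((7, len(names)))
    J[0, idx["J0"]] = 1.0
    s1h = S1 * hill
    J[0, idx["k1"]] = -s1h
    J[1, idx["k1"]] = 2.0 * s1h
    J[5, idx["k1"]] = -2.0 * s1h
    s2n = S2 * (N - N2)
    J[1, idx["k2"]] = -s2n
    J[2, idx["k2"]] = s2n
    J[4, idx["k2"]] = s2n
    s3a = S3 * (p["A"] - A3)
    J[2, idx["k3"]] = -s3a
    J[3, idx["k3"]] = s3a
    J[5, idx["k3"]] = 2.0 * s3a
    s4n = S4 * N2
    J[3, idx["k4"]] = -s4n
    J[4, idx["k4"]] = -s4n
    if include_k5:
        J[5, idx["k5"]] = -A3
    s2n2 = S2 * N2
    J[1, idx["k6"]] = -s2n2
    J[4, idx["k6"]] = -s2n2
    dK1 = p["k1"] * S1 * dhill_dK1
    J[0, idx["K1"]] = -dK1
    J[1, idx["K1"]] = 2.0 * dK1
    J[5, idx["K1"]] = -2.0 * dK1
    ex = S4 - S4e
    J[3, idx["kappa"]] = -ex
    J[6, idx["kappa"]] = p["phi"] * ex
    J[6, idx["phi"]] = p["kappa"] * ex
    J[6, idx["k_ex"]] = -S4e
    k3s3 = p["k3"] * S3
    J[2, idx["A"]] = -k3s3
    J[3, idx["A"]] = k3s3
    J[5, idx["A"]] = 2.0 * k3s3
    return J


def glycolysis_parameter_set(
    include_k5: bool = True, bound_factor: float = 5.0
) -> MechanisticParameterSet:
    """Bounded free-parameter metadata around the reference values.

    Bounds are ``[ref / bound_factor, ref * bound_factor]`` per parameter, a
    synthetic stand-in for published per-parameter bounds.
    """
    names = ODE_PARAMETER_NAMES if include_k5 else UDE_PARAMETER_NAMES
    ref = np.array([getattr(REFERENCE_CONSTANTS, n) for n in names])
    return MechanisticParameterSet(
        names=list(names),
        values=ref,
        lower_bounds=ref / bound_factor,
        upper_bounds=ref * bound_factor,
    )


def build_glycolysis_ode(bound_factor: float = 5.0) -> UDEProblem:
    """The fully mechanistic reference problem (no network)."""
    return UDEProblem(
        name="glycolysis",
        state_names=list(STATE_NAMES),
        observable_names=list(OBSERVABLE_NAMES),
        x0=REFERENCE_X0.copy(),
        parameters=glycolysis_parameter_set(include_k5=True, bound_factor=bound_factor),
        rhs_mechanistic=lambda t, x, th: _rhs(t, x, th, include_k5=True),
        rhs_jac_x=lambda t, x, th: _jac_x(t, x, th, include_k5=True),
        rhs_jac_theta=lambda t, x, th: _jac_theta(t, x, th, include_k5=True),
        observable_indices=OBSERVABLE_INDICES.copy(),
        t_span=(0.0, 5.0),
        stiff=False,
        dt_max=0.01,
    )


def build_glycolysis_ude(
    ann_spec: ANNSpec, bound_factor: float = 5.0
) -> UDEProblem:
    """Hybrid problem: ATP drain removed, network added to dA3/dt.

    The network must have seven inputs (the full state) and one output.
    """
    if ann_spec.n_inputs != 7 or ann_spec.n_outputs != 1:
        raise ValueError(
            "glycolysis hybrid model requires a 7-input, 1-output network, "
            f"got {ann_spec.n_inputs}->{ann_spec.n_outputs}"
        )
    placement = np.zeros((7, 1))
    placement[5, 0] = 1.0  # network output enters dA3/dt
    return UDEProblem(
        name="glycolysis_ude",
        state_names=list(STATE_NAMES),
        observable_names=list(OBSERVABLE_NAMES),
        x0=REFERENCE_X0.copy(),
        parameters=glycolysis_parameter_set(include_k5=False, bound_factor=bound_factor),
        rhs_mechanistic=lambda t, x, th: _rhs(t, x, th, include_k5=False),
        rhs_jac_x=lambda t, x, th: _jac_x(t, x, th, include_k5=False),
        rhs_jac_theta=lambda t, x, th: _jac_theta(t, x, th, include_k5=False),
        ann_spec=ann_spec,
        ann_state_matrix=placement,
        ann_input_indices=np.arange(7),
        observable_indices=OBSERVABLE_INDICES.copy(),
        t_span=(0.0, 5.0),
        stiff=False,
        dt_max=0.01,
    )
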