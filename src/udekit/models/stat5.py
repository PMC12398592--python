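"""STAT5 dimerisation model and its four hybrid scenarios.

Upon erythropoietin (Epo) stimulation, cytoplasmic STAT5A and STAT5B are
phosphorylated and associate into homo- (pApA, pBpB) and hetero-dimers
(pApB) that are imported into the nucleus (nucpApA, nucpBpB, nucpApB),
where they dissociate and are exported back as monomers.  Import/export
between cytoplasm (volume 1.4) and nucleus (volume 0.45) carries the volume
ratio in the rate terms.  The stimulus enters as a decaying input
``BaF3_Epo(t) = 1.25e-7 * exp(-Epo_degradation_BaF3 * t)``.  Measurements
are relative phosphorylation ratios (with antibody specificity constant
specC17 = 0.107), a strongly nonlinear observable mapping.

Six kinetic parameters are estimated (plus one noise standard deviation per
observable, nine parameters in total).  The four hybrid scenarios each
remove or augment one piece of mechanism with a network:

1. the export/dissociation of nuclear pApA, with a mass-conservation
   constraint built into the placement (one network output entering
   dSTAT5A/dt with factor +2 V_nuc/V_cyt and dnucpApA/dt with factor -1);
2. the entire rate of change of pApB;
3. three augmentation species K_A, K_B, K_AB with network-driven dynamics
   feeding mass-action export into the monomers (two-stage training);
4. the observable mapping of the measured STAT5A ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import ANNSpec
from ..parameters import MechanisticParameterSet
from .base import UDEProblem

__all__ = [
    "STAT5Constants",
    "V_CYT",
    "V_NUC",
    "SPEC_C17",
    "REFERENCE_PARAMETERS",
    "REFERENCE_SIGMA",
    "stat5_x0",
    "epo_input",
    "stat5_rhs",
    "stat5_observables",
    "build_stat5_ode",
    "build_stat5_scenario",
]

V_CYT = 1.4
V_NUC = 0.45
SPEC_C17 = 0.107

STATE_NAMES = [
    "STAT5A", "STAT5B", "pApA", "pBpB", "pApB", "nucpApA", "nucpBpB", "nucpApB",
]
OBSERVABLE_NAMES = ["pSTAT5A_rel", "pSTAT5B_rel", "rSTAT5A_rel"]

PARAMETER_NAMES = [
    "Epo_degradation_BaF3",
    "k_exp_hetero",
    "k_exp_homo",
    "k_imp_hetero",
    "k_imp_homo",
    "k_phos",
]
AUG_PARAMETER_NAMES = ["k_exp_aug_A", "k_exp_aug_B", "k_exp_aug_AB"]

#: Published maximum-likelihood estimates (linear scale).
REFERENCE_PARAMETERS = {
    "Epo_degradation_BaF3": 10.0 ** -1.568917588,
    "k_exp_hetero": 10.0 ** -4.999704894,
    "k_exp_homo": 10.0 ** -2.209698782,
    "k_imp_hetero": 10.0 ** -1.786006548,
    "k_imp_homo": 10.0 ** 4.990114009,
    "k_phos": 10.0 ** 4.197735488,
}
#: Published noise standard deviations per observable.
REFERENCE_SIGMA = np.array(
    [10.0 ** 0.585755271, 10.0 ** 0.818982819, 10.0 ** 0.498684404]
)

_TOTAL_STAT5 = 207.6
_RATIO_A = 0.693


@dataclass(frozen=True)
class STAT5Constants:
    """Kinetic rates plus the fixed volumes and antibody specificity."""

    k_phos: float
    k_imp_homo: float
    k_imp_hetero: float
    k_exp_homo: float
    k_exp_hetero: float
    Epo_degradation_BaF3: float
    k_exp_aug_A: float = 1.0
    k_exp_aug_B: float = 1.0
    k_exp_aug_AB: float = 1.0
    V_cyt: float = V_CYT
    V_nuc: float = V_NUC
    specC17: float = SPEC_C17

    def __post_init__(self):
        if (self.V_cyt, self.V_nuc, self.specC17) != (V_CYT, V_NUC, SPEC_C17):
            raise ValueError("V_cyt, V_nuc and specC17 are fixed constants")
        for name in (
            "k_phos", "k_imp_homo", "k_imp_hetero", "k_exp_homo",
            "k_exp_hetero", "Epo_degradation_BaF3",
            "k_exp_aug_A", "k_exp_aug_B", "k_exp_aug_AB",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name} must be positive")


def stat5_x0(n_states: int = 8) -> np.ndarray:
    """Known initial state: unphosphorylated monomers only."""
    x0 = np.zeros(n_states)
    x0[0] = _TOTAL_STAT5 * _RATIO_A
    x0[1] = _TOTAL_STAT5 * (1.0 - _RATIO_A)
    return x0


def epo_input(t, Epo_degradation_BaF3: float):
    """Decaying Epo stimulus concentration."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    return 1.25e-07 * np.exp(-Epo_degradation_BaF3 * np.asarray(t, dtype=float))


def _params(theta, names):
    return dict(zip(names, theta))


def stat5_rhs(t, x, theta, names=PARAMETER_NAMES):
    """Right-hand side of the original eight-state model."""
    p = _params(theta, names)
    A, B, pAA, pBB, pAB, nAA, nBB, nAB = x[:8]
    E = 1.25e-07 * np.exp(-p["Epo_degradation_BaF3"] * t)
    kph = p["k_phos"]
    r = V_NUC / V_CYT
    ri = V_CYT / V_NUC
    vAA = E * A * A * kph
    vAB = E * A * B * kph
    vBB = E * B * B * kph
    return np.array(
        [
            -2.0 * vAA - vAB + 2.0 * r * p["k_exp_homo"] * nAA
            + r * p["k_exp_hetero"] * nAB,
            -vAB - 2.0 * vBB + r * p["k_exp_hetero"] * nAB
            + 2.0 * r * p["k_exp_homo"] * nBB,
            vAA - p["k_imp_homo"] * pAA,
            vBB - p["k_imp_homo"] * pBB,
            vAB - p["k_imp_hetero"] * pAB,
            ri * p["k_imp_homo"] * pAA - p["k_exp_homo"] * nAA,
            ri * p["k_imp_homo"] * pBB - p["k_exp_homo"] * nBB,
            ri * p["k_imp_hetero"] * pAB - p["k_exp_hetero"] * nAB,
        ]
    )


def stat5_observables(x, specC17: float = SPEC_C17):
    """Relative phosphorylation ratios (vectorised over rows of ``x``)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    A, B = x[:, 0], x[:, 1]
    pAA, pBB, pAB = x[:, 2], x[:, 3], x[:, 4]
    c = specC17
    d1 = pAB + A * c + 2.0 * pAA * c
    d2 = (B * (c - 1.0) - pAB) + 2.0 * pBB * (c - 1.0)
    d3 = 2.0 * pAB + A * c + 2.0 * pAA * c - B * (c - 1.0) - 2.0 * pBB * (c - 1.0)
    if np.any(d1 == 0) or np.any(d2 == 0) or np.any(d3 == 0):
        raise ZeroDivisionError("observable mapping denominator is zero")
    y1 = (100.0 * pAB + 200.0 * pAA * c) / d1
    y2 = -(100.0 * pAB - 200.0 * pBB * (c - 1.0)) / d2
    y3 = (100.0 * pAB + 100.0 * A * c + 200.0 * pAA * c) / d3
    return np.column_stack([y1, y2, y3])


def _parameter_set(names) -> MechanisticParameterSet:
    ref = np.array([REFERENCE_PARAMETERS.get(n, 1.0) for n in names])
    return MechanisticParameterSet(
        names=list(names),
        values=ref,
        lower_bounds=np.full(len(names), 1e-5),
        upper_bounds=np.full(len(names), 1e5),
    )


def _obs_fn(t, states, theta):
    return stat5_observables(states)


def build_stat5_ode() -> UDEProblem:
    """The fully mechanistic reference problem."""
    return UDEProblem(
        name="stat5",
        state_names=list(STATE_NAMES),
        observable_names=list(OBSERVABLE_NAMES),
        x0=stat5_x0(),
        parameters=_parameter_set(PARAMETER_NAMES),
        rhs_mechanistic=lambda t, x, th: stat5_rhs(t, x, th),
        observable_fn=_obs_fn,
        t_span=(0.0, 240.0),
        stiff=True,
    )


def _scenario1_rhs(t, x, theta):
    dx = stat5_rhs(t, x, theta)
    p = _params(theta, PARAMETER_NAMES)
    r = V_NUC / V_CYT
    # remove the mechanistic nucpApA export that the network replaces
    dx[0] -= 2.0 * r * p["k_exp_homo"] * x[5]
    dx[5] += p["k_exp_homo"] * x[5]
    return dx


def _scenario2_rhs(t, x, theta):
    dx = stat5_rhs(t, x, theta)
    dx[4] = 0.0  # d pApB/dt is entirely the network's
    return dx


def _scenario3_rhs(t, x, theta):
    names = PARAMETER_NAMES + AUG_PARAMETER_NAMES
    p = _params(theta, names)
    dx8 = stat5_rhs(t, x[:8], theta[: len(PARAMETER_NAMES)])
    KA, KB, KAB = x[8], x[9], x[10]
    dx = np.zeros(11)
    dx[:8] = dx8
    dx[0] += p["k_exp_aug_A"] * KA + p["k_exp_aug_AB"] * KAB
    dx[1] += p["k_exp_aug_B"] * KB + p["k_exp_aug_AB"] * KAB
    dx[8] = -p["k_exp_aug_A"] * KA
    dx[9] = -p["k_exp_aug_B"] * KB
    dx[10] = -p["k_exp_aug_AB"] * KAB
    return dx


def build_stat5_scenario(n: int, ann_spec: ANNSpec) -> UDEProblem:
    """Hybrid STAT5 problem for scenario ``n`` in 1..4.

    Required network dimensions: scenario 1: 8->1 (all states); scenario 2:
    9->1 (all states plus the Epo stimulus); scenario 3: 6->6 (the three
    nuclear dimers and the three augmentation species); scenario 4: 8->1
    (all states, replacing the measured STAT5A-ratio observable).
    """
    expected = {1: (8, 1), 2: (9, 1), 3: (6, 6), 4: (8, 1)}
    if n not in expected:
        raise ValueError(f"scenario must be 1..4, got {n}")
    if (ann_spec.n_inputs, ann_spec.n_outputs) != expected[n]:
        raise ValueError(
            f"scenario {n} requires a {expected[n][0]}->{expected[n][1]} network, "
            f"got {ann_spec.n_inputs}->{ann_spec.n_outputs}"
        )
    common = dict(
        observable_names=list(OBSERVABLE_NAMES),
        observable_fn=_obs_fn,
        t_span=(0.0, 240.0),
        stiff=True,
    )
    if n == 1:
        placement = np.zeros((8, 1))
        placement[0, 0] = 2.0 * V_NUC / V_CYT
        placement[5, 0] = -1.0
        return UDEProblem(
            name="stat5_scenario1",
            state_names=list(STATE_NAMES),
            x0=stat5_x0(),
            parameters=_parameter_set(PARAMETER_NAMES),
            rhs_mechanistic=_scenario1_rhs,
            ann_spec=ann_spec,
            ann_state_matrix=placement,
            ann_input_indices=np.arange(8),
            **common,
        )
    if n == 2:
        placement = np.zeros((8, 1))
        placement[4, 0] = 1.0
        idx_epo = PARAMETER_NAMES.index("Epo_degradation_BaF3")
        return UDEProblem(
            name="stat5_scenario2",
            state_names=list(STATE_NAMES),
            x0=stat5_x0(),
            parameters=_parameter_set(PARAMETER_NAMES),
            rhs_mechanistic=_scenario2_rhs,
            ann_spec=ann_spec,
            ann_state_matrix=placement,
            ann_input_indices=np.arange(8),
            ann_time_inputs=lambda t, th: np.array([epo_input(t, th[idx_epo])]),
            **common,
        )
    if n == 3:
        placement = np.zeros((11, 6))
        # network outputs 1..6 drive nucpApA, nucpBpB, nucpApB, K_A, K_B, K_AB
        for col, state in enumerate([5, 6, 7, 8, 9, 10]):
            placement[state, col] = 1.0
        return UDEProblem(
            name="stat5_scenario3",
            state_names=list(STATE_NAMES) + ["K_A", "K_B", "K_AB"],
            x0=stat5_x0(11),
            parameters=_parameter_set(PARAMETER_NAMES + AUG_PARAMETER_NAMES),
            rhs_mechanistic=_scenario3_rhs,
            ann_spec=ann_spec,
            ann_state_matrix=placement,
            # input order: nucpApA, nucpApB, nucpBpB, then the augmentations
            ann_input_indices=np.array([5, 7, 6, 8, 9, 10]),
            **common,
        )
    # scenario 4: fully mechanistic dynamics, network as observable mapping
    return UDEProblem(
        name="stat5_scenario4",
        state_names=list(STATE_NAMES),
        x0=stat5_x0(),
        parameters=_parameter_set(PARAMETER_NAMES),
        rhs_mechanistic=lambda t, x, th: stat5_rhs(t, x, th),
        ann_spec=ann_spec,
        ann_input_indices=np.arange(8),
        ann_observable_index=2,
        **common,
    )
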