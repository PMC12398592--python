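"""Hybrid ODE problem container.

A ``UDEProblem`` bundles the mechanistic right-hand side, the placement of
the neural-network term (which states its outputs enter, with what signs and
stoichiometric factors), the observable mapping, the known initial state and
the bounded mechanistic parameter metadata.  The network contribution is
additive:

    dx/dt = f_M(t, x, theta_M) + B @ f_ANN(u(t, x), theta_ANN)

where ``B`` is the (n_states x n_outputs) placement matrix and ``u`` selects
the network inputs (a subset of states, optionally extended with known
time-dependent signals such as an external stimulus).  A network can instead
replace a single observable, in which case it does not enter the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ..nn import ANNParameters, ANNSpec, ann_forward
from ..parameters import MechanisticParameterSet

__all__ = ["UDEProblem"]


@dataclass
class UDEProblem:
    name: str
    state_names: list[str]
    observable_names: list[str]
    x0: np.ndarray
    parameters: MechanisticParameterSet
    rhs_mechanistic: Callable
    #: analytic d f_M / d x, (n_s, n_s); finite differences if None
    rhs_jac_x: Optional[Callable] = None
    #: analytic d f_M / d theta_M, (n_s, n_m); finite differences if None
    rhs_jac_theta: Optional[Callable] = None
    ann_spec: Optional[ANNSpec] = None
    #: placement matrix B, (n_s, n_outputs); None if the network is not in the RHS
    ann_state_matrix: Optional[np.ndarray] = None
    #: state indices fed to the network, in input order
    ann_input_indices: Optional[np.ndarray] = None
    #: extra known time signals appended to the network input, (t, theta) -> vector
    ann_time_inputs: Optional[Callable] = None
    #: linear observable mapping: y = x[observable_indices]
    observable_indices: Optional[np.ndarray] = None
    #: nonlinear observable mapping, (t, x, theta) -> y (vectorised over rows of x)
    observable_fn: Optional[Callable] = None
    #: index of the observable replaced by the network (h_ANN), or None
    ann_observable_index: Optional[int] = None
    t_span: tuple[float, float] = (0.0, 5.0)
    stiff: bool = False
    #: largest step of the fixed-step differentiable integrator
    dt_max: float = 0.01

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (self.n_states,):
            raise ValueError("x0 length must match the number of states")
        if self.ann_state_matrix is not None:
            self.ann_state_matrix = np.asarray(self.ann_state_matrix, dtype=float)
            if self.ann_state_matrix.shape[0] != self.n_states:
                raise ValueError("placement matrix rows must match the states")
        if self.ann_spec is not None:
            n_in = len(self.ann_input_indices) if self.ann_input_indices is not None else 0
            if self.ann_time_inputs is not None:
                n_in += self.n_time_inputs
            if n_in and n_in != self.ann_spec.n_inputs:
                raise ValueError(
                    f"network expects {self.ann_spec.n_inputs} inputs, "
                    f"problem provides {n_in}"
                )
            if self.ann_state_matrix is not None and (
                self.ann_state_matrix.shape[1] != self.ann_spec.n_outputs
            ):
                raise ValueError(
                    "placement matrix columns must match the network outputs"
                )
        if self.ann_input_indices is not None:
            self.ann_input_indices = np.asarray(self.ann_input_indices, dtype=int)
            if self.ann_input_indices.max() >= self.n_states:
                raise ValueError("network input index out of range")

    # -- dimensions ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_observables(self) -> int:
        return len(self.observable_names)

    @property
    def n_time_inputs(self) -> int:
        if self.ann_time_inputs is None:
            return 0
        probe = np.atleast_1d(self.ann_time_inputs(0.0, self.parameters.values))
        return probe.size

    @property
    def ann_in_rhs(self) -> bool:
        return self.ann_spec is not None and self.ann_state_matrix is not None

    # -- evaluation ---------------------------------------------------------
    def ann_inputs(self, t: float, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        u = x[self.ann_input_indices] if self.ann_input_indices is not None else x
        if self.ann_time_inputs is not None:
            u = np.concatenate([u, np.atleast_1d(self.ann_time_inputs(t, theta))])
        return u

    def rhs(
        self,
        t: float,
        x: np.ndarray,
        theta: np.ndarray,
        ann_params: ANNParameters | np.ndarray | None = None,
        ann_override: Callable | None = None,
    ) -> np.ndarray:
        """Full right-hand side, mechanistic plus network term.

        ``ann_override`` replaces the network by an arbitrary callable
        ``g(u) -> outputs`` on the same inputs (used for oracle
        substitution, e.g. re-inserting the exact mechanistic term).
        """
        dx = np.asarray(self.rhs_mechanistic(t, x, theta), dtype=float)
        if self.ann_state_matrix is not None and (
            ann_params is not None or ann_override is not None
        ):
            u = self.ann_inputs(t, x, theta)
            if ann_override is not None:
                out = np.atleast_1d(np.asarray(ann_override(u), dtype=float))
            else:
                out = ann_forward(self.ann_spec, ann_params, u)
            dx = dx + self.ann_state_matrix @ out
        return dx

    def observe(
        self,
        t: np.ndarray,
        states: np.ndarray,
        theta: np.ndarray,
        ann_params: ANNParameters | np.ndarray | None = None,
    ) -> np.ndarray:
        """Observable trajectory, (n_t, n_o), from a state trajectory."""
        states = np.atleast_2d(states)
        if self.observable_indices is not None:
            y = states[:, self.observable_indices].copy()
        else:
            y = np.asarray(self.observable_fn(t, states, theta), dtype=float)
        if self.ann_observable_index is not None and ann_params is not None:
            col = np.array(
                [
                    ann_forward(
                        self.ann_spec,
                        ann_params,
                        self.ann_inputs(ti, xi, theta),
                    )[0]
                    for ti, xi in zip(np.atleast_1d(t), states)
                ]
            )
            y[:, self.ann_observable_index] = col
        return y

    def free_parameter_names(self) -> list[str]:
        return list(self.parameters.names)
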