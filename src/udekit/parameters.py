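"""Parameter containers for hybrid ODE models.

A full model carries three parameter blocks: the bounded mechanistic rate
constants (estimated on the unconstrained tanh coordinate), the flat network
weight vector, and one noise standard deviation per observable (estimated as
``log sigma`` so positivity holds by construction).  ``ParameterVector``
packs the three blocks into a single flat vector in the order
``[rho, theta_ann, log_sigma]`` for generic gradient-based optimisers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import ANNParameters
from .transforms import (
    choose_offset,
    inverse_transform,
    transform_jacobian,
    transform_parameter,
)

__all__ = ["MechanisticParameterSet", "NoiseParameters", "ParameterVector"]


@dataclass
class MechanisticParameterSet:
    """Named, bounded mechanistic parameters with their tanh-transform offsets."""

    names: list[str]
    values: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    offsets: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        n = len(self.names)
        for arr, what in [
            (self.values, "values"),
            (self.lower_bounds, "lower_bounds"),
            (self.upper_bounds, "upper_bounds"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"{what} must have length {n}, got {arr.shape}")
        if not np.all(self.lower_bounds < self.upper_bounds):
            raise ValueError("require lower_bounds < upper_bounds elementwise")
        if not np.all(
            (self.lower_bounds <= self.values) & (self.values <= self.upper_bounds)
        ):
            raise ValueError("values must lie within the bounds")
        if self.offsets is None:
            self.offsets = choose_offset(self.lower_bounds, self.upper_bounds)
        self.offsets = np.atleast_1d(np.asarray(self.offsets, dtype=float))

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_rho(self, values=None) -> np.ndarray:
        """Map natural-scale values to the unconstrained coordinate."""
        v = self.values if values is None else np.asarray(values, dtype=float)
        return inverse_transform(v, self.lower_bounds, self.upper_bounds, self.offsets)

    def from_rho(self, rho) -> np.ndarray:
        return transform_parameter(
            rho, self.lower_bounds, self.upper_bounds, self.offsets
        )

    def rho_jacobian(self, rho) -> np.ndarray:
        """Diagonal d(theta)/d(rho) for the chain rule."""
        return transform_jacobian(
            rho, self.lower_bounds, self.upper_bounds, self.offsets
        )

    def replace_values(self, values) -> "MechanisticParameterSet":
        return MechanisticParameterSet(
            names=list(self.names),
            values=np.asarray(values, dtype=float),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            offsets=self.offsets.copy(),
        )


@dataclass
class NoiseParameters:
    """One additive-Gaussian standard deviation per observable."""

    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if not np.all(self.sigma > 0):
            raise ValueError("noise standard deviations must be positive")


@dataclass
class ParameterVector:
    """The full estimation vector of a hybrid model.

    Packing order of :meth:`pack`: mechanistic coordinates ``rho``, then the
    flat network weights, then ``log sigma`` per observable.
    """

    mechanistic: MechanisticParameterSet
    ann: ANNParameters | None
    noise: NoiseParameters

    @property
    def n_mechanistic(self) -> int:
        return len(self.mechanistic)

    @property
    def n_ann(self) -> int:
        return 0 if self.ann is None else self.ann.n_ann

    @property
    def n_noise(self) -> int:
        return self.noise.sigma.size

    @property
    def n_total(self) -> int:
        return self.n_mechanistic + self.n_ann + self.n_noise

    def pack(self) -> np.ndarray:
        parts = [self.mechanistic.to_rho()]
        if self.ann is not None:
            parts.append(self.ann.values)
        parts.append(np.log(self.noise.sigma))
        return np.concatenate(parts)

    def unpack(self, flat: np.ndarray) -> "ParameterVector":
        """New ``ParameterVector`` with values taken from a flat vector."""
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_total:
            raise ValueError(f"expected {self.n_total} entries, got {flat.size}")
        n_m, n_a = self.n_mechanistic, self.n_ann
        rho = flat[:n_m]
        mech = self.mechanistic.replace_values(self.mechanistic.from_rho(rho))
        ann = (
            None
            if self.ann is None
            else ANNParameters(values=flat[n_m : n_m + n_a].copy(), n_ann=n_a)
        )
        noise = NoiseParameters(sigma=np.exp(flat[n_m + n_a :]))
        return ParameterVector(mechanistic=mech, ann=ann, noise=noise)

    def split(self, flat: np.ndarray):
        """Views (rho, theta_ann, log_sigma) of a packed vector."""
        n_m, n_a = self.n_mechanistic, self.n_ann
        return flat[:n_m], flat[n_m : n_m + n_a], flat[n_m + n_a :]

    def to_dict(self) -> dict:
        return {
            "mechanistic": dict(
                zip(self.mechanistic.names, self.mechanistic.values.tolist())
            ),
            "ann": None if self.ann is None else self.ann.values.tolist(),
            "sigma": self.noise.sigma.tolist(),
        }
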