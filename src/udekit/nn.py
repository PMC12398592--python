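"""Fully connected feed-forward networks on flat numpy parameter vectors.

The networks used inside hybrid ODE models are small multilayer perceptrons
(1-4 hidden layers, 3-10 neurons each).  Weights live in a single flat
vector so that the whole model -- mechanistic parameters, network weights
and noise parameters -- can be handed to a generic optimiser.  The module
provides initialisation (Glorot-uniform hidden layers, zero output layer so
the hybrid model starts exactly at the mechanistic-only model), the forward
pass, and the reverse-mode pass returning gradients with respect to both the
weights and the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ANNSpec",
    "ANNParameters",
    "ACTIVATIONS",
    "ann_parameter_count",
    "ann_init",
    "ann_forward",
    "ann_forward_cached",
    "ann_vjp",
    "normalise_input",
    "normalise_input_grad",
]

#: Floor constant of the log input normalisation; keeps the logarithm
#: defined for zero or negative network inputs.
NORMALISATION_FLOOR = 1e-20


def normalise_input(x):
    """Elementwise ``log(x + c)`` for positive x, ``log(c)`` otherwise."""
    x = np.asarray(x, dtype=float)
    c = NORMALISATION_FLOOR
    out = np.where(x > 0.0, np.log(np.where(x > 0.0, x, 1.0) + c), np.log(c))
    return float(out) if out.ndim == 0 else out


def normalise_input_grad(x):
    """Derivative of :func:`normalise_input` (zero on the clamped branch)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0.0, 1.0 / (x + NORMALISATION_FLOOR), 0.0)
    return float(out) if out.ndim == 0 else out


def _tanh(z):
    return np.tanh(z)


def _tanh_grad(z, y):
    return 1.0 - y * y


def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z, y):
    return (z > 0.0).astype(float)


def _rbf(z):
    return np.exp(-z * z)


def _rbf_grad(z, y):
    return -2.0 * z * y


def _swish(z):
    return z / (1.0 + np.exp(-z))


def _swish_grad(z, y):
    s = 1.0 / (1.0 + np.exp(-z))
    return s + z * s * (1.0 - s)


#: activation name -> (function, derivative given (pre-activation, output))
ACTIVATIONS = {
    "tanh": (_tanh, _tanh_grad),
    "relu": (_relu, _relu_grad),
    "gaussian-rbf": (_rbf, _rbf_grad),
    "swish": (_swish, _swish_grad),
}


@dataclass(frozen=True)
class ANNSpec:
    """Architecture of a feed-forward network term.

    ``input_normalisation`` applies the elementwise log transform
    :func:`normalise_input` to the inputs before the first layer, a common
    conditioning device when input species span orders of magnitude.
    """

    n_inputs: int
    n_outputs: int
    n_hidden_layers: int = 1
    width: int = 5
    activation: str = "tanh"
    input_normalisation: bool = False

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("network dimensions must be positive")
        if self.n_hidden_layers < 1 or self.width < 1:
            raise ValueError("network dimensions must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(ACTIVATIONS)}"
            )

    @property
    def layer_sizes(self) -> list[int]:
        return [self.n_inputs] + [self.width] * self.n_hidden_layers + [self.n_outputs]


@dataclass
class ANNParameters:
    """Flat weight/bias vector of a network with ``n_ann`` parameters."""

    values: np.ndarray
    n_ann: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_ann:
            raise ValueError(
                f"parameter vector has {self.values.size} entries, expected {self.n_ann}"
            )


def ann_parameter_count(spec: ANNSpec) -> int:
    sizes = spec.layer_sizes
    return sum(
        sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1)
    )


def _unflatten(spec: ANNSpec, flat: np.ndarray):
    """Split a flat vector into per-layer (W, b) pairs; W is (out, in)."""
    sizes = spec.layer_sizes
    layers = []
    k = 0
    for i in range(len(sizes) - 1):
        fan_in, fan_out = sizes[i], sizes[i + 1]
        w = flat[k : k + fan_in * fan_out].reshape(fan_out, fan_in)
        k += fan_in * fan_out
        b = flat[k : k + fan_out]
        k += fan_out
        layers.append((w, b))
    return layers


def ann_init(spec: ANNSpec, seed: int) -> ANNParameters:
    """Glorot-uniform hidden layers; zero output layer and zero biases.

    The zero output layer makes the network output identically zero at
    initialisation, so the hybrid model starts exactly at its mechanistic
    part.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    parts = []
    n_layers = len(sizes) - 1
    for i in range(n_layers):
        fan_in, fan_out = sizes[i], sizes[i + 1]
        if i == n_layers - 1:
            w = np.zeros((fan_out, fan_in))
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(fan_out, fan_in))
        parts.append(w.ravel())
        parts.append(np.zeros(fan_out))
    flat = np.concatenate(parts)
    return ANNParameters(values=flat, n_ann=flat.size)


def ann_forward(spec: ANNSpec, params: ANNParameters | np.ndarray, x) -> np.ndarray:
    """Evaluate the network; linear (no activation) output layer."""
    return ann_forward_cached(spec, params, x)[0]


def ann_forward_cached(spec: ANNSpec, params: ANNParameters | np.ndarray, x):
    """Forward pass returning ``(output, cache)`` for the reverse pass."""
    flat = params.values if isinstance(params, ANNParameters) else np.asarray(params)
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.n_inputs,):
        raise ValueError(
            f"input has shape {x.shape}, expected ({spec.n_inputs},)"
        )
    act, _ = ACTIVATIONS[spec.activation]
    layers = _unflatten(spec, flat)
    raw = x
    if spec.input_normalisation:
        h = normalise_input(x)
    else:
        h = x
    hs, zs = [h], []
    for i, (w, b) in enumerate(layers):
        z = w @ h + b
        if i < len(layers) - 1:
            h = act(z)
        else:
            h = z
        zs.append(z)
        hs.append(h)
    return h, (layers, hs, zs, raw)


def ann_vjp(spec: ANNSpec, cache, cotangent: np.ndarray):
    """Reverse-mode pass.

    Given the ``cache`` from :func:`ann_forward_cached` and a cotangent
    vector ``v`` on the output, returns ``(v @ d out / d weights,
    v @ d out / d inputs)`` as ``(grad_flat, grad_x)``.
    """
    layers, hs, zs, raw = cache
    _, act_grad = ACTIVATIONS[spec.activation]
    delta = np.asarray(cotangent, dtype=float)
    grads = [None] * len(layers)
    for i in range(len(layers) - 1, -1, -1):
        w, b = layers[i]
        grads[i] = (np.outer(delta, hs[i]), delta.copy())
        delta = w.T @ delta
        if i > 0:
            delta = delta * act_grad(zs[i - 1], hs[i])
    grad_x = delta
    if spec.input_normalisation:
        grad_x = grad_x * normalise_input_grad(raw)
    flat = np.concatenate([np.concatenate([gw.ravel(), gb]) for gw, gb in grads])
    return flat, grad_x
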