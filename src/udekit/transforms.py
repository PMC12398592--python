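"""Bounded parameter transforms.

Mechanistic rate constants in biochemical models are positive, span orders of
magnitude and come with domain-knowledge bounds.  To use unconstrained
optimisers we re-parametrise each bounded parameter ``theta`` on an
unconstrained coordinate ``rho`` through a scaled tanh,

    theta = b_l + (tanh(rho - a) + 1) / 2 * (b_u - b_l),

which maps the real line onto the open interval ``(b_l, b_u)`` and, between
the bounds, approximates a log transform.  The offset ``a`` is chosen so that
``rho = 0`` corresponds to ``theta = 1`` whenever the bounds bracket 1 --
the same zero-to-one anchoring a log transform has.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "transform_parameter",
    "choose_offset",
    "inverse_transform",
    "transform_jacobian",
]


def _check_bounds(b_l, b_u) -> None:
    if not np.all(np.asarray(b_l) < np.asarray(b_u)):
        raise ValueError(
            f"invalid parameter bounds: require b_l < b_u, got b_l={b_l}, b_u={b_u}"
        )


def transform_parameter(rho, b_l, b_u, a):
    """Map the unconstrained coordinate ``rho`` to ``theta in (b_l, b_u)``.

    All arguments may be scalars or broadcastable arrays.
    """
    _check_bounds(b_l, b_u)
    return b_l + (np.tanh(np.asarray(rho) - a) + 1.0) / 2.0 * (b_u - b_l)


def choose_offset(b_l, b_u):
    """Offset ``a`` anchoring ``theta = 1`` at ``rho = 0``.

    If the bounds bracket 1 the anchor equation ``transform(0) = 1`` has the
    closed-form solution ``a = -artanh(2 (1 - b_l) / (b_u - b_l) - 1)``.
    When 1 lies outside the bounds no such anchor exists and ``a = 0`` is
    used, which places the bound midpoint at ``rho = 0``.
    """
    _check_bounds(b_l, b_u)
    b_l = np.asarray(b_l, dtype=float)
    b_u = np.asarray(b_u, dtype=float)
    inside = (b_l < 1.0) & (1.0 < b_u)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = -np.arctanh(2.0 * (1.0 - b_l) / (b_u - b_l) - 1.0)
    a = np.where(inside, a, 0.0)
    return float(a) if a.ndim == 0 else a


def inverse_transform(theta, b_l, b_u, a):
    """Unconstrained coordinate ``rho`` with ``transform(rho) = theta``.

    ``theta`` must lie strictly inside the bounds.
    """
    _check_bounds(b_l, b_u)
    theta = np.asarray(theta, dtype=float)
    if not np.all((np.asarray(b_l) < theta) & (theta < np.asarray(b_u))):
        raise ValueError(
            f"theta={theta} not strictly inside bounds ({b_l}, {b_u})"
        )
    u = 2.0 * (theta - b_l) / (np.asarray(b_u) - np.asarray(b_l)) - 1.0
    rho = np.arctanh(u) + a
    return float(rho) if rho.ndim == 0 else rho


def transform_jacobian(rho, b_l, b_u, a):
    """d(theta)/d(rho) of the tanh transform (used by the chain rule)."""
    t = np.tanh(np.asarray(rho) - a)
    return (1.0 - t * t) / 2.0 * (np.asarray(b_u) - np.asarray(b_l))
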