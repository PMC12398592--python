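"""Numerical integration and loss gradients.

Two integration routes coexist:

* :func:`integrate` wraps adaptive Runge-Kutta (non-stiff) and BDF-type
  (stiff) solvers for simulation, evaluation and cross-checking.  Solver
  failures (step-size collapse, state blow-up) are reported on the returned
  :class:`Trajectory` rather than raised, so a multi-start batch survives
  divergent parameter draws.

* :func:`rk4_solve` / :func:`rk4_adjoint` form the differentiable route used
  during training: a fixed-step classical Runge-Kutta forward pass over a
  grid that contains every measurement time, and a discrete adjoint that
  walks the same grid backwards accumulating exact reverse-mode gradients of
  any functional of the states at the measurement times.  The adjoint needs
  vector-Jacobian products of the right-hand side; analytic Jacobians are
  used when the problem provides them, central finite differences otherwise,
  and the network term is backpropagated analytically.

The discrete adjoint differentiates the discretised trajectory exactly, so
its gradients agree with finite differences of the discrete loss to solver
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .nn import ann_forward_cached, ann_vjp
from .models.base import UDEProblem

__all__ = [
    "Trajectory",
    "SimulationFailure",
    "integrate",
    "rk4_solve",
    "rk4_adjoint",
    "finite_difference_gradient",
    "gradient",
]

#: state magnitude above which the integration is declared divergent;
#: generous against the O(1)-O(100) concentrations of the built-in models
BLOWUP_THRESHOLD = 1e6

#: right-hand-side evaluation budget of one adaptive solve; pathological
#: (near-divergent, extremely stiff) parameter draws abort instead of
#: stalling a batch
MAX_RHS_EVALS = 50_000


class SimulationFailure(RuntimeError):
    """Raised internally when the fixed-step integration diverges."""


@dataclass
class Trajectory:
    """States evaluated at requested times, with a success flag."""

    times: np.ndarray
    states: np.ndarray
    success: bool
    failure_reason: Optional[str] = None

    def to_csv(self, path, state_names=None) -> None:
        import pandas as pd

        cols = state_names or [f"x{i}" for i in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def _full_rhs(problem: UDEProblem, theta, ann_params, ann_override):
    if problem.ann_in_rhs and (ann_params is not None or ann_override is not None):
        base = lambda t, x: problem.rhs(
            t, x, theta, ann_params=ann_params, ann_override=ann_override
        )
    else:
        base = lambda t, x: problem.rhs_mechanistic(t, x, theta)

    n_evals = [0]

    def guarded(t, x):
        # divergent or stalling trajectories poison the step so the solver
        # aborts fast instead of grinding down the step size indefinitely
        n_evals[0] += 1
        if (
            n_evals[0] > MAX_RHS_EVALS
            or not np.all(np.isfinite(x))
            or np.max(np.abs(x)) > BLOWUP_THRESHOLD
        ):
            return np.full_like(x, np.nan)
        return base(t, x)

    return guarded


def integrate(
    problem: UDEProblem,
    times,
    theta=None,
    ann_params=None,
    ann_override: Callable | None = None,
    solver: str | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Trajectory:
    """Solve the (hybrid) ODE and evaluate the states at ``times``.

    ``solver`` is ``"nonstiff"`` (adaptive explicit Runge-Kutta),
    ``"stiff"`` (BDF) or ``None`` to follow the problem's default.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty strictly increasing 1-D array")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    theta = problem.parameters.values if theta is None else np.asarray(theta, float)
    if solver is None:
        solver = "stiff" if problem.stiff else "nonstiff"
    method = {"nonstiff": "RK45", "stiff": "BDF"}[solver]
    rhs = _full_rhs(problem, theta, ann_params, ann_override)
    t0 = min(times[0], 0.0)
    with np.errstate(all="ignore"):
        sol = solve_ivp(
            rhs,
            (t0, times[-1]),
            problem.x0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
    if not sol.success or sol.y.shape[1] != times.size or not np.all(
        np.isfinite(sol.y)
    ):
        return Trajectory(
            times=times,
            states=np.full((times.size, problem.n_states), np.nan),
            success=False,
            failure_reason=sol.message if not sol.success else "non-finite state",
        )
    return Trajectory(times=times, states=sol.y.T, success=True)


# ---------------------------------------------------------------------------
# differentiable fixed-step route
# ---------------------------------------------------------------------------


def _build_grid(times: np.ndarray, t0: float, dt_max: float):
    """Uniform substeps between consecutive output times; grid hits every
    output time exactly.  Returns (grid_times, output_indices)."""
    knots = np.asarray(times, dtype=float)
    if knots[0] > t0:
        knots = np.concatenate([[t0], knots])
        out_offset = 1
    else:
        out_offset = 0
    grid = [knots[0]]
    out_idx = [0] if out_offset == 0 else []
    for a, b in zip(knots[:-1], knots[1:]):
        n_sub = max(1, int(np.ceil((b - a) / dt_max - 1e-12)))
        seg = a + (b - a) * np.arange(1, n_sub + 1) / n_sub
        grid.extend(seg.tolist())
        out_idx.append(len(grid) - 1)
    if out_offset:
        pass  # t0 node is not an output time
    return np.asarray(grid), np.asarray(out_idx, dtype=int)


class _RHSOps:
    """Right-hand side plus its vector-Jacobian products for one problem."""

    def __init__(self, problem: UDEProblem, theta: np.ndarray, ann_flat):
        self.problem = problem
        self.theta = theta
        self.ann_flat = ann_flat
        self.n_m = theta.size
        if problem.ann_in_rhs and problem.ann_time_inputs is not None:
            raise NotImplementedError(
                "the discrete adjoint does not propagate gradients through "
                "parameter-dependent time inputs; use the finite-difference "
                "gradient route for this problem"
            )

    def f(self, t, x):
        p = self.problem
        dx = p.rhs_mechanistic(t, x, self.theta)
        if p.ann_in_rhs and self.ann_flat is not None:
            u = x[p.ann_input_indices]
            out, _ = ann_forward_cached(p.ann_spec, self.ann_flat, u)
            dx = dx + p.ann_state_matrix @ out
        if not np.all(np.isfinite(dx)):
            raise SimulationFailure("non-finite right-hand side")
        return dx

    def vjp(self, t, x, v):
        """Returns (v @ df/dx, v @ df/dtheta, v @ df/dann)."""
        p = self.problem
        if p.rhs_jac_x is not None:
            jx = p.rhs_jac_x(t, x, self.theta)
        else:
            jx = _fd_jac(lambda z: p.rhs_mechanistic(t, z, self.theta), x)
        if p.rhs_jac_theta is not None:
            jt = p.rhs_jac_theta(t, x, self.theta)
        else:
            jt = _fd_jac(
                lambda th: p.rhs_mechanistic(t, x, th), self.theta
            )
        gx = v @ jx
        gt = v @ jt
        ga = None
        if p.ann_in_rhs and self.ann_flat is not None:
            u = x[p.ann_input_indices]
            _, cache = ann_forward_cached(p.ann_spec, self.ann_flat, u)
            w = p.ann_state_matrix.T @ v
            ga, gu = ann_vjp(p.ann_spec, cache, w)
            gx = gx.copy()
            np.add.at(gx, p.ann_input_indices, gu)
        return gx, gt, ga


def _fd_jac(fun, x, h: float = 1e-7):
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x))
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        J[:, i] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * step)
    return J


def rk4_solve(
    problem: UDEProblem,
    theta: np.ndarray,
    ann_flat,
    times,
    dt_max: float | None = None,
):
    """Fixed-step classical Runge-Kutta solve.

    Returns ``(states_at_times, cache)``; the cache feeds
    :func:`rk4_adjoint`.  Raises :class:`SimulationFailure` on blow-up.
    """
    times = np.asarray(times, dtype=float)
    dt_max = problem.dt_max if dt_max is None else dt_max
    grid, out_idx = _build_grid(times, min(times[0], 0.0), dt_max)
    ops = _RHSOps(problem, np.asarray(theta, float), ann_flat)
    n = grid.size
    xs = np.empty((n, problem.n_states))
    xs[0] = problem.x0
    x = problem.x0.copy()
    for i in range(n - 1):
        h = grid[i + 1] - grid[i]
        t = grid[i]
        k1 = ops.f(t, x)
        k2 = ops.f(t + 0.5 * h, x + 0.5 * h * k1)
        k3 = ops.f(t + 0.5 * h, x + 0.5 * h * k2)
        k4 = ops.f(t + h, x + h * k3)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > BLOWUP_THRESHOLD:
            raise SimulationFailure(f"state blow-up at t={grid[i + 1]:.4g}")
        xs[i + 1] = x
    cache = (grid, xs, out_idx, ops)
    return xs[out_idx], cache


def rk4_adjoint(cache, seed: np.ndarray):
    """Discrete adjoint of :func:`rk4_solve`.

    ``seed[j]`` is dL/dx at the j-th requested output time.  Returns
    ``(grad_theta, grad_ann)`` for a scalar loss L.
    """
    grid, xs, out_idx, ops = cache
    n = grid.size
    lam = np.zeros(ops.problem.n_states)
    gt = np.zeros(ops.n_m)
    ga = None if ops.ann_flat is None else np.zeros(np.asarray(ops.ann_flat).size)
    seed_at = {int(k): seed[j] for j, k in enumerate(out_idx)}
    if (n - 1) in seed_at:
        lam = lam + seed_at[n - 1]
    for i in range(n - 2, -1, -1):
        h = grid[i + 1] - grid[i]
        t = grid[i]
        x = xs[i]
        k1 = ops.f(t, x)
        s2 = x + 0.5 * h * k1
        k2 = ops.f(t + 0.5 * h, s2)
        s3 = x + 0.5 * h * k2
        k3 = ops.f(t + 0.5 * h, s3)
        s4 = x + h * k3
        # reverse of x_{i+1} = x_i + h/6 (k1 + 2 k2 + 2 k3 + k4)
        g_k4 = (h / 6.0) * lam
        g_k3 = (h / 3.0) * lam
        g_k2 = (h / 3.0) * lam
        g_k1 = (h / 6.0) * lam
        g_x = lam.copy()
        vx, vt, va = ops.vjp(t + h, s4, g_k4)
        g_x += vx
        g_k3 = g_k3 + h * vx
        gt += vt
        if va is not None:
            ga += va
        vx, vt, va = ops.vjp(t + 0.5 * h, s3, g_k3)
        g_x += vx
        g_k2 = g_k2 + 0.5 * h * vx
        gt += vt
        if va is not None:
            ga += va
        vx, vt, va = ops.vjp(t + 0.5 * h, s2, g_k2)
        g_x += vx
        g_k1 = g_k1 + 0.5 * h * vx
        gt += vt
        if va is not None:
            ga += va
        vx, vt, va = ops.vjp(t, x, g_k1)
        g_x += vx
        gt += vt
        if va is not None:
            ga += va
        lam = g_x
        if i in seed_at:
            lam = lam + seed_at[i]
    return gt, ga


def finite_difference_gradient(loss_fn: Callable, params, h: float = 1e-6):
    """Central finite differences of a scalar function of a flat vector."""
    params = np.asarray(params, dtype=float)
    g = np.empty_like(params)
    for i in range(params.size):
        step = h * max(1.0, abs(params[i]))
        pp = params.copy()
        pm = params.copy()
        pp[i] += step
        pm[i] -= step
        g[i] = (loss_fn(pp) - loss_fn(pm)) / (2.0 * step)
    return g


def gradient(loss_fn: Callable, params):
    """Gradient of a scalar loss with respect to a flat parameter vector.

    Uses the loss object's own reverse-mode path when it exposes
    ``value_and_grad``; falls back to central finite differences.
    """
    vag = getattr(loss_fn, "value_and_grad", None)
    if vag is not None:
        return vag(np.asarray(params, dtype=float))[1]
    return finite_difference_gradient(loss_fn, params)
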