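"""Compiled training kernels for the glycolysis problems.

The generic discrete-adjoint route in :mod:`udekit.simulate` is written in
plain numpy and dispatches per step through Python, which dominates the
cost of a multi-start study.  This module provides numerically identical
kernels for the glycolysis model family -- mechanistic right-hand side,
analytic Jacobians, the feed-forward network with its backward pass, and
the RK4 forward/adjoint sweeps -- compiled with numba.  The generic route
remains the reference; the two are cross-checked in the test suite.

Parameter layout matches the model definition: the twelve free constants
``J0, k1, k2, k3, k4, (k5,) k6, K1, kappa, phi, k_ex, A`` with ``k5``
present only in the fully mechanistic variant, and the NAD(H) total fixed
at 1.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is part of the target stack
    NUMBA_AVAILABLE = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


__all__ = ["supports", "fast_solve", "fast_adjoint", "NUMBA_AVAILABLE"]

_N_TOTAL = 1.0
_BLOWUP = 1e6

# activation ids
_ACT_IDS = {"tanh": 0, "relu": 1, "gaussian-rbf": 2, "swish": 3}
_LOG_FLOOR = np.log(1e-20)


@njit(cache=True)
def _act(z, aid):
    if aid == 0:
        return np.tanh(z)
    if aid == 1:
        return z if z > 0.0 else 0.0
    if aid == 2:
        return np.exp(-z * z)
    s = 1.0 / (1.0 + np.exp(-z))
    return z * s


@njit(cache=True)
def _act_grad(z, aid):
    if aid == 0:
        y = np.tanh(z)
        return 1.0 - y * y
    if aid == 1:
        return 1.0 if z > 0.0 else 0.0
    if aid == 2:
        return -2.0 * z * np.exp(-z * z)
    s = 1.0 / (1.0 + np.exp(-z))
    return s + z * s * (1.0 - s)


@njit(cache=True)
def _mlp_forward(w, sizes, aid, norm, x, out):
    """Forward pass; returns nothing, fills ``out`` (n_outputs,)."""
    maxw = 0
    for i in range(sizes.size):
        if sizes[i] > maxw:
            maxw = sizes[i]
    h = np.empty(maxw)
    h2 = np.empty(maxw)
    n_in = sizes[0]
    for i in range(n_in):
        if norm == 1:
            h[i] = np.log(x[i] + 1e-20) if x[i] > 0.0 else _LOG_FLOOR
        else:
            h[i] = x[i]
    k = 0
    n_lay = sizes.size - 1
    for l in range(n_lay):
        fi = sizes[l]
        fo = sizes[l + 1]
        for o in range(fo):
            z = 0.0
            for i in range(fi):
                z += w[k + o * fi + i] * h[i]
            z += w[k + fo * fi + o]
            if l < n_lay - 1:
                h2[o] = _act(z, aid)
            else:
                h2[o] = z
        k += fo * fi + fo
        for o in range(fo):
            h[o] = h2[o]
    for o in range(sizes[n_lay]):
        out[o] = h[o]


@njit(cache=True)
def _mlp_vjp(w, sizes, aid, norm, x, cot, gw, gx):
    """Backward pass: accumulates ``gw += v@dout/dw``; fills ``gx``."""
    maxw = 0
    for i in range(sizes.size):
        if sizes[i] > maxw:
            maxw = sizes[i]
    n_lay = sizes.size - 1
    # forward, storing activations (hs) and pre-activations (zs)
    hs = np.empty((n_lay + 1, maxw))
    zs = np.empty((n_lay, maxw))
    n_in = sizes[0]
    for i in range(n_in):
        if norm == 1:
            hs[0, i] = np.log(x[i] + 1e-20) if x[i] > 0.0 else _LOG_FLOOR
        else:
            hs[0, i] = x[i]
    offs = np.empty(n_lay, dtype=np.int64)
    k = 0
    for l in range(n_lay):
        offs[l] = k
        fi = sizes[l]
        fo = sizes[l + 1]
        for o in range(fo):
            z = 0.0
            for i in range(fi):
                z += w[k + o * fi + i] * hs[l, i]
            z += w[k + fo * fi + o]
            zs[l, o] = z
            hs[l + 1, o] = _act(z, aid) if l < n_lay - 1 else z
        k += fo * fi + fo
    # backward
    delta = np.empty(maxw)
    delta2 = np.empty(maxw)
    for o in range(sizes[n_lay]):
        delta[o] = cot[o]
    for l in range(n_lay - 1, -1, -1):
        fi = sizes[l]
        fo = sizes[l + 1]
        k = offs[l]
        for o in range(fo):
            d = delta[o]
            for i in range(fi):
                gw[k + o * fi + i] += d * hs[l, i]
            gw[k + fo * fi + o] += d
        for i in range(fi):
            s = 0.0
            for o in range(fo):
                s += w[k + o * fi + i] * delta[o]
            delta2[i] = s
        if l > 0:
            for i in range(fi):
                delta[i] = delta2[i] * _act_grad(zs[l - 1, i], aid)
        else:
            for i in range(fi):
                delta[i] = delta2[i]
    for i in range(n_in):
        if norm == 1:
            gx[i] = delta[i] / (x[i] + 1e-20) if x[i] > 0.0 else 0.0
        else:
            gx[i] = delta[i]


@njit(cache=True)
def _rhs(x, th, k5on, has_ann, w, sizes, aid, norm, dx):
    J0 = th[0]
    k1 = th[1]
    k2 = th[2]
    k3 = th[3]
    k4 = th[4]
    off = 1 if k5on == 1 else 0
    k6 = th[5 + off]
    K1 = th[6 + off]
    kap = th[7 + off]
    phi = th[8 + off]
    kex = th[9 + off]
    A = th[10 + off]
    S1, S2, S3, S4, N2, A3, S4e = x[0], x[1], x[2], x[3], x[4], x[5], x[6]
    u = (A3 / K1) ** 4
    hill = A3 / (1.0 + u)
    v1 = k1 * S1 * hill
    v2 = k2 * S2 * (_N_TOTAL - N2)
    v3 = k3 * S3 * (A - A3)
    v4 = k4 * S4 * N2
    v6 = k6 * S2 * N2
    ex = kap * (S4 - S4e)
    dx[0] = J0 - v1
    dx[1] = 2.0 * v1 - v2 - v6
    dx[2] = v2 - v3
    dx[3] = v3 - v4 - ex
    dx[4] = v2 - v4 - v6
    dx[5] = -2.0 * v1 + 2.0 * v3
    if k5on == 1:
        dx[5] -= th[5] * A3
    dx[6] = phi * ex - kex * S4e
    if has_ann == 1:
        out = np.empty(1)
        _mlp_forward(w, sizes, aid, norm, x, out)
        dx[5] += out[0]


@njit(cache=True)
def _vjp(x, th, k5on, has_ann, w, sizes, aid, norm, v, gx, gt, gw):
    """gx = v @ df/dx (overwrites); gt += v @ df/dtheta; gw += ann part."""
    k1 = th[1]
    k2 = th[2]
    k3 = th[3]
    k4 = th[4]
    off = 1 if k5on == 1 else 0
    k6 = th[5 + off]
    K1 = th[6 + off]
    kap = th[7 + off]
    phi = th[8 + off]
    kex = th[9 + off]
    A = th[10 + off]
    S1, S2, S3, S4, N2, A3, S4e = x[0], x[1], x[2], x[3], x[4], x[5], x[6]
    u = (A3 / K1) ** 4
    den = (1.0 + u) ** 2
    hill = A3 / (1.0 + u)
    dhill = (1.0 - 3.0 * u) / den
    dhill_dK1 = A3 * 4.0 * u / (K1 * den)
    # --- states ---
    gx[0] = v[0] * (-k1 * hill) + v[1] * (2.0 * k1 * hill) + v[5] * (-2.0 * k1 * hill)
    gx[1] = (
        v[1] * (-k2 * (_N_TOTAL - N2) - k6 * N2)
        + v[2] * (k2 * (_N_TOTAL - N2))
        + v[4] * (k2 * (_N_TOTAL - N2) - k6 * N2)
    )
    gx[2] = (
        v[2] * (-k3 * (A - A3)) + v[3] * (k3 * (A - A3)) + v[5] * (2.0 * k3 * (A - A3))
    )
    gx[3] = v[3] * (-k4 * N2 - kap) + v[4] * (-k4 * N2) + v[6] * (phi * kap)
    gx[4] = (
        v[1] * (k2 * S2 - k6 * S2)
        + v[2] * (-k2 * S2)
        + v[3] * (-k4 * S4)
        + v[4] * (-k2 * S2 - k4 * S4 - k6 * S2)
    )
    a3term = -2.0 * k1 * S1 * dhill - 2.0 * k3 * S3
    if k5on == 1:
        a3term -= th[5]
    gx[5] = (
        v[0] * (-k1 * S1 * dhill)
        + v[1] * (2.0 * k1 * S1 * dhill)
        + v[2] * (k3 * S3)
        + v[3] * (-k3 * S3)
        + v[5] * a3term
    )
    gx[6] = v[3] * kap + v[6] * (-phi * kap - kex)
    # --- parameters ---
    s1h = S1 * hill
    s2n = S2 * (_N_TOTAL - N2)
    s3a = S3 * (A - A3)
    s4n = S4 * N2
    s2n2 = S2 * N2
    ex = S4 - S4e
    dK1 = k1 * S1 * dhill_dK1
    gt[0] += v[0]
    gt[1] += -v[0] * s1h + 2.0 * v[1] * s1h - 2.0 * v[5] * s1h
    gt[2] += (-v[1] + v[2] + v[4]) * s2n
    gt[3] += (-v[2] + v[3]) * s3a + 2.0 * v[5] * s3a
    gt[4] += (-v[3] - v[4]) * s4n
    if k5on == 1:
        gt[5] += -v[5] * A3
    gt[5 + off] += (-v[1] - v[4]) * s2n2
    gt[6 + off] += (-v[0] + 2.0 * v[1] - 2.0 * v[5]) * dK1
    gt[7 + off] += -v[3] * ex + v[6] * phi * ex
    gt[8 + off] += v[6] * kap * ex
    gt[9 + off] += -v[6] * S4e
    gt[10 + off] += (-v[2] + v[3] + 2.0 * v[5]) * k3 * S3
    if has_ann == 1:
        cot = np.empty(1)
        cot[0] = v[5]
        gu = np.empty(7)
        _mlp_vjp(w, sizes, aid, norm, x, cot, gw, gu)
        for i in range(7):
            gx[i] += gu[i]


@njit(cache=True)
def _forward(grid, x0, th, k5on, has_ann, w, sizes, aid, norm):
    n = grid.size
    xs = np.empty((n, 7))
    for j in range(7):
        xs[0, j] = x0[j]
    x = x0.copy()
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    tmp = np.empty(7)
    for i in range(n - 1):
        h = grid[i + 1] - grid[i]
        _rhs(x, th, k5on, has_ann, w, sizes, aid, norm, k1)
        for j in range(7):
            tmp[j] = x[j] + 0.5 * h * k1[j]
        _rhs(tmp, th, k5on, has_ann, w, sizes, aid, norm, k2)
        for j in range(7):
            tmp[j] = x[j] + 0.5 * h * k2[j]
        _rhs(tmp, th, k5on, has_ann, w, sizes, aid, norm, k3)
        for j in range(7):
            tmp[j] = x[j] + h * k3[j]
        _rhs(tmp, th, k5on, has_ann, w, sizes, aid, norm, k4)
        ok = True
        for j in range(7):
            x[j] = x[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not np.isfinite(x[j]) or abs(x[j]) > _BLOWUP:
                ok = False
        if not ok:
            return xs, i + 1
        for j in range(7):
            xs[i + 1, j] = x[j]
    return xs, -1


@njit(cache=True)
def _adjoint(grid, xs, out_idx, seed, th, k5on, has_ann, w, sizes, aid, norm, n_t):
    n = grid.size
    gt = np.zeros(th.size)
    gw = np.zeros(w.size)
    lam = np.zeros(7)
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    s2 = np.empty(7)
    s3 = np.empty(7)
    s4 = np.empty(7)
    g_k1 = np.empty(7)
    g_k2 = np.empty(7)
    g_k3 = np.empty(7)
    g_k4 = np.empty(7)
    vx = np.empty(7)
    # map grid index -> seed row
    seed_row = np.full(n, -1, dtype=np.int64)
    for j in range(n_t):
        seed_row[out_idx[j]] = j
    if seed_row[n - 1] >= 0:
        for j in range(7):
            lam[j] += seed[seed_row[n - 1], j]
    for i in range(n - 2, -1, -1):
        h = grid[i + 1] - grid[i]
        x = xs[i]
        _rhs(x, th, k5on, has_ann, w, sizes, aid, norm, k1)
        for j in range(7):
            s2[j] = x[j] + 0.5 * h * k1[j]
        _rhs(s2, th, k5on, has_ann, w, sizes, aid, norm, k2)
        for j in range(7):
            s3[j] = x[j] + 0.5 * h * k2[j]
        _rhs(s3, th, k5on, has_ann, w, sizes, aid, norm, k3)
        for j in range(7):
            s4[j] = x[j] + h * k3[j]
        for j in range(7):
            g_k4[j] = (h / 6.0) * lam[j]
            g_k3[j] = (h / 3.0) * lam[j]
            g_k2[j] = (h / 3.0) * lam[j]
            g_k1[j] = (h / 6.0) * lam[j]
        _vjp(s4, th, k5on, has_ann, w, sizes, aid, norm, g_k4, vx, gt, gw)
        for j in range(7):
            lam[j] += vx[j]
            g_k3[j] += h * vx[j]
        _vjp(s3, th, k5on, has_ann, w, sizes, aid, norm, g_k3, vx, gt, gw)
        for j in range(7):
            lam[j] += vx[j]
            g_k2[j] += 0.5 * h * vx[j]
        _vjp(s2, th, k5on, has_ann, w, sizes, aid, norm, g_k2, vx, gt, gw)
        for j in range(7):
            lam[j] += vx[j]
            g_k1[j] += 0.5 * h * vx[j]
        _vjp(x, th, k5on, has_ann, w, sizes, aid, norm, g_k1, vx, gt, gw)
        for j in range(7):
            lam[j] += vx[j]
        if seed_row[i] >= 0:
            for j in range(7):
                lam[j] += seed[seed_row[i], j]
    return gt, gw


# ---------------------------------------------------------------------------
# adapters matching the generic rk4_solve / rk4_adjoint contracts
# ---------------------------------------------------------------------------


def supports(problem) -> bool:
    """Whether the compiled kernels apply to this problem."""
    if not NUMBA_AVAILABLE:
        return False
    if problem.name not in ("glycolysis", "glycolysis_ude"):
        return False
    if problem.ann_spec is not None and problem.name == "glycolysis_ude":
        return True
    return problem.ann_spec is None


def _meta(problem, ann_flat):
    k5on = 1 if problem.name == "glycolysis" else 0
    if ann_flat is not None and problem.ann_spec is not None:
        has_ann = 1
        w = np.ascontiguousarray(np.asarray(ann_flat, dtype=float))
        sizes = np.asarray(problem.ann_spec.layer_sizes, dtype=np.int64)
        aid = _ACT_IDS[problem.ann_spec.activation]
        norm = 1 if problem.ann_spec.input_normalisation else 0
    else:
        has_ann = 0
        w = np.zeros(0)
        sizes = np.array([7, 1], dtype=np.int64)
        aid = 0
        norm = 0
    return k5on, has_ann, w, sizes, aid, norm


def fast_solve(problem, theta, ann_flat, times, dt_max=None):
    from .simulate import SimulationFailure, _build_grid

    times = np.asarray(times, dtype=float)
    dt_max = problem.dt_max if dt_max is None else dt_max
    grid, out_idx = _build_grid(times, min(times[0], 0.0), dt_max)
    k5on, has_ann, w, sizes, aid, norm = _meta(problem, ann_flat)
    th = np.ascontiguousarray(np.asarray(theta, dtype=float))
    xs, fail = _forward(grid, problem.x0, th, k5on, has_ann, w, sizes, aid, norm)
    if fail >= 0:
        raise SimulationFailure(f"state blow-up at t={grid[fail]:.4g}")
    cache = (grid, xs, out_idx, (th, k5on, has_ann, w, sizes, aid, norm))
    return xs[out_idx], cache


def fast_adjoint(cache, seed):
    grid, xs, out_idx, (th, k5on, has_ann, w, sizes, aid, norm) = cache
    gt, gw = _adjoint(
        grid,
        xs,
        np.asarray(out_idx, dtype=np.int64),
        np.ascontiguousarray(seed),
        th,
        k5on,
        has_ann,
        w,
        sizes,
        aid,
        norm,
        seed.shape[0],
    )
    return gt, (gw if has_ann else None)
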