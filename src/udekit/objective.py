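"""Noise model, likelihood and the regularised training objective.

Measurements carry additive Gaussian noise with one standard deviation per
observable, estimated jointly with all other parameters.  The negative
log-likelihood of a record set is

    J = 1/2 * sum_records [ log(2 pi sigma_s^2) + (y_s - ybar_s)^2 / sigma_s^2 ]

with ``s`` the record's observable.  Training minimises J on the training
partition plus a weight-decay penalty ``lambda * ||theta_ANN||^2 / n_ANN``
on the network weights; the validation partition is scored with the plain
NLL (no penalty) for early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .nn import ANNParameters, ann_forward_cached, ann_vjp, ann_parameter_count, ann_init
from .parameters import MechanisticParameterSet, NoiseParameters, ParameterVector
from .models.base import UDEProblem
from .simulate import SimulationFailure, rk4_solve, rk4_adjoint, _fd_jac

__all__ = [
    "Dataset",
    "nll",
    "regularised_loss",
    "optimal_sigma",
    "TrainingLoss",
]

RECORD_COLUMNS = ["observableId", "time", "measurement"]


@dataclass
class Dataset:
    """Timestamped observable records with train/validation partition labels.

    ``records`` columns: ``observableId``, ``time``, ``measurement`` and
    optionally ``partition`` (``train``/``validation``) and
    ``is_initial_condition``.
    """

    records: pd.DataFrame
    observable_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.records.copy()
        for col in RECORD_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"dataset records require a {col!r} column")
        if "partition" not in df.columns:
            df["partition"] = "train"
        if "is_initial_condition" not in df.columns:
            df["is_initial_condition"] = False
        if not self.observable_names:
            self.observable_names = sorted(df["observableId"].unique().tolist())
        unknown = set(df["observableId"]) - set(self.observable_names)
        if unknown:
            raise ValueError(f"unknown observable ids: {sorted(unknown)}")
        bad = set(df["partition"]) - {"train", "validation"}
        if bad:
            raise ValueError(f"unknown partition labels: {sorted(bad)}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, partition: str) -> "Dataset":
        return Dataset(
            records=self.records[self.records["partition"] == partition].copy(),
            observable_names=list(self.observable_names),
        )

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.records["time"].unique())

    def counts(self) -> dict:
        part = self.records.drop_duplicates(["time", "partition"])
        return {
            "train": int((part["partition"] == "train").sum()),
            "validation": int((part["partition"] == "validation").sum()),
        }

    def align(self, observable_names: list[str] | None = None):
        """Index arrays for vectorised likelihood evaluation.

        Returns ``(times, t_idx, o_idx, y, is_train)`` where ``times`` is
        the sorted union of record times and record ``r`` refers to
        ``predictions[t_idx[r], o_idx[r]]``.
        """
        names = observable_names or self.observable_names
        times = self.times
        t_pos = {t: i for i, t in enumerate(times)}
        o_pos = {n: i for i, n in enumerate(names)}
        df = self.records
        t_idx = df["time"].map(t_pos).to_numpy(dtype=int)
        o_idx = df["observableId"].map(o_pos).to_numpy(dtype=int)
        y = df["measurement"].to_numpy(dtype=float)
        is_train = (df["partition"] == "train").to_numpy()
        return times, t_idx, o_idx, y, is_train


def nll(predictions, data: Dataset, sigma: NoiseParameters) -> float:
    """Negative log-likelihood of a record set under the Gaussian noise model.

    ``predictions`` are per-record model outputs aligned with
    ``data.records``.  Non-finite predictions yield ``+inf``.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(data),):
        raise ValueError(
            f"predictions have shape {predictions.shape}, expected ({len(data)},)"
        )
    if not np.all(np.isfinite(predictions)):
        return np.inf
    o_pos = {n: i for i, n in enumerate(data.observable_names)}
    o_idx = data.records["observableId"].map(o_pos).to_numpy(dtype=int)
    y = data.records["measurement"].to_numpy(dtype=float)
    s = sigma.sigma[o_idx]
    r = y - predictions
    return float(0.5 * np.sum(np.log(2.0 * np.pi * s**2) + (r / s) ** 2))


def regularised_loss(nll_value: float, theta_ann, lam: float) -> float:
    """Training objective: NLL plus mean-squared-weight decay penalty."""
    if lam < 0:
        raise ValueError("regularisation strength must be non-negative")
    if theta_ann is None:
        return float(nll_value)
    vals = theta_ann.values if isinstance(theta_ann, ANNParameters) else np.asarray(theta_ann)
    if vals.size == 0:
        return float(nll_value)
    return float(nll_value + lam * np.sum(vals**2) / vals.size)


def optimal_sigma(residuals: dict | list) -> NoiseParameters:
    """Closed-form stationary noise levels: sigma_s^2 = mean squared residual.

    ``residuals`` maps observables (or lists per observable) to residual
    arrays; each must be non-empty.
    """
    groups = list(residuals.values()) if isinstance(residuals, dict) else list(residuals)
    sigmas = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size == 0:
            raise ValueError("every observable needs at least one residual")
        sigmas.append(np.sqrt(np.mean(g**2)))
    return NoiseParameters(sigma=np.array(sigmas))


class TrainingLoss:
    """Regularised training NLL of a hybrid problem on a dataset.

    Callable on the packed parameter vector ``[rho, theta_ann, log_sigma]``;
    ``value_and_grad`` additionally returns the exact reverse-mode gradient
    (discrete adjoint through the fixed-step solver, analytic network
    backpropagation and analytic noise-parameter derivatives) plus a side
    dictionary with the unregularised training NLL and the validation NLL
    used for early stopping.

    Simulation failures map to an infinite loss so that a multi-start batch
    simply discards the divergent start.
    """

    def __init__(
        self,
        problem: UDEProblem,
        dataset: Dataset,
        lam: float = 0.0,
        dt_max: float | None = None,
    ):
        if lam < 0:
            raise ValueError("regularisation strength must be non-negative")
        self.problem = problem
        self.dataset = dataset
        self.lam = float(lam)
        self.dt_max = dt_max
        names = problem.observable_names
        self.times, self.t_idx, self.o_idx, self.y, self.is_train = dataset.align(names)
        if self.times[0] < problem.t_span[0] or self.times[-1] > problem.t_span[1]:
            raise ValueError("dataset times outside the problem horizon")
        self.template = self._template()
        from . import _fastpath

        if _fastpath.supports(problem):
            self._solve, self._adjoint = _fastpath.fast_solve, _fastpath.fast_adjoint
        else:
            self._solve, self._adjoint = rk4_solve, rk4_adjoint

    def _template(self) -> ParameterVector:
        p = self.problem
        ann = None
        if p.ann_spec is not None:
            ann = ann_init(p.ann_spec, seed=0)
        return ParameterVector(
            mechanistic=p.parameters,
            ann=ann,
            noise=NoiseParameters(sigma=np.ones(p.n_observables)),
        )

    @property
    def n_parameters(self) -> int:
        return self.template.n_total

    def initial_vector(
        self,
        theta=None,
        ann_params: ANNParameters | None = None,
        sigma=None,
    ) -> np.ndarray:
        """Packed start vector; sigma defaults to the closed-form optimum at
        the given parameters (keeps the initial likelihood finite and
        scaled)."""
        p = self.problem
        mech = p.parameters if theta is None else p.parameters.replace_values(theta)
        ann = ann_params if ann_params is not None else (
            ann_init(p.ann_spec, seed=0) if p.ann_spec is not None else None
        )
        if sigma is None:
            flat0 = ParameterVector(
                mech, ann, NoiseParameters(np.ones(p.n_observables))
            ).pack()
            preds = self._predict(flat0)[0]
            if preds is None:
                sigma = np.ones(p.n_observables)
            else:
                r = self.y - preds[self.t_idx, self.o_idx]
                sigma = np.array(
                    [
                        max(np.sqrt(np.mean(r[self.o_idx == k] ** 2)), 1e-6)
                        for k in range(p.n_observables)
                    ]
                )
        return ParameterVector(mech, ann, NoiseParameters(np.asarray(sigma))).pack()

    # -- forward ------------------------------------------------------------
    def _predict(self, flat: np.ndarray):
        """(predictions (n_t, n_o) or None, cache, theta, ann_flat)."""
        rho, ann_flat, _ = self.template.split(flat)
        theta = self.problem.parameters.from_rho(rho)
        ann = ann_flat if ann_flat.size else None
        try:
            states, cache = self._solve(
                self.problem, theta, ann, self.times, dt_max=self.dt_max
            )
        except SimulationFailure:
            return None, None, theta, ann
        preds = self.problem.observe(self.times, states, theta, ann)
        if not np.all(np.isfinite(preds)):
            return None, None, theta, ann
        return preds, cache, theta, ann

    def _nll_terms(self, preds, log_sigma, mask):
        # extreme trial points (huge log sigma, wild residuals) legitimately
        # overflow to an infinite NLL; silence the expected warnings
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            s = np.exp(log_sigma)[self.o_idx[mask]]
            r = self.y[mask] - preds[self.t_idx[mask], self.o_idx[mask]]
            return float(0.5 * np.sum(np.log(2.0 * np.pi * s**2) + (r / s) ** 2))

    def __call__(self, flat: np.ndarray) -> float:
        return self.value_and_grad(flat, with_grad=False)[0]

    def value_and_grad(self, flat: np.ndarray, with_grad: bool = True):
        flat = np.asarray(flat, dtype=float)
        rho, ann_flat, log_sigma = self.template.split(flat)
        preds, cache, theta, ann = self._predict(flat)
        extras = {"train_nll": np.inf, "validation_nll": np.inf}
        if preds is None:
            return np.inf, np.zeros_like(flat), extras
        train_nll = self._nll_terms(preds, log_sigma, self.is_train)
        if np.any(~self.is_train):
            extras["validation_nll"] = self._nll_terms(
                preds, log_sigma, ~self.is_train
            )
        extras["train_nll"] = train_nll
        loss = regularised_loss(train_nll, ann, self.lam)
        if not with_grad:
            return loss, None, extras
        grad = np.zeros_like(flat)
        n_m = rho.size
        n_a = ann_flat.size
        # residual terms on the training partition
        mask = self.is_train
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            sig = np.exp(log_sigma)
            s = sig[self.o_idx[mask]]
            r = self.y[mask] - preds[self.t_idx[mask], self.o_idx[mask]]
            dl_dpred = r / s**2  # dL/d ybar = -(y - ybar)/s^2, sign folded below
        # d L / d log sigma per observable: sum over its records of 1 - r^2/s^2
        g_ls = np.zeros(self.problem.n_observables)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            np.add.at(g_ls, self.o_idx[mask], 1.0 - (r / s) ** 2)
        g_ls = np.where(np.isfinite(g_ls), g_ls, 0.0)
        grad[n_m + n_a :] = g_ls
        # seed dL/dx at the measurement times
        seed = np.zeros((self.times.size, self.problem.n_states))
        p = self.problem
        dl_dy = np.zeros((self.times.size, p.n_observables))
        np.add.at(
            dl_dy, (self.t_idx[mask], self.o_idx[mask]), -dl_dpred
        )
        if p.observable_indices is not None:
            seed[:, p.observable_indices] += dl_dy
        else:
            for j in np.nonzero(np.any(dl_dy != 0.0, axis=1))[0]:
                cols = [
                    k
                    for k in range(p.n_observables)
                    if k != p.ann_observable_index
                ]
                if cols:
                    jac = _fd_jac(
                        lambda z: np.asarray(
                            p.observable_fn(self.times[j], z[None, :], theta)
                        )[0, cols],
                        cache[1][cache[2][j]],
                    )
                    seed[j] += dl_dy[j, cols] @ jac
        # network-in-observable contribution (does not pass through the ODE)
        if p.ann_observable_index is not None and ann is not None:
            k = p.ann_observable_index
            for j in range(self.times.size):
                w = dl_dy[j, k]
                if w == 0.0:
                    continue
                xj = cache[1][cache[2][j]]
                u = p.ann_inputs(self.times[j], xj, theta)
                _, c = ann_forward_cached(p.ann_spec, ann, u)
                gflat, gu = ann_vjp(p.ann_spec, c, np.array([w]))
                grad[n_m : n_m + n_a] += gflat
                sx = np.zeros(p.n_states)
                np.add.at(sx, p.ann_input_indices, gu)
                seed[j] += sx
        g_theta, g_ann = self._adjoint(cache, seed)
        grad[:n_m] += g_theta * p.parameters.rho_jacobian(rho)
        if n_a and g_ann is not None:
            grad[n_m : n_m + n_a] += g_ann
        if n_a and self.lam > 0:
            grad[n_m : n_m + n_a] += 2.0 * self.lam * ann_flat / n_a
        return loss, grad, extras

    def validation_nll(self, flat: np.ndarray) -> float:
        return self.value_and_grad(flat, with_grad=False)[2]["validation_nll"]

    def nll_on(self, flat: np.ndarray, partition: str | None = None) -> float:
        """Plain NLL on a partition (or on all records if None)."""
        _, _, log_sigma = self.template.split(np.asarray(flat, float))
        preds = self._predict(np.asarray(flat, float))[0]
        if preds is None:
            return np.inf
        if partition is None:
            mask = np.ones(len(self.dataset), dtype=bool)
        else:
            mask = self.is_train if partition == "train" else ~self.is_train
        return self._nll_terms(preds, log_sigma, mask)
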