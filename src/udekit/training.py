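"""Gradient-based training: single start, two stage and multi start.

A single optimisation run minimises the regularised training NLL with ADAM
for a fixed number of epochs and then BFGS up to a total epoch budget (one
BFGS iteration counts as one epoch).  The validation NLL is evaluated every
epoch and the parameter vector with the best validation score is retained
(early stopping); when the dataset has no validation partition the training
NLL takes that role and early stopping degenerates to best-so-far.

Because the objective is non-convex and multi-modal, reliable estimation
needs a global strategy: many independent runs from Latin-hypercube-sampled
mechanistic parameters and jointly sampled hyperparameters (network depth,
width, activation, input normalisation, learning rate, regularisation
strength).  The best model of a batch is the one with the lowest plain NLL
on all data used during training, i.e. training plus validation records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .nn import ACTIVATIONS, ANNSpec, ann_init
from .parameters import MechanisticParameterSet, ParameterVector
from .objective import Dataset, TrainingLoss
from .models.base import UDEProblem

__all__ = [
    "HyperParameters",
    "HyperRanges",
    "Budget",
    "FitResult",
    "MultiStartResult",
    "train_single",
    "train_two_stage",
    "sample_starts",
    "run_multistart",
    "child_seed",
]


@dataclass(frozen=True)
class Budget:
    """Epoch budget: ADAM epochs first, BFGS up to the total."""

    adam: int = 500
    total: int = 3000

    def __post_init__(self):
        if self.adam < 0 or self.total < self.adam:
            raise ValueError("require 0 <= adam <= total epochs")


@dataclass
class HyperParameters:
    """One sampled hyperparameter setting.

    ``lam = 0`` means no regularisation.  ``ann_spec`` may be None for a
    purely mechanistic fit.
    """

    ann_spec: Optional[ANNSpec]
    learning_rate: float = 1e-3
    lam: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.lam < 0:
            raise ValueError("regularisation strength must be non-negative")

    def to_dict(self) -> dict:
        d = {"learning_rate": self.learning_rate, "lam": self.lam}
        if self.ann_spec is not None:
            d["ann_spec"] = asdict(self.ann_spec)
        return d


@dataclass
class HyperRanges:
    """Hyperparameter sampling ranges for a multi-start study.

    Continuous ranges (learning rate, regularisation) are sampled
    log-uniformly; ``no_regularisation_share`` is the probability mass given
    to lam = 0 ("no regularisation") ahead of the log-uniform range.  The
    default share is 1/(d+1) where d is the number of decades the range
    spans, treating "none" as one more level of the roughly decade-wise
    grid.
    """

    hidden_layers: tuple[int, ...] = (1, 2, 3, 4)
    widths: tuple[int, ...] = (3, 5, 10)
    activations: tuple[str, ...] = ("tanh", "relu", "gaussian-rbf", "swish")
    input_normalisation: tuple[bool, ...] = (True, False)
    learning_rate_range: tuple[float, float] = (1e-4, 1e-1)
    lam_range: Optional[tuple[float, float]] = (1e-4, 1e1)
    include_no_regularisation: bool = True
    no_regularisation_share: Optional[float] = None

    def __post_init__(self):
        for name in ("hidden_layers", "widths", "activations", "input_normalisation"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty range for {name}")
        bad = set(self.activations) - set(ACTIVATIONS)
        if bad:
            raise ValueError(f"unknown activations {sorted(bad)}")
        if self.lam_range is None and not self.include_no_regularisation:
            raise ValueError("no regularisation setting can be sampled")

    @property
    def none_share(self) -> float:
        if not self.include_no_regularisation:
            return 0.0
        if self.lam_range is None:
            return 1.0
        if self.no_regularisation_share is not None:
            return self.no_regularisation_share
        decades = np.log10(self.lam_range[1] / self.lam_range[0])
        return 1.0 / (decades + 1.0)


# Table-style presets for the studied problems.  The glycolysis
# regularisation range extends to 10: the study's results discuss sampled
# strengths up to the 1-10 band, which a lower cap could not produce.
GLYCOLYSIS_RANGES = HyperRanges()
STAT5_SCENARIO123_RANGES = HyperRanges(
    hidden_layers=(3,),
    widths=(5,),
    activations=("tanh",),
    learning_rate_range=(1e-4, 1e-2),
    lam_range=(1e-3, 1.0),
)
STAT5_SCENARIO4_RANGES = HyperRanges(
    learning_rate_range=(1e-4, 1e-1),
    lam_range=(1e-3, 1e3),
)


@dataclass
class FitResult:
    """Outcome of one optimisation run."""

    best_flat: np.ndarray
    final_flat: np.ndarray
    best_params: ParameterVector
    final_params: ParameterVector
    train_nll_trace: list[float]
    validation_nll_trace: list[float]
    status: str  # converged | budget_exhausted | simulation_failed
    hyperparameters: HyperParameters
    seed: int
    best_validation_nll: float
    #: plain NLL over all records (train + validation) at the best vector;
    #: the multi-start selection criterion
    selection_nll: float
    stage1: Optional["FitResult"] = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "seed": int(self.seed),
            "hyperparameters": self.hyperparameters.to_dict(),
            "best_validation_nll": float(self.best_validation_nll),
            "selection_nll": float(self.selection_nll),
            "train_nll_trace": [float(v) for v in self.train_nll_trace],
            "validation_nll_trace": [float(v) for v in self.validation_nll_trace],
            "best_params": self.best_params.to_dict(),
        }


def _adam_epochs(loss, flat, lr, n_epochs, tracker):
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8
    n_bad = 0
    for epoch in range(n_epochs):
        value, grad, extras = loss.value_and_grad(flat)
        tracker(flat, value, extras)
        if not np.isfinite(value) or not np.all(np.isfinite(grad)):
            n_bad += 1
            if n_bad >= 10 and tracker.n_finite == 0:
                return flat, "simulation_failed"
            continue
        t = epoch + 1
        gnorm = np.linalg.norm(grad)
        if gnorm > 1e6:  # keep second moments finite on wild landscapes
            grad = grad * (1e6 / gnorm)
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        flat = flat - lr * mhat / (np.sqrt(vhat) + eps)
    return flat, None


class _Tracker:
    """Per-epoch bookkeeping of traces and the early-stopping optimum."""

    def __init__(self, has_validation: bool):
        self.has_validation = has_validation
        self.train_trace: list[float] = []
        self.val_trace: list[float] = []
        self.best_score = np.inf
        self.best_flat = None
        self.n_finite = 0

    def __call__(self, flat, value, extras):
        tn = extras["train_nll"]
        vn = extras["validation_nll"]
        self.train_trace.append(tn)
        self.val_trace.append(vn)
        if np.isfinite(tn):
            self.n_finite += 1
        score = vn if self.has_validation else tn
        if np.isfinite(score) and score < self.best_score:
            self.best_score = score
            self.best_flat = np.asarray(flat, dtype=float).copy()


def train_single(
    problem: UDEProblem,
    dataset: Dataset,
    hyper: HyperParameters,
    init_theta=None,
    seed: int = 0,
    budget: Budget = Budget(),
    dt_max: float | None = None,
) -> FitResult:
    """One ADAM -> BFGS run with early stopping.

    ``init_theta`` are natural-scale mechanistic start values (defaults to
    the problem's stored values); the network is freshly initialised from
    ``seed``; the noise levels start at their closed-form optimum for the
    initial predictions.
    """
    loss = TrainingLoss(problem, dataset, lam=hyper.lam, dt_max=dt_max)
    ann0 = (
        ann_init(problem.ann_spec, seed=seed) if problem.ann_spec is not None else None
    )
    flat = loss.initial_vector(theta=init_theta, ann_params=ann0)
    has_val = bool(np.any(~loss.is_train))
    tracker = _Tracker(has_validation=has_val)

    flat, failed = _adam_epochs(loss, flat, hyper.learning_rate, budget.adam, tracker)
    status = None
    if failed is not None:
        status = failed
    else:
        n_bfgs = budget.total - budget.adam
        if n_bfgs > 0 and np.isfinite(loss(flat)):

            def fun(x):
                value, grad, extras = loss.value_and_grad(x)
                if not np.isfinite(value):
                    return 1e12, np.zeros_like(x)
                if not np.all(np.isfinite(grad)):
                    grad = np.where(np.isfinite(grad), grad, 0.0)
                gnorm = np.linalg.norm(grad)
                if gnorm > 1e8:  # keep the line search numerically sane
                    grad = grad * (1e8 / gnorm)
                return value, grad

            def cb(xk):
                value, _, extras = loss.value_and_grad(xk, with_grad=False)
                tracker(xk, value, extras)

            res = minimize(
                fun,
                flat,
                jac=True,
                method="BFGS",
                callback=cb,
                options={"maxiter": n_bfgs, "gtol": 1e-8},
            )
            flat = res.x
            # status 0: gradient tolerance reached; otherwise the budget ran
            # out or the line search hit precision limits
            status = "converged" if res.status == 0 else "budget_exhausted"
        elif tracker.n_finite == 0:
            status = "simulation_failed"
        else:
            status = "budget_exhausted"

    if tracker.best_flat is None:
        tracker.best_flat = flat
        status = status or "simulation_failed"
        if tracker.n_finite == 0:
            status = "simulation_failed"
    best_flat = tracker.best_flat
    selection = loss.nll_on(best_flat, partition=None)
    return FitResult(
        best_flat=best_flat,
        final_flat=flat,
        best_params=loss.template.unpack(best_flat),
        final_params=loss.template.unpack(flat),
        train_nll_trace=tracker.train_trace,
        validation_nll_trace=tracker.val_trace,
        status=status or "budget_exhausted",
        hyperparameters=hyper,
        seed=seed,
        best_validation_nll=tracker.best_score if has_val else np.inf,
        selection_nll=selection,
    )


def train_two_stage(
    problem_ode: UDEProblem,
    problem_ude: UDEProblem,
    dataset: Dataset,
    hyper: HyperParameters,
    init_theta=None,
    seed: int = 0,
    budget: Budget = Budget(),
    dt_max: float | None = None,
) -> FitResult:
    """Mechanistic-first training for problems that extend a consistent ODE.

    Stage 1 fits the mechanistic parameters alone; stage 2 starts the full
    hybrid model from the stage-1 estimates (parameters matched by name;
    parameters new to the hybrid model keep their stored values) and fits
    everything.  The stage-1 result is archived on the returned
    ``FitResult``.
    """
    stage1 = train_single(
        problem_ode,
        dataset,
        HyperParameters(ann_spec=None, learning_rate=hyper.learning_rate, lam=0.0),
        init_theta=init_theta,
        seed=seed,
        budget=budget,
        dt_max=dt_max,
    )
    if stage1.status == "simulation_failed":
        stage1.stage1 = None
        return stage1
    est = dict(
        zip(stage1.best_params.mechanistic.names, stage1.best_params.mechanistic.values)
    )
    theta2 = np.array(
        [
            est.get(name, problem_ude.parameters.values[i])
            for i, name in enumerate(problem_ude.parameters.names)
        ]
    )
    result = train_single(
        problem_ude,
        dataset,
        hyper,
        init_theta=theta2,
        seed=seed,
        budget=budget,
        dt_max=dt_max,
    )
    result.stage1 = stage1
    return result


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic, order-independent per-start seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def sample_starts(
    n_starts: int,
    ranges: HyperRanges,
    parameters: MechanisticParameterSet,
    seed: int,
    rho_halfwidth: float = 2.0,
):
    """Jointly Latin-hypercube-sample initial parameters and hyperparameters.

    Mechanistic start values are stratified on the unconstrained tanh
    coordinate within ``offset +- rho_halfwidth`` (log-like spacing inside
    the bounds); discrete hyperparameters take stratified levels from their
    listed sets; learning rate and regularisation strength are log-uniform,
    with the configured share of starts using no regularisation.  Returns a
    list of ``(init_theta, HyperParameters)`` and is deterministic for a
    fixed seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    n_m = len(parameters)
    d = n_m + 6
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    u = sampler.random(n_starts)
    starts = []
    for i in range(n_starts):
        ui = u[i]
        rho = parameters.offsets + (2.0 * ui[:n_m] - 1.0) * rho_halfwidth
        theta = parameters.from_rho(rho)
        uh = ui[n_m:]
        layers = ranges.hidden_layers[
            min(int(uh[0] * len(ranges.hidden_layers)), len(ranges.hidden_layers) - 1)
        ]
        width = ranges.widths[min(int(uh[1] * len(ranges.widths)), len(ranges.widths) - 1)]
        act = ranges.activations[
            min(int(uh[2] * len(ranges.activations)), len(ranges.activations) - 1)
        ]
        norm = ranges.input_normalisation[
            min(
                int(uh[3] * len(ranges.input_normalisation)),
                len(ranges.input_normalisation) - 1,
            )
        ]
        lr = ranges.learning_rate_range[0] * (
            ranges.learning_rate_range[1] / ranges.learning_rate_range[0]
        ) ** uh[4]
        p0 = ranges.none_share
        if uh[5] < p0 or ranges.lam_range is None:
            lam = 0.0
        else:
            w = (uh[5] - p0) / (1.0 - p0)
            lam = ranges.lam_range[0] * (
                ranges.lam_range[1] / ranges.lam_range[0]
            ) ** w
        starts.append(
            (
                theta,
                HyperParameters(
                    ann_spec=None,  # filled by the problem factory below
                    learning_rate=lr,
                    lam=lam,
                ),
            )
        )
        # attach the architecture; ANNSpec dimensions come from the factory
        starts[-1][1].__dict__["_arch"] = (layers, width, act, norm)
    return starts


@dataclass
class MultiStartResult:
    results: list[FitResult]
    best_index: int

    @property
    def best(self) -> FitResult:
        return self.results[self.best_index]


def run_multistart(
    problem_factory: Callable[[ANNSpec], UDEProblem] | UDEProblem,
    dataset: Dataset,
    n_starts: int,
    ranges: HyperRanges,
    seed: int,
    budget: Budget = Budget(),
    ann_io: tuple[int, int] | None = None,
    dt_max: float | None = None,
    parameters: MechanisticParameterSet | None = None,
    progress: Callable | None = None,
) -> MultiStartResult:
    """Multi-start optimisation with joint (hyper-)parameter sampling.

    ``problem_factory`` maps a sampled ``ANNSpec`` to a problem (or is a
    fixed problem whose network spec, if any, is reused).  The best model
    minimises the plain NLL over all records used during training.
    """
    if isinstance(problem_factory, UDEProblem):
        fixed = problem_factory
        ref = fixed

        def factory(spec):
            return fixed
    else:
        factory = problem_factory
        probe_arch = ANNSpec(
            n_inputs=ann_io[0],
            n_outputs=ann_io[1],
            n_hidden_layers=ranges.hidden_layers[0],
            width=ranges.widths[0],
            activation=ranges.activations[0],
        )
        ref = factory(probe_arch)
    params = parameters if parameters is not None else ref.parameters
    starts = sample_starts(n_starts, ranges, params, seed)
    results = []
    for i, (theta0, hyper) in enumerate(starts):
        layers, width, act, norm = hyper.__dict__.pop("_arch")
        if ann_io is not None and not isinstance(problem_factory, UDEProblem):
            hyper.ann_spec = ANNSpec(
                n_inputs=ann_io[0],
                n_outputs=ann_io[1],
                n_hidden_layers=layers,
                width=width,
                activation=act,
                input_normalisation=norm,
            )
            prob = factory(hyper.ann_spec)
        else:
            prob = factory(None)
            hyper.ann_spec = prob.ann_spec
        res = train_single(
            prob,
            dataset,
            hyper,
            init_theta=theta0,
            seed=child_seed(seed, i),
            budget=budget,
            dt_max=dt_max,
        )
        results.append(res)
        if progress is not None:
            progress(i, res)
    finite = [
        i for i, r in enumerate(results) if np.isfinite(r.selection_nll)
    ]
    if not finite:
        statuses = {}
        for r in results:
            statuses[r.status] = statuses.get(r.status, 0) + 1
        raise RuntimeError(f"all {n_starts} starts failed: {statuses}")
    best = min(finite, key=lambda i: results[i].selection_nll)
    return MultiStartResult(results=results, best_index=best)
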