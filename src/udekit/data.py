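"""Synthetic glycolysis datasets, train/validation splits and measurement I/O.

The glycolysis study grid crosses five sampling densities (8, 16, 31, 46 or
61 points per observable, uniform on t in [0, 1.5] including both
endpoints) with four noise levels (5, 10, 20 or 35 percent).  The noise
level maps to one additive Gaussian standard deviation per observable,

    sigma_s = (noise_percent / 100) * mean |ybar_s|  over the training window,

consistent with a single observable-specific sigma.  The noise-free truth
is also kept on the extrapolation window t in (1.5, 5], where prediction
quality is scored.

Splits follow fixed per-density bookkeeping: the known initial condition at
t = 0 is always a training record and does not take part in the split; the
remaining time points alternate between train and validation (even temporal
coverage without randomness) with counts 8 -> 4:3, 16 -> 7:8 and a 1:1
split (extra point to train) for 31, 46 and 61.  Measurement tables use a
tab-separated dialect with columns ``observableId``, ``time``,
``measurement``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .objective import Dataset
from .models.glycolysis import (
    GlycolysisConstants,
    REFERENCE_CONSTANTS,
    REFERENCE_X0,
    OBSERVABLE_NAMES,
    OBSERVABLE_INDICES,
    glycolysis_rhs,
)

__all__ = [
    "DataSetting",
    "SyntheticTruth",
    "GlycolysisDataGenerator",
    "generate_glycolysis_dataset",
    "split_dataset",
    "split_dataset_ratio",
    "load_measurements",
    "write_measurements",
    "load_boehm_measurements",
    "SPLIT_COUNTS",
]

CANONICAL_N_POINTS = (8, 16, 31, 46, 61)
CANONICAL_NOISE = (5.0, 10.0, 20.0, 35.0)

#: (train, validation) counts of the non-initial time points per density
SPLIT_COUNTS = {8: (4, 3), 16: (7, 8), 31: (15, 15), 46: (23, 22), 61: (30, 30)}

TRAIN_WINDOW = (0.0, 1.5)
TEST_WINDOW = (1.5, 5.0)
N_TEST_POINTS = 100


@dataclass(frozen=True)
class DataSetting:
    """One cell of the density x noise study grid."""

    n_points_per_observable: int = 46
    noise_percent: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_points_per_observable < 2:
            raise ValueError("need at least two time points")
        if self.noise_percent < 0:
            raise ValueError("noise level must be non-negative")

    @property
    def canonical(self) -> bool:
        return (
            self.n_points_per_observable in CANONICAL_N_POINTS
            and self.noise_percent in CANONICAL_NOISE
        )


@dataclass
class SyntheticTruth:
    """Noise-free reference trajectories and the noise scale actually used."""

    train_times: np.ndarray
    train_values: np.ndarray  # (n_t, n_o)
    test_times: np.ndarray
    test_values: np.ndarray
    sigma: np.ndarray  # per observable
    observable_names: list[str] = field(default_factory=lambda: list(OBSERVABLE_NAMES))


class GlycolysisDataGenerator:
    """Generates noisy study datasets from one reference simulation.

    The reference trajectory is simulated once at tight tolerances and
    cached, so the noise-free truth is identical across noise settings and
    repeated draws are cheap.
    """

    def __init__(
        self,
        constants: GlycolysisConstants = REFERENCE_CONSTANTS,
        x0: np.ndarray = REFERENCE_X0,
        rtol: float = 1e-10,
        atol: float = 1e-12,
    ):
        self.constants = constants
        self.x0 = np.asarray(x0, dtype=float)
        self._sol = None
        self._rtol, self._atol = rtol, atol

    def _solution(self):
        if self._sol is None:
            sol = solve_ivp(
                lambda t, x: glycolysis_rhs(t, x, self.constants),
                (0.0, TEST_WINDOW[1]),
                self.x0,
                rtol=self._rtol,
                atol=self._atol,
                dense_output=True,
            )
            if not sol.success:
                raise RuntimeError(f"reference simulation failed: {sol.message}")
            self._sol = sol
        return self._sol

    def truth_states(self, times) -> np.ndarray:
        return self._solution().sol(np.asarray(times, dtype=float)).T

    def truth_observables(self, times) -> np.ndarray:
        return self.truth_states(times)[:, OBSERVABLE_INDICES]

    def truth(self, setting: DataSetting) -> SyntheticTruth:
        n = setting.n_points_per_observable
        train_times = np.linspace(*TRAIN_WINDOW, n)
        test_times = (
            TEST_WINDOW[0]
            + (TEST_WINDOW[1] - TEST_WINDOW[0])
            * np.arange(1, N_TEST_POINTS + 1)
            / N_TEST_POINTS
        )
        train_values = self.truth_observables(train_times)
        sigma = (setting.noise_percent / 100.0) * np.mean(
            np.abs(train_values), axis=0
        )
        return SyntheticTruth(
            train_times=train_times,
            train_values=train_values,
            test_times=test_times,
            test_values=self.truth_observables(test_times),
            sigma=sigma,
        )

    def generate(self, setting: DataSetting, split: bool = True):
        """One noisy dataset realisation plus its noise-free truth."""
        truth = self.truth(setting)
        rng = np.random.default_rng(setting.seed)
        noisy = truth.train_values + rng.normal(
            scale=truth.sigma if np.any(truth.sigma > 0) else 0.0,
            size=truth.train_values.shape,
        ) if np.any(truth.sigma > 0) else truth.train_values.copy()
        rows = []
        for j, name in enumerate(OBSERVABLE_NAMES):
            for i, t in enumerate(truth.train_times):
                rows.append(
                    {
                        "observableId": name,
                        "time": float(t),
                        "measurement": float(noisy[i, j]),
                        "is_initial_condition": bool(t == 0.0),
                    }
                )
        dataset = Dataset(
            records=pd.DataFrame(rows), observable_names=list(OBSERVABLE_NAMES)
        )
        if split:
            dataset = split_dataset(dataset, setting.n_points_per_observable)
        return dataset, truth


def generate_glycolysis_dataset(
    setting: DataSetting,
    reference: GlycolysisConstants = REFERENCE_CONSTANTS,
    split: bool = True,
):
    """Convenience wrapper building a fresh generator per call."""
    return GlycolysisDataGenerator(constants=reference).generate(setting, split=split)


def split_dataset(dataset: Dataset, n_points: int) -> Dataset:
    """Deterministic train/validation partition by time point.

    The t = 0 record is always training; the remaining points alternate so
    that validation spreads evenly over the window, with the alternation
    phase chosen to reproduce the fixed per-density counts.  Unknown
    densities fall back to a 1:1 alternation with a warning.
    """
    df = dataset.records.copy()
    times = np.sort(df["time"].unique())
    noninit = times[times > times.min()] if times.min() == 0.0 else times
    m = noninit.size
    required = SPLIT_COUNTS.get(n_points)
    if required is None:
        warnings.warn(
            f"no canonical split for {n_points} points; using a 1:1 alternation",
            stacklevel=2,
        )
        required = (int(np.ceil(m / 2)), m // 2)
    for start_with_train in (True, False):
        labels = {
            t: ("train" if (i % 2 == 0) == start_with_train else "validation")
            for i, t in enumerate(noninit)
        }
        counts = (
            sum(1 for v in labels.values() if v == "train"),
            sum(1 for v in labels.values() if v == "validation"),
        )
        if counts == tuple(required):
            break
    else:
        raise ValueError(
            f"cannot realise a {required} split of {m} non-initial points"
        )
    if times.min() == 0.0:
        labels[times.min()] = "train"
    df["partition"] = df["time"].map(labels)
    df["is_initial_condition"] = df["time"] == 0.0 if times.min() == 0.0 else False
    return Dataset(records=df, observable_names=list(dataset.observable_names))


def split_dataset_ratio(dataset: Dataset, ratio: tuple[int, int] = (4, 1)) -> Dataset:
    """Ratio-based split by time point (used for the measured STAT5 data).

    Every block of ``train + validation`` consecutive time points sends its
    last ``validation`` points to the validation set.
    """
    r_t, r_v = ratio
    block = r_t + r_v
    df = dataset.records.copy()
    times = np.sort(df["time"].unique())
    labels = {
        t: ("validation" if i % block >= r_t else "train")
        for i, t in enumerate(times)
    }
    df["partition"] = df["time"].map(labels)
    return Dataset(records=df, observable_names=list(dataset.observable_names))


def write_measurements(dataset: Dataset, path) -> None:
    """Write a measurement table (tab-separated, observableId/time/measurement
    plus the partition bookkeeping columns)."""
    dataset.records.to_csv(path, sep="\t", index=False)


def load_measurements(path, observable_names: list[str] | None = None) -> Dataset:
    """Read a tab-separated measurement table.

    Requires columns ``observableId``, ``time``, ``measurement``; malformed
    numeric fields are reported with their line number.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("observableId", "time", "measurement") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("time", "measurement"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if coerced.isna().any():
            bad_rows = np.nonzero(coerced.isna().to_numpy())[0]
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: malformed {col!r} value on line {int(bad_rows[0]) + 2}"
            )
        df[col] = coerced
    return Dataset(records=df, observable_names=observable_names or [])


def load_boehm_measurements(split: bool = True) -> Dataset:
    """The published STAT5 phospho-ratio time courses (16 time points x 3
    observables), with the 4:1 train/validation split applied by default."""
    ref = resources.files("udekit.datasets") / "boehm_stat5.tsv"
    with resources.as_file(ref) as path:
        ds = load_measurements(path)
    if split:
        ds = split_dataset_ratio(ds, (4, 1))
    return ds


def load_boehm_reference() -> dict:
    """Published reference parameters and noise levels for the STAT5 data."""
    ref = resources.files("udekit.datasets") / "boehm_reference.json"
    return json.loads(ref.read_text())
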