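"""Single-start, two-stage and multi-start optimisation behaviour."""

import numpy as np
import pandas as pd
import pytest

from udekit.models.base import UDEProblem
from udekit.models import build_glycolysis_ude
from udekit.nn import ANNSpec
from udekit.objective import Dataset
from udekit.parameters import MechanisticParameterSet
from udekit.training import (
    Budget,
    HyperParameters,
    HyperRanges,
    child_seed,
    run_multistart,
    sample_starts,
    train_single,
    train_two_stage,
)


def decay_problem(with_ann=False, k=0.7):
    spec = ANNSpec(1, 1, 1, 3, "tanh") if with_ann else None
    placement = np.array([[1.0]]) if with_ann else None
    return UDEProblem(
        name="decay_toy",
        state_names=["x"],
        observable_names=["x"],
        x0=np.array([1.0]),
        parameters=MechanisticParameterSet(
            names=["k"], values=[k], lower_bounds=[0.05], upper_bounds=[10.0]
        ),
        rhs_mechanistic=lambda t, x, th: -th[0] * x,
        rhs_jac_x=lambda t, x, th: np.array([[-th[0]]]),
        rhs_jac_theta=lambda t, x, th: np.array([[-x[0]]]),
        ann_spec=spec,
        ann_state_matrix=placement,
        ann_input_indices=np.array([0]) if with_ann else None,
        observable_indices=np.array([0]),
        t_span=(0.0, 5.0),
        dt_max=0.05,
    )


def decay_dataset(k=0.7, n=9, validation=True, noise=0.0, seed=0):
    times = np.linspace(0.0, 4.0, n)
    rng = np.random.default_rng(seed)
    rows = []
    for i, t in enumerate(times):
        rows.append(
            {
                "observableId": "x",
                "time": float(t),
                "measurement": float(np.exp(-k * t) + noise * rng.standard_normal()),
                "partition": "validation" if validation and i % 3 == 2 else "train",
            }
        )
    return Dataset(records=pd.DataFrame(rows))


class TestTrainSingle:
    def test_recovers_decay_rate_from_noise_free_data(self):
        prob = decay_problem()
        ds = decay_dataset(k=0.7)
        hyper = HyperParameters(ann_spec=None, learning_rate=0.05)
        res = train_single(
            prob, ds, hyper, init_theta=[2.0], seed=0, budget=Budget(100, 300)
        )
        k_hat = res.best_params.mechanistic.values[0]
        assert k_hat == pytest.approx(0.7, rel=0.01)

    def test_early_stopping_bookkeeping(self):
        prob = decay_problem()
        ds = decay_dataset()
        res = train_single(
            prob,
            ds,
            HyperParameters(ann_spec=None, learning_rate=0.05),
            init_theta=[3.0],
            budget=Budget(60, 60),
        )
        trace = np.array(res.validation_nll_trace)
        finite = trace[np.isfinite(trace)]
        assert res.best_validation_nll == pytest.approx(finite.min())

    def test_without_validation_best_is_min_train(self):
        prob = decay_problem()
        ds = decay_dataset(validation=False)
        res = train_single(
            prob,
            ds,
            HyperParameters(ann_spec=None, learning_rate=0.05),
            init_theta=[3.0],
            budget=Budget(50, 50),
        )
        trace = np.array(res.train_nll_trace)
        loss_at_best = trace[np.isfinite(trace)].min()
        # best vector corresponds to the trace minimum (best-so-far rule)
        assert res.selection_nll <= loss_at_best + 1e-6

    def test_strong_regularisation_suppresses_network(self):
        prob = decay_problem(with_ann=True)
        # noisy data keeps the jointly estimated sigma bounded away from the
        # degenerate noise-free optimum, so the weight penalty dominates
        ds = decay_dataset(noise=0.02)
        res = train_single(
            prob,
            ds,
            HyperParameters(ann_spec=prob.ann_spec, learning_rate=0.05, lam=1e6),
            init_theta=[1.5],
            seed=1,
            budget=Budget(150, 400),
        )
        # the converged minimiser has a suppressed network ...
        assert np.linalg.norm(res.final_params.ann.values) < 1e-3
        # ... and the mechanistic parameter still converges (early stopping may
        # retain an earlier iterate, so allow the looser best-vector norm too)
        assert np.linalg.norm(res.best_params.ann.values) < 0.05
        assert res.best_params.mechanistic.values[0] == pytest.approx(0.7, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        prob = decay_problem(with_ann=True)
        ds = decay_dataset()
        hyper = HyperParameters(ann_spec=prob.ann_spec, learning_rate=0.02, lam=0.1)
        a = train_single(prob, ds, hyper, init_theta=[1.2], seed=5, budget=Budget(30, 60))
        b = train_single(prob, ds, hyper, init_theta=[1.2], seed=5, budget=Budget(30, 60))
        np.testing.assert_allclose(a.best_flat, b.best_flat, atol=1e-10)
        assert a.train_nll_trace == b.train_nll_trace


class TestTwoStage:
    def test_stage2_does_not_regress_and_archives_stage1(self):
        prob_ode = decay_problem(with_ann=False)
        prob_ude = decay_problem(with_ann=True)
        ds = decay_dataset(noise=0.02)
        hyper = HyperParameters(
            ann_spec=prob_ude.ann_spec, learning_rate=0.02, lam=0.01
        )
        res = train_two_stage(
            prob_ode, prob_ude, ds, hyper, init_theta=[2.0], budget=Budget(80, 200)
        )
        assert res.stage1 is not None
        assert res.stage1.stage1 is None
        # the hybrid model nests the mechanistic one
        assert res.selection_nll <= res.stage1.selection_nll + 1e-8
        # stage-2 traces do not contain the stage-1 trace
        assert len(res.train_nll_trace) <= 200


class TestSampling:
    def ranges(self):
        return HyperRanges()

    def params(self):
        return MechanisticParameterSet(
            names=["a", "b"],
            values=[1.0, 1.0],
            lower_bounds=[0.1, 0.5],
            upper_bounds=[10.0, 2.0],
        )

    def test_latin_hypercube_stratification(self):
        n = 8
        starts = sample_starts(n, self.ranges(), self.params(), seed=3)
        p = self.params()
        # each start's parameter lies in a distinct stratum per dimension
        for dim in range(2):
            rho = np.array([p.to_rho(s[0])[dim] for s in starts])
            u = (rho - p.offsets[dim] + 2.0) / 4.0
            strata = np.floor(u * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_within_bounds_and_deterministic(self):
        starts = sample_starts(16, self.ranges(), self.params(), seed=9)
        again = sample_starts(16, self.ranges(), self.params(), seed=9)
        p = self.params()
        for (t1, h1), (t2, h2) in zip(starts, again):
            np.testing.assert_array_equal(t1, t2)
            assert h1.learning_rate == h2.learning_rate and h1.lam == h2.lam
            assert np.all((p.lower_bounds < t1) & (t1 < p.upper_bounds))

    def test_hyperparameters_from_listed_sets(self):
        ranges = self.ranges()
        starts = sample_starts(64, ranges, self.params(), seed=1)
        archs = [h.__dict__["_arch"] for _, h in starts]
        layers = {a[0] for a in archs}
        widths = {a[1] for a in archs}
        acts = {a[2] for a in archs}
        assert layers <= {1, 2, 3, 4} and layers == {1, 2, 3, 4}
        assert widths <= {3, 5, 10} and widths == {3, 5, 10}
        assert acts == {"tanh", "relu", "gaussian-rbf", "swish"}
        for _, h in starts:
            if h.lam > 0:
                assert 1e-4 <= h.lam <= 1e1
            assert 1e-4 <= h.learning_rate <= 1e-1
        assert any(h.lam == 0.0 for _, h in starts)

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            HyperRanges(widths=())


class TestMultiStart:
    def test_single_start_reduces_to_train_single(self, dataset_16pts):
        ds, _ = dataset_16pts
        ranges = HyperRanges(
            hidden_layers=(1,), widths=(3,), activations=("tanh",),
            input_normalisation=(False,),
        )
        ms = run_multistart(
            lambda spec: build_glycolysis_ude(spec),
            ds,
            n_starts=1,
            ranges=ranges,
            seed=1,
            budget=Budget(10, 20),
            ann_io=(7, 1),
        )
        assert ms.best_index == 0
        assert len(ms.results) == 1

    def test_best_is_min_selection_nll(self, dataset_16pts):
        ds, _ = dataset_16pts
        ranges = HyperRanges(
            hidden_layers=(1,), widths=(3, 5), activations=("tanh",),
            input_normalisation=(False,),
        )
        ms = run_multistart(
            lambda spec: build_glycolysis_ude(spec),
            ds,
            n_starts=4,
            ranges=ranges,
            seed=7,
            budget=Budget(15, 30),
            ann_io=(7, 1),
        )
        sel = [r.selection_nll for r in ms.results]
        assert ms.best.selection_nll == min(s for s in sel if np.isfinite(s))
        for r in ms.results:
            assert r.hyperparameters.ann_spec.width in (3, 5)


def test_child_seed_properties():
    seeds = [child_seed(1, i) for i in range(100)]
    assert len(set(seeds)) == 100
    assert all(0 <= s < 2**31 for s in seeds)
    assert child_seed(1, 5) == child_seed(1, 5)
    assert child_seed(1, 5) != child_seed(2, 5)
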