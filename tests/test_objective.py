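"""Likelihood, regularisation and noise estimation."""

import numpy as np
import pandas as pd
import pytest

from udekit.nn import ANNParameters
from udekit.objective import Dataset, TrainingLoss, nll, optimal_sigma, regularised_loss
from udekit.parameters import NoiseParameters


def make_dataset(records):
    return Dataset(records=pd.DataFrame(records))


class TestNLL:
    def test_zero_residuals_unit_sigma(self):
        ds = make_dataset(
            [
                {"observableId": "a", "time": 0.0, "measurement": 1.0},
                {"observableId": "a", "time": 1.0, "measurement": 2.0},
            ]
        )
        value = nll(np.array([1.0, 2.0]), ds, NoiseParameters([1.0]))
        assert value == pytest.approx(np.log(2 * np.pi), rel=1e-12)

    def test_single_unit_residual(self):
        ds = make_dataset([{"observableId": "a", "time": 0.0, "measurement": 1.0}])
        value = nll(np.array([0.0]), ds, NoiseParameters([1.0]))
        assert value == pytest.approx(0.5 * (np.log(2 * np.pi) + 1.0), rel=1e-12)

    def test_nonfinite_prediction_is_infinite(self):
        ds = make_dataset([{"observableId": "a", "time": 0.0, "measurement": 1.0}])
        assert np.isinf(nll(np.array([np.nan]), ds, NoiseParameters([1.0])))

    def test_additive_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        rows = [
            {"observableId": ["a", "b"][i % 2], "time": float(i), "measurement": rng.normal()}
            for i in range(10)
        ]
        preds = rng.normal(size=10)
        sigma = NoiseParameters([0.7, 1.3])
        ds = make_dataset(rows)
        total = nll(preds, ds, sigma)
        parts = sum(
            nll(preds[i : i + 1], make_dataset(rows[i : i + 1]),
                NoiseParameters([sigma.sigma[i % 2]]))
            for i in range(10)
        )
        assert total == pytest.approx(parts, rel=1e-12)
        perm = rng.permutation(10)
        ds2 = make_dataset([rows[i] for i in perm])
        assert nll(preds[perm], ds2, sigma) == pytest.approx(total, rel=1e-12)

    def test_published_stat5_reference_value(self):
        """Reference parameters on the published measurements reproduce the
        printed negative log-likelihood of 138.22."""
        from udekit.data import load_boehm_measurements, load_boehm_reference
        from udekit.models import build_stat5_ode
        from udekit.simulate import integrate

        ds = load_boehm_measurements(split=False)
        ref = load_boehm_reference()
        prob = build_stat5_ode()
        theta = np.array([ref["parameters"][n] for n in prob.parameters.names])
        times = ds.times
        traj = integrate(prob, times, theta=theta, rtol=1e-10, atol=1e-12)
        assert traj.success
        y = prob.observe(times, traj.states, theta)
        t_pos = {t: i for i, t in enumerate(times)}
        o_pos = {n: i for i, n in enumerate(prob.observable_names)}
        preds = np.array(
            [
                y[t_pos[r.time], o_pos[r.observableId]]
                for r in ds.records.itertuples()
            ]
        )
        sigma = NoiseParameters(
            [ref["sigma"][n] for n in prob.observable_names]
        )
        assert nll(preds, ds, sigma) == pytest.approx(138.22, abs=0.005)


class TestRegularisedLoss:
    def test_zero_weights_no_penalty(self):
        assert regularised_loss(3.5, ANNParameters(np.zeros(4), 4), 2.0) == 3.5

    def test_hand_evaluated_penalty(self):
        # lambda * ||theta||^2 / n = 2 * 4 / 4 = 2
        assert regularised_loss(1.0, np.ones(4), 2.0) == pytest.approx(3.0)

    def test_lambda_zero_is_plain_nll(self):
        assert regularised_loss(1.7, np.ones(10), 0.0) == pytest.approx(1.7)

    def test_monotone_in_lambda(self):
        w = np.array([0.3, -1.2, 0.8])
        losses = [regularised_loss(1.0, w, lam) for lam in (0.0, 0.1, 1.0, 10.0)]
        assert np.all(np.diff(losses) >= 0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            regularised_loss(1.0, np.ones(2), -0.1)


class TestOptimalSigma:
    def test_hand_values(self):
        s = optimal_sigma({"a": [1.0, -1.0]})
        assert s.sigma[0] == pytest.approx(1.0)
        s = optimal_sigma({"a": [3.0]})
        assert s.sigma[0] == pytest.approx(3.0)

    def test_is_the_likelihood_optimum(self):
        rng = np.random.default_rng(1)
        residuals = {"a": rng.normal(size=12), "b": 2 * rng.normal(size=8)}
        best = optimal_sigma(residuals)
        rows, preds = [], []
        for name, rs in residuals.items():
            for i, r in enumerate(rs):
                rows.append({"observableId": name, "time": float(i), "measurement": r})
                preds.append(0.0)
        ds = make_dataset(rows)
        base = nll(np.array(preds), ds, best)
        for factor in (0.5, 0.9, 1.1, 2.0):
            for k in range(2):
                sig = best.sigma.copy()
                sig[k] *= factor
                assert nll(np.array(preds), ds, NoiseParameters(sig)) > base

    def test_stationarity_by_finite_differences(self):
        residuals = {"a": [0.5, -0.7, 1.1]}
        best = optimal_sigma(residuals)
        rows = [
            {"observableId": "a", "time": float(i), "measurement": r}
            for i, r in enumerate(residuals["a"])
        ]
        ds = make_dataset(rows)
        preds = np.zeros(3)
        h = 1e-6
        up = nll(preds, ds, NoiseParameters(best.sigma + h))
        dn = nll(preds, ds, NoiseParameters(best.sigma - h))
        assert (up - dn) / (2 * h) == pytest.approx(0.0, abs=1e-4)

    def test_empty_observable_rejected(self):
        with pytest.raises(ValueError):
            optimal_sigma({"a": []})


class TestDataset:
    def test_unknown_observable_rejected(self):
        with pytest.raises(ValueError):
            Dataset(
                records=pd.DataFrame(
                    [{"observableId": "zz", "time": 0.0, "measurement": 1.0}]
                ),
                observable_names=["a"],
            )

    def test_partition_counts(self, dataset_16pts):
        ds, _ = dataset_16pts
        assert ds.counts() == {"train": 8, "validation": 8}

    def test_validation_loss_excludes_regularisation(self, glyc_ude, dataset_16pts):
        ds, _ = dataset_16pts
        rng = np.random.default_rng(0)
        plain = TrainingLoss(glyc_ude, ds, lam=0.0)
        heavy = TrainingLoss(glyc_ude, ds, lam=1e4)
        flat = plain.initial_vector()
        n_m = len(glyc_ude.parameters)
        flat[n_m : n_m + plain.template.n_ann] = 0.3 * rng.standard_normal(
            plain.template.n_ann
        )
        # identical validation NLL despite very different training objectives
        v0 = plain.value_and_grad(flat, with_grad=False)
        v1 = heavy.value_and_grad(flat, with_grad=False)
        assert v0[2]["validation_nll"] == pytest.approx(v1[2]["validation_nll"])
        assert v1[0] > v0[0] + 100.0
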