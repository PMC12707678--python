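"""Network construction, perturbed batches, training loop contracts."""

import numpy as np
import pandas as pd
import pytest

from pesnet.network import (
    MLP,
    NetworkSpec,
    TrainConfig,
    build_network,
    fit,
    make_perturbed_inputs,
    predict,
)
from pesnet.priors import (
    ConstraintWeights,
    PriorEffect,
    constraint_loss_grads,
    manual_lambda_weights,
)


def small_regression_data(seed=0, n=200, slope=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 1))
    y = slope * X[:, 0]
    cols = ["x"]
    split = n // 2
    return (
        pd.DataFrame(X[:split], columns=cols),
        pd.Series(y[:split]),
        pd.DataFrame(X[split:], columns=cols),
        pd.Series(y[split:]),
    )


class TestBuildAndPredict:
    def test_seeded_initialization_is_deterministic(self):
        spec = NetworkSpec(n_inputs=4, hidden_sizes=(16,))
        a, b = build_network(spec, seed=0), build_network(spec, seed=0)
        assert np.array_equal(a.get_flat(), b.get_flat())
        c = build_network(spec, seed=1)
        assert not np.array_equal(a.get_flat(), c.get_flat())

    def test_classification_outputs_are_probabilities(self):
        model = build_network(NetworkSpec(3, (16,), task="binary_classification"), seed=0)
        p = predict(model, np.random.default_rng(0).normal(size=(50, 3)))
        assert np.all((p > 0) & (p < 1))

    def test_rate_outputs_are_positive(self):
        model = build_network(NetworkSpec(2, (8,), task="rate_regression"), seed=0)
        f = predict(model, np.random.default_rng(0).normal(size=(50, 2)))
        assert np.all(f > 0)

    def test_predict_is_pure(self):
        model = build_network(NetworkSpec(2, (8,)), seed=0)
        X = np.random.default_rng(1).normal(size=(20, 2))
        assert np.array_equal(predict(model, X), predict(model, X))

    def test_width_mismatch_rejected(self):
        model = build_network(NetworkSpec(3, (8,)), seed=0)
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((5, 2)))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(0, (8,))
        with pytest.raises(ValueError):
            NetworkSpec(3, (0,))
        with pytest.raises(ValueError):
            NetworkSpec(3, (8,), task="multiclass")


class TestPerturbedInputs:
    def test_src_shifts_plus_h(self):
        X = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        pb = make_perturbed_inputs(X, [PriorEffect("a", "SRC", 1.0)])
        assert np.allclose(pb.perturbed[0][:, 0], 1.0)
        assert np.allclose(pb.perturbed[0][:, 1], 0.0)

    def test_or_shifts_minus_h(self):
        X = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        pb = make_perturbed_inputs(X, [PriorEffect("b", "OR", 2.0)])  # h = 1/2
        assert np.allclose(pb.perturbed[0][:, 1], -0.5)
        assert np.allclose(pb.perturbed[0][:, 0], 0.0)

    def test_one_matrix_per_prior_each_single_column(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a", "b", "c"])
        priors = [PriorEffect("a", "SRC", 1.0), PriorEffect("c", "RR", 0.5)]
        pb = make_perturbed_inputs(X, priors)
        assert len(pb.perturbed) == 2
        for k, j in enumerate(pb.columns):
            diff = pb.perturbed[k] - pb.base
            changed = np.nonzero(np.any(diff != 0, axis=0))[0]
            assert list(changed) == [j]
            assert np.allclose(np.abs(diff[:, j]), abs(priors[k].step))

    def test_unknown_variable_rejected(self):
        X = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        with pytest.raises(KeyError, match="z"):
            make_perturbed_inputs(X, [PriorEffect("z", "SRC", 1.0)])


class TestFit:
    def test_agnostic_fit_recovers_noiseless_linear_signal(self):
        Xtr, ytr, Xva, yva = small_regression_data()
        model = build_network(NetworkSpec(1, (32,)), seed=0)
        fit(model, Xtr, ytr, Xva, yva, config=TrainConfig(batch_size=16, max_epochs=300, seed=0))
        pred = predict(model, Xva)
        ss_res = np.sum((pred - yva.to_numpy()) ** 2)
        ss_tot = np.sum((yva - yva.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95

    def test_constraint_dominated_limit_pins_marginal_slope(self):
        # data slope 2 vs prior slope 5 with lambda0 -> 0: constraint wins
        Xtr, ytr, Xva, yva = small_regression_data(slope=2.0)
        prior = PriorEffect("x", "SRC", 5.0)
        weights = manual_lambda_weights(0.01, 1)
        model = build_network(NetworkSpec(1, (32,)), seed=0)
        fit(model, Xtr, ytr, Xva, yva, priors=[prior], weights=weights,
            config=TrainConfig(batch_size=16, max_epochs=400, seed=0))
        X = Xva.to_numpy()
        slope = np.mean(predict(model, X + 1.0) - predict(model, X))
        assert slope == pytest.approx(5.0, rel=0.05)

    def test_identical_seeds_reproduce_histories(self):
        Xtr, ytr, Xva, yva = small_regression_data()
        prior = PriorEffect("x", "SRC", 2.0)
        w = manual_lambda_weights(0.5, 1)
        results = []
        for _ in range(2):
            model = build_network(NetworkSpec(1, (8,)), seed=3)
            r = fit(model, Xtr, ytr, Xva, yva, priors=[prior], weights=w,
                    config=TrainConfig(batch_size=32, max_epochs=30, patience=30, seed=3))
            results.append(r)
        pd.testing.assert_frame_equal(results[0].history, results[1].history)
        assert np.array_equal(results[0].model.get_flat(), results[1].model.get_flat())

    def test_no_priors_matches_lambda0_one_trajectory(self):
        # with lambda0 = 1 the composite objective IS the prediction loss,
        # so training must follow the agnostic trajectory exactly
        Xtr, ytr, Xva, yva = small_regression_data()
        m1 = build_network(NetworkSpec(1, (8,)), seed=5)
        r1 = fit(m1, Xtr, ytr, Xva, yva,
                 config=TrainConfig(batch_size=32, max_epochs=20, patience=20, seed=5))
        m2 = build_network(NetworkSpec(1, (8,)), seed=5)
        eps = 1e-9  # a vanishing constraint weight, numerically negligible
        w = ConstraintWeights(lambda0=1 - eps, lambdas=(eps,))
        r2 = fit(m2, Xtr, ytr, Xva, yva, priors=[PriorEffect("x", "SRC", 2.0)], weights=w,
                 config=TrainConfig(batch_size=32, max_epochs=20, patience=20, seed=5))
        assert np.allclose(r1.model.get_flat(), r2.model.get_flat(), atol=1e-6)

    def test_early_stopping_restores_best_epoch(self):
        Xtr, ytr, Xva, yva = small_regression_data()
        model = build_network(NetworkSpec(1, (16,)), seed=0)
        r = fit(model, Xtr, ytr, Xva, yva,
                config=TrainConfig(batch_size=16, max_epochs=200, seed=0))
        assert r.best_epoch <= r.stopped_epoch <= 200
        monitored = r.history["val_monitored"].to_numpy()
        assert monitored[r.best_epoch - 1] == monitored.min()

    def test_history_tracks_every_loss_term(self):
        Xtr, ytr, Xva, yva = small_regression_data()
        model = build_network(NetworkSpec(1, (8,)), seed=0)
        r = fit(model, Xtr, ytr, Xva, yva, priors=[PriorEffect("x", "SRC", 2.0)],
                weights=manual_lambda_weights(0.5, 1),
                config=TrainConfig(batch_size=32, max_epochs=5, patience=5, seed=0))
        for col in ("train_pred", "val_pred", "train_meta_0", "val_meta_0", "val_monitored"):
            assert col in r.history.columns

    def test_misaligned_weights_rejected(self):
        Xtr, ytr, Xva, yva = small_regression_data()
        model = build_network(NetworkSpec(1, (8,)), seed=0)
        with pytest.raises(ValueError, match="aligned"):
            fit(model, Xtr, ytr, Xva, yva, priors=[PriorEffect("x", "SRC", 1.0)],
                weights=ConstraintWeights(1.0))


class TestGradients:
    @pytest.mark.parametrize("etype,task", [
        ("SRC", "regression"),
        ("OR", "binary_classification"),
        ("RR", "rate_regression"),
    ])
    def test_violated_constraint_has_nonzero_finite_difference_gradient(self, etype, task):
        """Analytic constraint gradients match central finite differences."""
        from pesnet.network import _constraint_terms

        rng = np.random.default_rng(0)
        spec = NetworkSpec(2, (4,), task=task)
        model = build_network(spec, seed=0)
        prior = PriorEffect("a", etype, 1.5)
        X = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        pb = make_perturbed_inputs(X, [prior])

        def loss_at(flat):
            model.set_flat(flat)
            _, _, _, terms = _constraint_terms(model, pb, [prior], want_grads=False)
            return terms[0][0]

        flat0 = model.get_flat().copy()
        _, _, cache_base, terms = _constraint_terms(model, pb, [prior], want_grads=True)
        _, d_b, d_p, cache_p = terms[0]
        g = model.backward(cache_p, d_p)
        g = [a + b for a, b in zip(g, model.backward(cache_base, d_b))]
        analytic = np.concatenate([x.ravel() for x in g])

        assert np.linalg.norm(analytic) > 1e-8  # the constraint is violated
        eps = 1e-6
        idx = rng.choice(flat0.size, size=10, replace=False)
        for i in idx:
            e = np.zeros_like(flat0)
            e[i] = eps
            fd = (loss_at(flat0 + e) - loss_at(flat0 - e)) / (2 * eps)
            assert fd == pytest.approx(analytic[i], rel=1e-3, abs=1e-7)
        model.set_flat(flat0)


def test_conflicting_prior_shifts_slope_monotonically_with_weight():
    """Raising the constraint weight moves the learned marginal effect from
    the data-implied slope toward the prior value."""
    Xtr, ytr, Xva, yva = small_regression_data(slope=2.0)
    prior = PriorEffect("x", "SRC", 5.0)
    slopes = []
    for lam0 in (0.9, 0.5, 0.05):
        model = build_network(NetworkSpec(1, (16,)), seed=0)
        fit(model, Xtr, ytr, Xva, yva, priors=[prior],
            weights=manual_lambda_weights(lam0, 1),
            config=TrainConfig(batch_size=32, max_epochs=200, seed=0))
        X = Xva.to_numpy()
        slopes.append(float(np.mean(predict(model, X + 1.0) - predict(model, X))))
    assert slopes[0] < slopes[1] < slopes[2]
    assert 2.0 < slopes[0] < 5.0 and slopes[2] > 4.0
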