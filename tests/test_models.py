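"""Recurrent classifiers: exact gradients, architecture contracts,
reduction of the decay cell to a plain gated unit, and training behavior."""

import numpy as np
import pytest

from ahecast.models import (
    TrainSpec,
    baseline_logreg,
    baseline_svm,
    build_decay_gru,
    build_lstm,
    fit,
    predict_proba,
)
from ahecast.nn import GRUDClassifier, LSTMClassifier, binary_cross_entropy, sigmoid
from ahecast.evaluation import auroc
from ahecast.windowing import WindowDataset


def toy_dataset(n=80, T=10, seed=0, signal=0.3, label_noise=0.0):
    """Half positives with a downward MAP trend, half flat negatives."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(0.5, 0.05, (n, T, 3))
    trend = np.linspace(0.0, signal, T)
    X[y == 1, :, 0] -= trend
    X = np.clip(X, 0.0, 1.0)
    if label_noise > 0:
        flip = rng.random(n) < label_noise
        y = np.where(flip, 1 - y, y)
    delta = np.ones((n, T, 3))
    delta[:, 0, :] = 0.0
    return WindowDataset(
        obs_length=T,
        gap_length=10,
        X=X,
        X_raw=X.copy(),
        mask=np.ones((n, T, 3)),
        delta=delta,
        x_last=X.copy(),
        y=y,
        patient_ids=np.array([f"p{i}" for i in range(n)], dtype=object),
        start_indices=np.zeros(n, dtype=int),
    )


def numerical_grads(model, inputs, y, keys, eps=1e-6, stride=7):
    out = {}
    for key in keys:
        p = model.params[key]
        idxs = range(0, p.size, max(1, p.size // stride))
        grads = {}
        for idx in idxs:
            orig = p.flat[idx]
            p.flat[idx] = orig + eps
            probs, _ = model.forward(inputs, train=False)
            lp = binary_cross_entropy(probs, y)
            p.flat[idx] = orig - eps
            probs, _ = model.forward(inputs, train=False)
            lm = binary_cross_entropy(probs, y)
            p.flat[idx] = orig
            grads[idx] = (lp - lm) / (2 * eps)
        out[key] = grads
    return out


class TestLSTMArchitecture:
    def test_forward_probabilities_in_unit_interval(self):
        model = build_lstm(timesteps=20, seed=0)
        X = np.random.default_rng(0).random((8, 20, 3))
        probs, _ = model.forward(X)
        assert np.all((probs > 0) & (probs < 1))

    def test_same_seed_same_initial_parameters(self):
        a = build_lstm(timesteps=30, seed=5)
        b = build_lstm(timesteps=30, seed=5)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_parameter_count_closed_form(self):
        model = build_lstm(timesteps=60)
        H, F = 60, 3
        expected = (
            4 * H * (F + H) + 4 * H  # first layer
            + 4 * H * (H + H) + 4 * H  # second layer
            + H + 1  # dense head
        )
        assert model.n_params() == expected == 44461

    def test_invalid_timesteps_rejected(self):
        with pytest.raises(ValueError):
            build_lstm(timesteps=25)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        model = LSTMClassifier(timesteps=7, units=(5, 4), dropout=0.0, seed=1)
        X = rng.random((6, 7, 3))
        y = rng.integers(0, 2, 6).astype(float)
        probs, cache = model.forward(X)
        grads = model.backward(cache, (probs - y) / len(y))
        for key, numeric in numerical_grads(model, X, y, model.params).items():
            for idx, ng in numeric.items():
                assert grads[key].flat[idx] == pytest.approx(ng, abs=1e-6, rel=1e-3)

    def test_batch_size_invariance(self):
        model = build_lstm(timesteps=10, seed=2)
        X = np.random.default_rng(2).random((7, 10, 3))
        full = model.predict_proba(X)
        single = model.predict_proba(X, batch_size=1)
        np.testing.assert_allclose(full, single, atol=1e-12)
        np.testing.assert_allclose(model.predict_proba(X[[0, 0]])[0], full[0])


class TestDecayGRU:
    def _inputs(self, rng, B=5, T=8, D=3, missing=0.3):
        vals = rng.random((B, T, D))
        mask = (rng.random((B, T, D)) > missing).astype(float)
        delta = np.zeros((B, T, D))
        for t in range(1, T):
            delta[:, t] = np.where(mask[:, t - 1] > 0, 1.0, 1.0 + delta[:, t - 1])
        last = np.full((B, T, D), np.nan)
        current = np.full((B, D), np.nan)
        for t in range(T):
            current = np.where(mask[:, t] > 0, vals[:, t], current)
            last[:, t] = current
        return (vals * mask, mask, delta, last)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        model = GRUDClassifier(timesteps=8, units=5, dropout=0.0, seed=3)
        model.params["wgx"] += rng.normal(0, 0.5, 3)
        model.params["Wgh"] += rng.normal(0, 0.3, (3, 5))
        model.params["bgx"] += 0.1
        model.params["bgh"] += 0.05
        inputs = self._inputs(rng)
        y = rng.integers(0, 2, 5).astype(float)
        probs, cache = model.forward(inputs)
        grads = model.backward(cache, (probs - y) / len(y))
        for key, numeric in numerical_grads(model, inputs, y, model.params).items():
            for idx, ng in numeric.items():
                assert grads[key].flat[idx] == pytest.approx(ng, abs=1e-6, rel=1e-3)

    def test_zero_decay_full_observation_reduces_to_standard_gru(self):
        """With all-ones mask, zeroed decay and mask weights, the hidden
        trajectory equals an independently coded standard GRU's."""
        rng = np.random.default_rng(4)
        B, T, D, H = 4, 12, 3, 6
        model = GRUDClassifier(timesteps=T, n_features=D, units=H, seed=4)
        for key in ("wgx", "bgx", "Wgh", "bgh", "Wmr", "Wmz", "Wmh"):
            model.params[key] = np.zeros_like(model.params[key])
        X = rng.random((B, T, D))
        mask = np.ones((B, T, D))
        delta = np.ones((B, T, D))
        delta[:, 0] = 0.0
        traj = model.hidden_trajectory((X, mask, delta, X))

        p = model.params
        h = np.zeros((B, H))
        for t in range(T):
            x = X[:, t]
            r = sigmoid(x @ p["Wxr"] + h @ p["Whr"] + p["br"])
            z = sigmoid(x @ p["Wxz"] + h @ p["Whz"] + p["bz"])
            htil = np.tanh(x @ p["Wxh"] + (r * h) @ p["Whh"] + p["bh"])
            h = (1.0 - z) * h + z * htil
            np.testing.assert_allclose(traj[:, t], h, atol=1e-12)

    def test_input_decay_relaxes_toward_channel_mean(self):
        """A channel missing from step k onward drifts monotonically from
        its last observed value toward the channel mean."""
        T, H = 20, 4
        model = GRUDClassifier(timesteps=T, units=H, seed=5)
        model.params["wgx"] = np.array([0.5, 0.5, 0.5])
        model.set_feature_means(np.array([0.5, 0.5, 0.5]))
        mask = np.ones((1, T, 3))
        mask[0, 5:, 0] = 0.0
        delta = np.zeros((1, T, 3))
        for t in range(1, T):
            delta[0, t] = np.where(mask[0, t - 1] > 0, 1.0, 1.0 + delta[0, t - 1])
        vals = np.full((1, T, 3), 0.9) * mask
        last = np.full((1, T, 3), 0.9)
        _, cache = model.forward((vals, mask, delta, last))
        xhat0 = np.array([step[6][0, 0] for step in cache[0]])
        relaxing = xhat0[5:]
        assert np.all(np.diff(relaxing) < 0)  # decaying toward 0.5 from 0.9
        assert relaxing[-1] > 0.5

    def test_output_range_and_shape_checks(self):
        rng = np.random.default_rng(6)
        model = build_decay_gru(timesteps=10, seed=6)
        inputs = self._inputs(rng, B=3, T=10)
        probs, _ = model.forward(inputs)
        assert probs.shape == (3,) and np.all((probs > 0) & (probs < 1))
        bad = (inputs[0], inputs[1][:, :5], inputs[2], inputs[3])
        with pytest.raises(ValueError):
            model.forward(bad)


class TestFit:
    def test_learnable_toy_reaches_high_training_auroc(self):
        train = toy_dataset(n=80, seed=10)
        val = toy_dataset(n=40, seed=11)
        model = build_lstm(timesteps=10, seed=10)
        model, log = fit(model, train, val, TrainSpec(epochs=50, seed=10))
        assert auroc(predict_proba(model, train), train.y) > 0.95

    def test_loss_decreases_over_first_restart_period(self):
        train = toy_dataset(n=80, seed=12)
        val = toy_dataset(n=40, seed=13)
        model = build_lstm(timesteps=10, seed=12)
        _, log = fit(model, train, val, TrainSpec(epochs=10, seed=12))
        assert log.train_loss[-1] < log.train_loss[0]

    def test_shuffled_labels_give_chance_validation_auroc(self):
        aurocs = []
        for seed in range(5):
            train = toy_dataset(n=80, seed=20 + seed, signal=0.0)
            val = toy_dataset(n=60, seed=40 + seed, signal=0.0)
            model = build_lstm(timesteps=10, seed=seed)
            spec = TrainSpec(epochs=8, seed=seed, shuffle_labels=True)
            model, _ = fit(model, train, val, spec)
            aurocs.append(auroc(predict_proba(model, val), val.y))
        assert 0.4 <= float(np.mean(aurocs)) <= 0.6

    def test_same_seed_reproduces_validation_loss(self):
        train = toy_dataset(n=40, seed=30)
        val = toy_dataset(n=20, seed=31)
        logs = []
        for _ in range(2):
            model = build_lstm(timesteps=10, seed=7)
            _, log = fit(model, train, val, TrainSpec(epochs=5, seed=7))
            logs.append(log.val_loss)
        assert logs[0] == logs[1]

    def test_single_class_training_rejected(self):
        ds = toy_dataset(n=20, seed=1)
        ds.y[:] = 1
        with pytest.raises(ValueError):
            fit(build_lstm(timesteps=10), ds, ds, TrainSpec(epochs=1))

    def test_grud_fit_improves_on_toy(self):
        train = toy_dataset(n=80, seed=14)
        val = toy_dataset(n=40, seed=15)
        model = build_decay_gru(timesteps=10, seed=14)
        model, log = fit(model, train, val, TrainSpec(epochs=100, seed=14))
        assert auroc(predict_proba(model, train), train.y) > 0.9


class TestBaselines:
    def test_logreg_separable_and_sign(self):
        train = toy_dataset(n=100, seed=50, signal=0.4)
        test = toy_dataset(n=60, seed=51, signal=0.4)
        probs, clf = baseline_logreg(train, test)
        assert auroc(probs, test.y) > 0.95
        assert clf.coef_[0, 0] < 0  # lower mean MAP, higher episode risk

    def test_logreg_uninformative_feature_is_chance(self):
        train = toy_dataset(n=100, seed=52, signal=0.0)
        test = toy_dataset(n=100, seed=53, signal=0.0)
        probs, _ = baseline_logreg(train, test)
        assert abs(auroc(probs, test.y) - 0.5) < 0.15

    def test_svm_separable(self):
        train = toy_dataset(n=100, seed=54, signal=0.4)
        test = toy_dataset(n=60, seed=55, signal=0.4)
        scores, _ = baseline_svm(train, test)
        assert auroc(scores, test.y) > 0.95

    def test_single_class_rejected(self):
        ds = toy_dataset(n=20, seed=56)
        ds.y[:] = 0
        with pytest.raises(ValueError):
            baseline_logreg(ds, ds)
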