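import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metadecode import _mlp
from metadecode import (
    LabeledDataset,
    PlainDecoder,
    ReweightedDecoder,
    TrainerConfig,
    epsilon_weighted_loss,
    forward_predict,
    meta_gradient_step,
    rectify_and_normalize,
)
from conftest import make_toy_task


# --------------------------------------------------------------------------
# independent meta-gradient oracle: differentiates the validation loss
# through the explicit one-step update numerically, using only the forward
# pass — no backprop code is shared with the implementation under test


def _flatten(params):
    return np.concatenate([a.ravel() for W_b in params for a in W_b])


def _unflatten(vec, template):
    out, k = [], 0
    for W, b in template:
        w = vec[k : k + W.size].reshape(W.shape)
        k += W.size
        bb = vec[k : k + b.size]
        k += b.size
        out.append((w, bb))
    return out


def _loss_eps(theta_vec, template, x, y, eps):
    logits, _ = _mlp.forward(_unflatten(theta_vec, template), x)
    return float(eps @ _mlp.per_sample_ce(logits, y))


def _val_loss(theta_vec, template, xv, yv):
    logits, _ = _mlp.forward(_unflatten(theta_vec, template), xv)
    return float(_mlp.per_sample_ce(logits, yv).mean())


def mu_by_nested_finite_differences(
    params, xf, yf, xv, yv, alpha, h_eps=1e-4, h_theta=1e-6
):
    theta = _flatten(params)

    def theta_hat(eps):
        grad = np.empty_like(theta)
        for j in range(len(theta)):
            e = np.zeros_like(theta)
            e[j] = h_theta
            grad[j] = (
                _loss_eps(theta + e, params, xf, yf, eps)
                - _loss_eps(theta - e, params, xf, yf, eps)
            ) / (2 * h_theta)
        return theta - alpha * grad

    mu = np.empty(len(yf))
    for i in range(len(yf)):
        eps = np.zeros(len(yf))
        eps[i] = h_eps
        up = _val_loss(theta_hat(eps), params, xv, yv)
        eps[i] = -h_eps
        down = _val_loss(theta_hat(eps), params, xv, yv)
        mu[i] = -(up - down) / (2 * h_eps)
    return mu


class TestMetaGradient:
    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(42)
        cfg = TrainerConfig(inner_step_size=0.1, hidden_sizes=(3,))
        for _ in range(20):
            params = _mlp.init_params((2, 3, 2), rng)
            xf = rng.normal(size=(3, 2))
            yf = rng.integers(0, 2, 3)
            xv = rng.normal(size=(3, 2))
            yv = rng.integers(0, 2, 3)
            rec = meta_gradient_step(params, (xf, yf), (xv, yv), cfg)
            oracle = mu_by_nested_finite_differences(
                params, xf, yf, xv, yv, alpha=0.1
            )
            scale = max(np.abs(oracle).max(), 1e-3)
            assert np.allclose(rec.mu, oracle, rtol=1e-4, atol=1e-6 * scale)

    def test_zero_inner_step_gives_zero_mu(self):
        rng = np.random.default_rng(0)
        params = _mlp.init_params((2, 3, 2), rng)
        cfg = TrainerConfig(inner_step_size=0.0, hidden_sizes=(3,))
        rec = meta_gradient_step(
            params,
            (rng.normal(size=(3, 2)), rng.integers(0, 2, 3)),
            (rng.normal(size=(3, 2)), rng.integers(0, 2, 3)),
            cfg,
        )
        assert np.all(rec.mu == 0.0)

    def test_sample_matching_validation_batch_gets_top_positive_mu(self):
        rng = np.random.default_rng(7)
        params = _mlp.init_params((4, 5, 2), rng)
        cfg = TrainerConfig(inner_step_size=0.05, hidden_sizes=(5,))
        xf = rng.normal(size=(4, 4))
        yf = np.array([1, 0, 0, 1])
        xv = np.tile(xf[0], (3, 1))  # validation batch = copies of sample 0
        yv = np.array([1, 1, 1])
        rec = meta_gradient_step(params, (xf, yf), (xv, yv), cfg)
        assert rec.mu[0] > 0
        assert rec.mu[0] == rec.mu.max()

    def test_meta_rate_scaling_cancels_after_normalization(self):
        rng = np.random.default_rng(8)
        params = _mlp.init_params((2, 3, 2), rng)
        batches = (
            (rng.normal(size=(4, 2)), rng.integers(0, 2, 4)),
            (rng.normal(size=(4, 2)), rng.integers(0, 2, 4)),
        )
        a = meta_gradient_step(
            params, *batches, TrainerConfig(hidden_sizes=(3,), meta_rate=1.0)
        )
        b = meta_gradient_step(
            params, *batches, TrainerConfig(hidden_sizes=(3,), meta_rate=7.5)
        )
        assert np.allclose(b.mu, 7.5 * a.mu)
        assert np.allclose(a.normalized, b.normalized)


class TestForwardPredict:
    def test_zero_output_layer_ties_to_class_zero(self):
        params = [
            (np.eye(3), np.zeros(3)),
            (np.zeros((3, 2)), np.zeros(2)),
        ]
        scores, labels = forward_predict(params, np.random.default_rng(0).normal(size=(5, 3)))
        assert np.all(scores[:, 0] == scores[:, 1])
        assert np.all(labels == 0)

    def test_one_prediction_per_row(self):
        rng = np.random.default_rng(1)
        params = _mlp.init_params((4, 3, 2), rng)
        _, labels = forward_predict(params, rng.normal(size=(7, 4)))
        assert labels.shape == (7,)
        assert set(np.unique(labels)) <= {0, 1}

    def test_hand_computed_toy_forward_pass(self):
        W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        b1 = np.array([0.0, -1.0])
        W2 = np.array([[2.0, 0.0], [-1.0, 1.0]])
        b2 = np.array([0.5, -0.5])
        x = np.array([[1.0, 2.0]])
        # hidden: relu([1*1+2*0.5, 1*(-1)+2*2-1]) = relu([2, 2]) = [2, 2]
        # scores: [2*2-2*1+0.5, 2*0+2*1-0.5] = [2.5, 1.5]
        scores, labels = forward_predict([(W1, b1), (W2, b2)], x)
        assert np.allclose(scores, [[2.5, 1.5]])
        assert labels[0] == 0

    def test_width_mismatch_rejected(self):
        params = _mlp.init_params((4, 3, 2), np.random.default_rng(0))
        with pytest.raises(ValueError):
            forward_predict(params, np.zeros((2, 5)))


class TestEpsilonWeightedLoss:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.params = _mlp.init_params((3, 4, 2), rng)
        self.x = rng.normal(size=(4, 3))
        self.y = rng.integers(0, 2, 4)

    def test_zero_eps_gives_zero(self):
        assert epsilon_weighted_loss(self.params, self.x, self.y, np.zeros(4)) == 0.0

    def test_selector_eps_gives_single_sample_loss(self):
        eps = np.array([1.0, 0.0, 0.0, 0.0])
        logits, _ = _mlp.forward(self.params, self.x[:1])
        expected = float(_mlp.per_sample_ce(logits, self.y[:1])[0])
        assert epsilon_weighted_loss(self.params, self.x, self.y, eps) == pytest.approx(expected)

    def test_all_ones_equals_n_times_mean(self):
        # independent mean CE via explicit log-softmax arithmetic
        logits, _ = _mlp.forward(self.params, self.x)
        z = logits - logits.max(axis=1, keepdims=True)
        log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        mean_ce = -log_p[np.arange(4), self.y].mean()
        value = epsilon_weighted_loss(self.params, self.x, self.y, np.ones(4))
        assert value == pytest.approx(4 * mean_ce)


class TestRectifyAndNormalize:
    @pytest.mark.parametrize(
        "mu,expected",
        [
            ([1.0, 3.0], [0.25, 0.75]),
            ([-1.0, -2.0], [0.0, 0.0]),
            ([2.0, -1.0, 2.0], [0.5, 0.0, 0.5]),
        ],
    )
    def test_cases(self, mu, expected):
        assert np.allclose(rectify_and_normalize(np.array(mu)), expected)

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_positive_scaling_invariance(self, mu, c):
        mu = np.array(mu)
        assert np.allclose(
            rectify_and_normalize(mu), rectify_and_normalize(c * mu)
        )

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_sum_is_zero_or_one(self, mu):
        w = rectify_and_normalize(np.array(mu))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(0.0) or w.sum() == pytest.approx(1.0)


class TestReweightedTraining:
    def test_mislabeled_samples_down_weighted_across_seeds(self, small_trainer_config):
        for seed in range(5):
            train, val, _ = make_toy_task(flip_fraction=0.4, seed=seed)
            fit = ReweightedDecoder(train, val, small_trainer_config).fit(seed)
            w = fit.aggregate_weights
            mask = train.mislabel_mask
            assert w[mask].mean() < w[~mask].mean()

    def test_not_harmful_on_clean_data(self, small_trainer_config):
        from metadecode import f1_score, mix_datasets

        train, val, test = make_toy_task(flip_fraction=0.0, seed=3)
        bare = LabeledDataset(train.features, train.labels)
        rw = ReweightedDecoder(train, val, small_trainer_config).fit(3)
        plain = PlainDecoder(
            mix_datasets([bare, val]), small_trainer_config
        ).fit(3)
        f1_rw = f1_score(test.labels, rw.predict(test.features))
        f1_plain = f1_score(test.labels, plain.predict(test.features))
        assert f1_rw >= f1_plain - 0.05

    def test_zero_steps_returns_initialized_model(self):
        train, val, _ = make_toy_task(seed=0)
        cfg = TrainerConfig(hidden_sizes=(4,), max_steps=0, max_epochs=5)
        fit = ReweightedDecoder(train, val, cfg).fit(11)
        expected = _mlp.init_params((2, 4, 2), np.random.default_rng(11))
        for (W, b), (We, be) in zip(fit.params, expected):
            assert np.array_equal(W, We)
            assert np.array_equal(b, be)
        assert fit.weight_trace == [] and fit.n_steps_run == 0

    def test_weight_record_invariants_on_real_fit(self, small_trainer_config):
        train, val, _ = make_toy_task(seed=1)
        fit = ReweightedDecoder(train, val, small_trainer_config).fit(1)
        assert len(fit.weight_trace) > 0
        for rec in fit.weight_trace[:: max(1, len(fit.weight_trace) // 25)]:
            assert np.array_equal(rec.rectified, np.maximum(rec.mu, 0.0))
            assert np.all(rec.normalized >= 0)
            s = rec.normalized.sum()
            assert abs(s) < 1e-12 or s == pytest.approx(1.0)

    def test_batch_size_must_match_validation(self):
        train, val, _ = make_toy_task(seed=0)
        with pytest.raises(ValueError):
            ReweightedDecoder(train, val, TrainerConfig(batch_size=7))


class TestPlainTraining:
    def test_loss_decreases_on_clean_separable_data(self, small_trainer_config):
        train, _, _ = make_toy_task(flip_fraction=0.0, seed=5)
        fit = PlainDecoder(train, small_trainer_config).fit(5)
        curve = fit.train_loss_curve
        assert curve[-5:].mean() < curve[:5].mean()

    def test_merged_baseline_input_size(self):
        from metadecode import mix_datasets

        _, val, test = make_toy_task(n_val=20, n_test=60, seed=2)
        merged = mix_datasets([test, val])
        assert merged.n_samples == 80
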