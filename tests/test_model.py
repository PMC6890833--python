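import math

import numpy as np
import pytest

from diagnet.model import (
    HybridModelParams,
    TrainConfig,
    _gradients,
    classify_prob,
    decode,
    encode,
    fine_tune_slp,
    init_model,
    joint_loss,
    predict_label,
    train_joint,
)


def toy_params():
    """1-feature, 1-unit network with hand-set parameters."""
    return HybridModelParams(
        W_enc=np.array([[0.5]]),
        b_enc=np.array([0.1]),
        b_dec=np.array([0.2]),
        W_slp=np.array([0.3]),
        b_slp=-0.1,
    )


def separable_toy(rng, n=40, d=4):
    """Two Gaussian blobs separated along the first feature."""
    X0 = rng.normal(-1.0, 0.3, size=(n // 2, d))
    X1 = rng.normal(1.0, 0.3, size=(n // 2, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestInitModel:
    def test_seed_reproducibility(self):
        a, b = init_model(10, 5, seed=3), init_model(10, 5, seed=3)
        np.testing.assert_array_equal(a.W_enc, b.W_enc)
        np.testing.assert_array_equal(a.W_slp, b.W_slp)

    def test_default_bottleneck_halves_input(self):
        assert init_model(9950).bottleneck_dim == 4975

    def test_biases_start_at_zero(self):
        params = init_model(6, 3)
        assert np.all(params.b_enc == 0) and np.all(params.b_dec == 0)
        assert params.b_slp == 0.0

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            init_model(4, 5)
        with pytest.raises(ValueError):
            init_model(4, 0)


class TestForwardPass:
    def test_encode_closed_form(self):
        h = encode(toy_params(), np.array([0.5]))
        assert h[0] == pytest.approx(math.tanh(0.5 * 0.5 + 0.1))

    def test_encode_range_and_zero_case(self, rng):
        params = init_model(6, 3, seed=0)
        h = encode(params, rng.uniform(-5, 5, size=6))
        assert np.all((-1 < h) & (h < 1))
        zero = HybridModelParams(
            W_enc=np.zeros((3, 6)), b_enc=np.zeros(3), b_dec=np.zeros(6),
            W_slp=np.zeros(3), b_slp=0.0,
        )
        np.testing.assert_array_equal(encode(zero, np.ones(6)), 0.0)

    def test_decode_is_linear_with_tied_weight(self):
        params = HybridModelParams(
            W_enc=np.array([[2.0]]), b_enc=np.array([0.0]),
            b_dec=np.array([1.0]), W_slp=np.array([0.0]), b_slp=0.0,
        )
        assert decode(params, np.array([3.0]))[0] == pytest.approx(7.0)
        np.testing.assert_array_equal(decode(params, np.array([0.0])), [1.0])

    def test_decode_tracks_encoder_weight(self, rng):
        params = init_model(6, 3, seed=1)
        h = rng.uniform(-1, 1, size=3)
        before = decode(params, h)
        params.W_enc[0, 0] += 0.5  # decoder has no independent weight
        after = decode(params, h)
        assert not np.allclose(before, after)

    def test_classify_prob_zero_weights_give_half(self):
        params = HybridModelParams(
            W_enc=np.zeros((2, 4)), b_enc=np.zeros(2), b_dec=np.zeros(4),
            W_slp=np.zeros(2), b_slp=0.0,
        )
        assert classify_prob(params, np.ones(4)) == pytest.approx(0.5)

    def test_classify_prob_saturates_with_large_logit(self):
        params = toy_params()
        params.b_slp = 50.0
        assert classify_prob(params, np.array([0.5])) == pytest.approx(1.0)

    @pytest.mark.parametrize("prob_shift, expected", [(0.0, 1), (-0.1, 0), (3.0, 1)])
    def test_predict_label_threshold_boundary_is_positive(self, prob_shift, expected):
        params = HybridModelParams(
            W_enc=np.zeros((2, 4)), b_enc=np.zeros(2), b_dec=np.zeros(4),
            W_slp=np.zeros(2), b_slp=prob_shift,
        )
        # b_slp 0 -> probability exactly 0.5 -> patient class by convention
        assert predict_label(params, np.ones(4)) == expected


class TestJointLoss:
    def test_hand_computed_single_sample(self):
        params = toy_params()
        x, y = 0.7, 1.0
        h = math.tanh(0.5 * x + 0.1)
        mse = (0.5 * h + 0.2 - x) ** 2
        p = 1.0 / (1.0 + math.exp(-(0.3 * h - 0.1)))
        ce = -math.log(p)
        assert joint_loss(params, np.array([[x]]), np.array([y])) == pytest.approx(
            mse + ce, abs=1e-10
        )

    def test_ce_weight_zero_leaves_pure_mse(self):
        params = toy_params()
        x = np.array([[0.7]])
        h = math.tanh(0.45)
        mse = (0.5 * h + 0.2 - 0.7) ** 2
        assert joint_loss(params, x, np.array([1.0]), (1.0, 0.0)) == pytest.approx(mse)

    def test_perfect_fit_drives_loss_to_zero(self):
        # identity-ish reconstruction of 0 and a huge correct logit
        params = HybridModelParams(
            W_enc=np.array([[1.0]]), b_enc=np.array([0.0]),
            b_dec=np.array([0.0]), W_slp=np.array([0.0]), b_slp=100.0,
        )
        loss = joint_loss(params, np.array([[0.0]]), np.array([1.0]))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(toy_params(), np.empty((0, 1)), np.empty(0))


class TestGradients:
    def test_analytic_matches_central_finite_differences(self, rng):
        params = init_model(4, 2, seed=8)
        X = rng.uniform(-1, 1, size=(6, 4))
        y = rng.integers(0, 2, size=6).astype(float)
        weights = (1.0, 1.0)
        grads = _gradients(params, X, y, weights)
        eps = 1e-6

        def loss_of(p):
            return joint_loss(p, X, y, weights)

        for name in ("W_enc", "b_enc", "b_dec", "W_slp"):
            array = getattr(params, name)
            numeric = np.zeros_like(array)
            it = np.nditer(array, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                perturbed = params.copy()
                getattr(perturbed, name)[idx] += eps
                up = loss_of(perturbed)
                getattr(perturbed, name)[idx] -= 2 * eps
                down = loss_of(perturbed)
                numeric[idx] = (up - down) / (2 * eps)
            np.testing.assert_allclose(
                grads[name], numeric, rtol=1e-5, atol=1e-8
            )
        perturbed = params.copy()
        perturbed.b_slp += eps
        up = loss_of(perturbed)
        perturbed.b_slp -= 2 * eps
        down = loss_of(perturbed)
        assert grads["b_slp"] == pytest.approx((up - down) / (2 * eps), rel=1e-5)


class TestTraining:
    def test_loss_decreases_on_separable_toy(self, rng):
        X, y = separable_toy(rng)
        params = init_model(4, 2, seed=0)
        config = TrainConfig(joint_epochs=25, seed=0)
        trained, trajectory = train_joint(params, X, y, config)
        assert len(trajectory) == 26
        assert trajectory[-1] < trajectory[0]

    def test_trajectory_deterministic_from_seed(self, rng):
        X, y = separable_toy(rng)
        config = TrainConfig(joint_epochs=5, seed=4)
        _p1, t1 = train_joint(init_model(4, 2, seed=4), X, y, config)
        _p2, t2 = train_joint(init_model(4, 2, seed=4), X, y, config)
        assert t1 == t2

    def test_zero_learning_rate_is_a_no_op(self, rng):
        X, y = separable_toy(rng)
        params = init_model(4, 2, seed=0)
        config = TrainConfig(joint_epochs=3, learning_rate=0.0, seed=0)
        trained, trajectory = train_joint(params, X, y, config)
        np.testing.assert_array_equal(trained.W_enc, params.W_enc)
        assert len(set(trajectory)) == 1

    def test_finetune_freezes_encoder_bit_for_bit(self, rng):
        X, y = separable_toy(rng)
        config = TrainConfig(joint_epochs=5, finetune_epochs=5, seed=0)
        params, _t = train_joint(init_model(4, 2, seed=0), X, y, config)
        tuned = fine_tune_slp(params, X, y, config)
        assert tuned.W_enc.tobytes() == params.W_enc.tobytes()
        assert tuned.b_enc.tobytes() == params.b_enc.tobytes()
        assert tuned.b_dec.tobytes() == params.b_dec.tobytes()
        assert not np.array_equal(tuned.W_slp, params.W_slp)

    def test_finetune_does_not_increase_training_ce(self, rng):
        X, y = separable_toy(rng)
        config = TrainConfig(joint_epochs=10, finetune_epochs=5, seed=0)
        params, _t = train_joint(init_model(4, 2, seed=0), X, y, config)
        tuned = fine_tune_slp(params, X, y, config)
        ce_before = joint_loss(params, X, y, (0.0, 1.0))
        ce_after = joint_loss(tuned, X, y, (0.0, 1.0))
        assert ce_after <= ce_before + 1e-9

    def test_zero_finetune_epochs_is_identity(self, rng):
        X, y = separable_toy(rng)
        config = TrainConfig(joint_epochs=2, finetune_epochs=0, seed=0)
        params, _t = train_joint(init_model(4, 2, seed=0), X, y, config)
        tuned = fine_tune_slp(params, X, y, config)
        assert tuned.W_slp.tobytes() == params.W_slp.tobytes()

    def test_heldout_accuracy_on_separable_data(self, rng):
        X, y = separable_toy(rng, n=120)
        order = rng.permutation(120)
        train_idx, test_idx = order[:90], order[90:]
        params = init_model(4, 2, seed=1)
        config = TrainConfig(seed=1)
        params, _t = train_joint(params, X[train_idx], y[train_idx], config)
        params = fine_tune_slp(params, X[train_idx], y[train_idx], config)
        preds = predict_label(params, X[test_idx])
        assert np.mean(preds == y[test_idx]) >= 0.9

    def test_save_load_round_trip(self, tmp_path, rng):
        params = init_model(6, 3, seed=2)
        path = tmp_path / "model.npz"
        params.save(path)
        loaded = HybridModelParams.load(path)
        x = rng.uniform(-1, 1, size=6)
        assert classify_prob(loaded, x) == classify_prob(params, x)
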