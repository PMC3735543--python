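import math

import numpy as np
import pytest

from ervpredict import mlp_core as mc


def test_init_determinism_and_spread():
    a = mc.init_model(123)
    b = mc.init_model(123)
    np.testing.assert_array_equal(a.pack(), b.pack())
    c = mc.init_model(124)
    assert np.any(a.pack() != c.pack())
    assert a.pack().shape == (19,)
    assert np.all(np.abs(a.pack()) < 0.5)


def test_init_mean_near_zero_over_many_seeds():
    thetas = np.stack([mc.init_model(s).pack() for s in range(10_000)])
    # uniform(-0.5, 0.5): sd per parameter = 1/sqrt(12); SE of the mean over 10k draws
    se = (1 / math.sqrt(12)) / math.sqrt(10_000)
    assert np.all(np.abs(thetas.mean(axis=0)) < 3 * se)


def test_forward_zero_weights_is_half():
    model = mc.MlpModel.unpack(np.zeros(19))
    assert mc.forward(model, np.array([0.3, 0.9, 0.1, 0.7])) == pytest.approx(0.5)


def test_forward_manual_oracle():
    """Hand-specified parameters checked against an explicit scalar computation."""
    theta = np.array([
        0.2, -0.1, 0.4, 0.3,   # hidden neuron 1 weights
        -0.3, 0.5, 0.1, -0.2,  # hidden neuron 2
        0.05, 0.05, -0.5, 0.6, # hidden neuron 3
        0.1, -0.2, 0.3,        # hidden biases
        0.7, -0.4, 0.25,       # output weights
        -0.15,                 # output bias
    ])
    x = np.array([1.0, 0.0, 0.8, 0.5744])
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    h = [
        sig(0.2 * 1 + -0.1 * 0 + 0.4 * 0.8 + 0.3 * 0.5744 + 0.1),
        sig(-0.3 * 1 + 0.5 * 0 + 0.1 * 0.8 + -0.2 * 0.5744 + -0.2),
        sig(0.05 * 1 + 0.05 * 0 + -0.5 * 0.8 + 0.6 * 0.5744 + 0.3),
    ]
    expected = sig(0.7 * h[0] + -0.4 * h[1] + 0.25 * h[2] + -0.15)
    assert mc.forward(mc.MlpModel.unpack(theta), x) == pytest.approx(expected, abs=1e-12)


def test_forward_monotone_in_output_weight():
    model = mc.init_model(5)
    x = np.array([0.5, 0.5, 0.5, 0.5])
    y0 = mc.forward(model, x)
    bumped = mc.MlpModel.unpack(model.pack() + np.eye(19)[15] * 0.1)  # hidden activations are positive
    assert mc.forward(bumped, x) > y0


def test_gradient_matches_finite_differences(rng):
    for trial in range(5):
        model = mc.init_model(trial)
        X = rng.random((6, 4))
        t = rng.integers(0, 2, 6).astype(float)
        g = mc.gradient(model, (X, t))
        theta = model.pack()
        fd = np.empty(19)
        for i in range(19):
            e = np.zeros(19)
            e[i] = 1e-6
            fd[i] = (mc.loss(mc.MlpModel.unpack(theta + e), (X, t)) -
                     mc.loss(mc.MlpModel.unpack(theta - e), (X, t))) / 2e-6
        np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-9)


def test_gradient_zero_at_fit():
    """Residual identity: when every output equals its target the gradient vanishes."""
    model = mc.init_model(3)
    X = np.array([[0.2, 0.4, 0.6, 0.8]])
    y = mc.forward(model, X[0])
    g = mc.gradient(model, (X, np.array([y])))
    np.testing.assert_allclose(g, 0.0, atol=1e-12)


def test_gradient_symmetry_zero_weights():
    """Zero weights + symmetric targets: the output-bias gradient cancels."""
    model = mc.MlpModel.unpack(np.zeros(19))
    X = np.array([[0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4]])
    g = mc.gradient(model, (X, np.array([0.0, 1.0])))
    assert g[18] == pytest.approx(0.0, abs=1e-15)


def test_train_separable_toy():
    X = np.array([[0, 0, 0.1, 0.1], [0, 1, 0.2, 0.1], [1, 0, 0.9, 0.8], [1, 1, 0.8, 0.9]], dtype=float)
    t = np.array([0, 0, 1, 1], dtype=float)
    res = mc.train(mc.init_model(11), (X, t), mc.TrainConfig(seed=11))
    assert res.converged
    preds = mc.forward(res.model, X)
    assert np.array_equal(preds >= 0.5, t.astype(bool))


def test_train_all_negative_targets():
    X = np.array([[0.1, 0.9, 0.3, 0.7], [0.5, 0.2, 0.8, 0.1], [0.9, 0.9, 0.9, 0.9]])
    t = np.zeros(3)
    res = mc.train(mc.init_model(2), (X, t), mc.TrainConfig(seed=2))
    assert np.all(mc.forward(res.model, X) < 0.1)


def test_gd_loss_monotone_on_fixture():
    """Plain gradient descent with a small step: loss never increases."""
    rng = np.random.default_rng(0)
    X = rng.random((10, 4))
    t = rng.integers(0, 2, 10).astype(float)
    model = mc.init_model(0)
    cfg = mc.TrainConfig(learning_rate=0.01, algorithm="gd", max_epochs=1, stop_threshold=1e-12)
    losses = [mc.loss(model, (X, t))]
    for _ in range(300):
        model = mc.train(model, (X, t), cfg).model
        losses.append(mc.loss(model, (X, t)))
    diffs = np.diff(losses)
    assert np.all(diffs <= 1e-12)


def test_training_deterministic():
    X = np.random.default_rng(1).random((8, 4))
    t = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    cfg = mc.TrainConfig(seed=9, max_epochs=500)
    a = mc.train(mc.init_model(9), (X, t), cfg)
    b = mc.train(mc.init_model(9), (X, t), cfg)
    np.testing.assert_array_equal(a.model.pack(), b.model.pack())
    assert a.final_error == b.final_error


def test_hidden_unit_relabeling_invariance():
    """Permuting hidden units together with their weights leaves outputs unchanged."""
    model = mc.init_model(21)
    perm = [2, 0, 1]
    permuted = mc.MlpModel(
        hidden_weights=model.hidden_weights[perm],
        hidden_bias=model.hidden_bias[perm],
        output_weights=model.output_weights[perm],
        output_bias=model.output_bias,
    )
    X = np.random.default_rng(3).random((20, 4))
    np.testing.assert_allclose(mc.forward(model, X), mc.forward(permuted, X), rtol=1e-12)


def test_stacked_training_equals_individual():
    X = np.random.default_rng(4).random((12, 4))
    t = np.tile([0.0, 1.0], 6)
    cfg = mc.TrainConfig(max_epochs=800)
    stack = mc.init_stack([41, 42, 43])
    trained, _, _, _ = mc.train_stack(stack, X, t, cfg)
    for r, seed in enumerate([41, 42, 43]):
        solo = mc.train(mc.init_model(seed), (X, t), cfg)
        np.testing.assert_array_equal(mc.stack_member(trained, r).pack(), solo.model.pack())


def test_nonfinite_targets_rejected():
    X = np.random.default_rng(5).random((4, 4))
    t = np.array([0.0, 1.0, np.nan, 0.0])
    with pytest.raises(ValueError, match="target"):
        mc.train(mc.init_model(1), (X, t), mc.TrainConfig())
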