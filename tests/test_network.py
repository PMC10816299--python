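"""Residual network construction, backprop correctness, training contracts."""

import numpy as np
import pytest

from hepasafe import (
    LossConfig,
    NetworkConfig,
    RegressorSpec,
    TrainConfig,
    build_network,
    forward,
    load_checkpoint,
    make_baseline,
    save_checkpoint,
    train,
)
from hepasafe.baselines import ResectionNetRegressor
from hepasafe.network import TrainingDivergedError

SMALL = NetworkConfig(input_dim=5, hidden=8, expand=16, shrink4=6, shrink5=4,
                      dropout=0.0, seed=42)


def toy_linear_data(n=64, d=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = X @ w * 10 + 100 + noise * rng.normal(size=n)
    return X, y


def test_default_network_outputs_scalar():
    net = build_network()
    x = np.random.default_rng(0).normal(size=23)
    out = forward(net, x)
    assert isinstance(out, float) and np.isfinite(out)


def test_same_seed_gives_identical_parameters():
    p1 = build_network(SMALL).params()
    p2 = build_network(SMALL).params()
    for (a, _), (b, _) in zip(p1, p2):
        assert np.array_equal(a, b)
    p3 = build_network(NetworkConfig(**{**SMALL.__dict__, "seed": 43})).params()
    assert any(not np.array_equal(a, b) for (a, _), (b, _) in zip(p1, p3))


def test_parameter_count_is_deterministic_function_of_widths():
    def expected(cfg):
        def affine(i, o):
            return i * o + o

        def res(d):
            return 2 * affine(d, d)

        return (
            affine(cfg.input_dim, cfg.hidden) + res(cfg.hidden)
            + affine(cfg.hidden, cfg.expand) + res(cfg.expand)
            + affine(cfg.expand, cfg.hidden) + res(cfg.hidden)
            + affine(cfg.hidden, cfg.shrink4) + res(cfg.shrink4)
            + affine(cfg.shrink4, cfg.shrink5) + affine(cfg.shrink5, 1)
        )

    for cfg in (SMALL, NetworkConfig()):
        assert build_network(cfg).n_parameters() == expected(cfg)


def test_zeroed_parameters_collapse_to_final_bias():
    net = build_network(SMALL)
    for p, _ in net.params():
        p[...] = 0.0
    net.layers[-1].b[...] = 7.5
    X = np.random.default_rng(1).normal(size=(10, 5))
    assert np.allclose(net.predict(X), 7.5)


def test_forward_deterministic_and_batch_consistent():
    net = build_network(SMALL)
    X = np.random.default_rng(2).normal(size=(6, 5))
    batch = net.predict(X)
    assert np.array_equal(batch, net.predict(X))
    singles = [forward(net, x) for x in X]
    assert np.allclose(batch, singles)


def test_forward_dimension_mismatch():
    net = build_network(SMALL)
    with pytest.raises(ValueError, match="features"):
        net.predict(np.zeros((3, 7)))


def test_network_backprop_matches_finite_differences():
    # end-to-end gradient of a scalar loss through every layer type
    net = build_network(SMALL)
    X = np.random.default_rng(3).normal(size=(7, 5))
    y = np.random.default_rng(4).normal(size=7)

    def loss_value():
        pred = net._forward_std(X)
        return 0.5 * float(((pred - y) ** 2).sum())

    pred = net._forward_std(X)
    net._backward(pred - y)
    grads = [(p, g.copy()) for p, g in net.params()]
    eps = 1e-6
    rng = np.random.default_rng(5)
    for p, g in grads:
        flat = p.reshape(-1)
        for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_value()
            flat[idx] = orig - eps
            down = loss_value()
            flat[idx] = orig
            num = (up - down) / (2 * eps)
            assert g.reshape(-1)[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)


def test_epochs_zero_returns_network_unchanged():
    net = build_network(SMALL)
    before = [p.copy() for p, _ in net.params()]
    _, history = train(net, *toy_linear_data(), TrainConfig(epochs=0))
    assert history == []
    for p_before, (p_after, _) in zip(before, net.params()):
        assert np.array_equal(p_before, p_after)


def test_training_reduces_loss_and_is_seed_deterministic():
    X, y = toy_linear_data(noise=1.0)
    cfg = TrainConfig(epochs=200, loss="mse", seed=9)
    _, h1 = train(build_network(SMALL), X, y, cfg)
    _, h2 = train(build_network(SMALL), X, y, cfg)
    assert h1 == h2
    assert h1[-1] < h1[0]


def test_convergence_on_noiseless_linear_data():
    X, y = toy_linear_data(noise=0.0)
    cfg = TrainConfig(epochs=1500, loss="mse", weight_decay=0.0, seed=1)
    _, history = train(build_network(SMALL), X, y, cfg)
    assert history[-1] < 0.01 * history[0]


def test_training_is_invariant_to_sample_permutation():
    X, y = toy_linear_data(n=40, noise=0.5)
    perm = np.random.default_rng(8).permutation(len(y))
    cfg = TrainConfig(epochs=50, seed=3)
    net_a, _ = train(build_network(SMALL), X, y, cfg)
    cfg_b = TrainConfig(epochs=50, seed=3)
    net_b, _ = train(build_network(SMALL), X[perm], y[perm], cfg_b)
    for (pa, _), (pb, _) in zip(net_a.params(), net_b.params()):
        assert np.allclose(pa, pb, atol=1e-10)


def test_standardization_changes_little_on_well_conditioned_data():
    X, y = toy_linear_data(n=80, noise=0.0)
    cfg_on = TrainConfig(epochs=1500, loss="mse", weight_decay=0.0,
                         standardize_inputs=True, seed=2)
    cfg_off = TrainConfig(epochs=1500, loss="mse", weight_decay=0.0,
                          standardize_inputs=False, seed=2)
    net_on, _ = train(build_network(SMALL), X, y, cfg_on)
    net_off, _ = train(build_network(SMALL), X, y, cfg_off)
    spread = y.std()
    rmse = np.sqrt(np.mean((net_on.predict(X) - net_off.predict(X)) ** 2))
    assert rmse < 0.15 * spread


def test_divergence_raises_with_epoch():
    X, y = toy_linear_data()
    cfg = TrainConfig(epochs=50, learning_rate=1e12, loss="mse")
    with pytest.raises((TrainingDivergedError, FloatingPointError, ValueError)):
        with np.errstate(over="ignore", invalid="ignore"):
            train(build_network(SMALL), X, y, cfg)


def test_checkpoint_roundtrip(tmp_path):
    X, y = toy_linear_data()
    net, _ = train(build_network(SMALL), X, y, TrainConfig(epochs=20))
    path = tmp_path / "ckpt.json"
    save_checkpoint(net, path)
    back = load_checkpoint(path)
    assert np.allclose(net.predict(X), back.predict(X))


# -- baseline registry -------------------------------------------------------

def test_linear_baseline_recovers_line():
    X = np.linspace(0, 10, 50).reshape(-1, 1)
    y = 2 * X[:, 0] + 1
    model = make_baseline(RegressorSpec("linear"))
    model.fit(X, y)
    assert model.coef_[0] == pytest.approx(2.0)
    assert model.intercept_ == pytest.approx(1.0)


def test_poly2_fits_quadratic():
    X = np.linspace(-3, 3, 60).reshape(-1, 1)
    y = 0.5 * X[:, 0] ** 2 - X[:, 0] + 4
    model = make_baseline(RegressorSpec("poly2"))
    model.fit(X, y)
    assert np.max(np.abs(model.predict(X) - y)) < 1e-8


def test_decision_tree_overfits_training_set():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 4))
    y = rng.normal(size=50)
    model = make_baseline(RegressorSpec("decision_tree"))
    model.fit(X, y)
    assert np.mean((model.predict(X) - y) ** 2) < 1e-12


def test_unknown_model_name_lists_valid_names():
    with pytest.raises(ValueError, match="linear"):
        RegressorSpec("not_a_model")


def test_resection_net_regressor_fit_predict(cohort52):
    from hepasafe.cohort import cohort_to_arrays

    X, y = cohort_to_arrays(cohort52.records)
    model = ResectionNetRegressor(loss="weighted_liver", seed=0)
    model.fit(X, y)
    preds = model.predict(X)
    assert preds.shape == y.shape
    assert np.all(np.isfinite(preds))
    assert model.history_[-1] < model.history_[0]
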