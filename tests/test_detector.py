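"""Combined loss, network contracts, training and prediction
post-processing."""

from dataclasses import replace

import numpy as np
import pytest

from noisematch import nn
from noisematch.detector import (
    LesionDetector,
    LossConfig,
    NetworkConfig,
    TrainConfig,
    build_network,
    combined_loss,
    combined_loss_grad,
    load_checkpoint,
    postprocess_logits,
    save_checkpoint,
    train,
)


def _loss_oracle(z, g, bce_w=1.0, dice_w=1.0, eps=1.0):
    """Element-wise reimplementation of the combined loss."""
    z = np.asarray(z, float)
    g = np.asarray(g, float)
    p = 1.0 / (1.0 + np.exp(-z))
    bce = float(np.mean(-g * np.log(p) - (1 - g) * np.log1p(-p)))
    dice = 1.0 - (2 * (p * g).sum() + eps) / (p.sum() + g.sum() + eps)
    return bce_w * bce + dice_w * dice


def test_loss_perfect_prediction_limit():
    g = np.zeros((6, 6))
    g[2:4, 2:4] = 1
    z = np.where(g > 0, 80.0, -80.0)
    assert combined_loss(z, g) == pytest.approx(0.0, abs=1e-10)


def test_loss_empty_gold_confident_negative():
    g = np.zeros((6, 6))
    z = np.full((6, 6), -80.0)
    assert combined_loss(z, g, LossConfig(smooth_eps=1.0)) == pytest.approx(
        0.0, abs=1e-10
    )


def test_loss_matches_oracle(rng):
    for _ in range(10):
        z = rng.standard_normal((8, 8)) * 3
        g = (rng.uniform(size=(8, 8)) > 0.7).astype(float)
        assert combined_loss(z, g) == pytest.approx(_loss_oracle(z, g), abs=1e-6)
        w = LossConfig(bce_weight=0.3, dice_weight=2.0, smooth_eps=0.5)
        assert combined_loss(z, g, w) == pytest.approx(
            _loss_oracle(z, g, 0.3, 2.0, 0.5), abs=1e-6
        )


def test_loss_gradient_matches_finite_differences(rng):
    z = rng.standard_normal((5, 5))
    g = (rng.uniform(size=(5, 5)) > 0.6).astype(float)
    _, grad = combined_loss_grad(z, g)
    eps = 1e-4
    for _ in range(6):
        idx = tuple(rng.integers(0, 5, size=2))
        zp, zm = z.copy(), z.copy()
        zp[idx] += eps
        zm[idx] -= eps
        num = (combined_loss(zp, g) - combined_loss(zm, g)) / (2 * eps)
        assert grad[idx] == pytest.approx(num, abs=1e-5)


def test_loss_nonnegative_and_shape_mismatch(rng):
    z = rng.standard_normal((4, 4))
    g = np.zeros((4, 4))
    assert combined_loss(z, g) >= 0
    with pytest.raises(ValueError):
        combined_loss(z, np.zeros((3, 3)))


def test_dice_term_permutation_invariant(rng):
    z = rng.standard_normal(64)
    g = (rng.uniform(size=64) > 0.5).astype(float)
    perm = rng.permutation(64)
    cfg = LossConfig(bce_weight=0.0, dice_weight=1.0)
    assert combined_loss(z.reshape(8, 8), g.reshape(8, 8), cfg) == pytest.approx(
        combined_loss(z[perm].reshape(8, 8), g[perm].reshape(8, 8), cfg)
    )


# -- network contracts -----------------------------------------------------


def test_network_forward_shape_and_finiteness():
    net = build_network(NetworkConfig(base_channels=4), seed=0)
    x = np.zeros((2, 16, 16), dtype=np.float32)
    y = net.forward(x)
    assert y.shape == (2, 16, 16)
    assert np.all(np.isfinite(y))


def test_network_build_deterministic():
    a = build_network(NetworkConfig(base_channels=4), seed=3)
    b = build_network(NetworkConfig(base_channels=4), seed=3)
    pa, pb = a.params(), b.params()
    assert len(pa) == len(pb)
    for x, y in zip(pa, pb):
        np.testing.assert_array_equal(x.value, y.value)


def test_network_rejects_indivisible_grid():
    net = build_network(NetworkConfig(base_channels=4), seed=0)
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 15, 15), dtype=np.float32))


def test_network_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(n_down_blocks=4, n_up_blocks=3)
    with pytest.raises(ValueError):
        NetworkConfig(n_down_blocks=3, n_transposed_layers=2)


def test_network_gradient_nonzero(rng):
    net = build_network(NetworkConfig(base_channels=4), seed=1)
    x = rng.standard_normal((2, 8, 8)).astype(np.float32)
    g = (rng.uniform(size=(2, 8, 8)) > 0.8).astype(np.float32)
    logits = net.forward(x)
    _, dlog = combined_loss_grad(logits, g)
    params = net.params()
    for p in params:
        p.grad[...] = 0
    net.backward(dlog)
    total = sum(float(np.abs(p.grad).sum()) for p in params)
    assert np.isfinite(total) and total > 0


# -- prediction post-processing -------------------------------------------


def test_postprocess_all_negative_logits():
    assert postprocess_logits(np.full((32, 32), -5.0)).n_components == 0


def test_postprocess_filter_boundary():
    """Components of 19 and 21 pixels at the fixed 20-pixel filter:
    only the 21-pixel one survives."""
    logits = np.full((32, 32), -1.0)
    logits[2:6, 2:7] = 1.0
    logits[4, 4] = -1.0  # 19 pixels
    logits[20:23, 20:27] = 1.0  # 21 pixels
    mask = postprocess_logits(logits)
    assert mask.n_components == 1
    assert np.count_nonzero(np.asarray(mask.labels)) == 21


def test_postprocess_binarizes_at_zero():
    logits = np.full((16, 16), -0.01)
    logits[2:7, 2:7] = 0.01  # 25 pixels, just above 0
    assert postprocess_logits(logits).n_components == 1
    assert postprocess_logits(logits - 0.02).n_components == 0


def test_postprocess_survivors_at_least_20(rng):
    for _ in range(100):
        logits = rng.standard_normal((48, 48))
        mask = postprocess_logits(logits)
        labels = np.asarray(mask.labels)
        for k in range(1, mask.n_components + 1):
            assert np.count_nonzero(labels == k) >= 20


# -- training --------------------------------------------------------------


def _easy_dataset(n=14, seed=100):
    """High-contrast blobs on a flat background: trivially learnable."""
    rng = np.random.default_rng(seed)
    X, Y = [], []
    for _ in range(n):
        img = rng.normal(5.0, 0.3, size=(32, 32)).astype(np.float32)
        mask = np.zeros((32, 32), bool)
        for _ in range(2):
            i, j = rng.integers(4, 24, size=2)
            img[i : i + 6, j : j + 6] = 25.0
            mask[i : i + 6, j : j + 6] = True
        X.append(np.clip(img, 0, None))
        Y.append(mask)
    return np.stack(X), np.stack(Y)


@pytest.fixture(scope="module")
def toy_fit():
    X, Y = _easy_dataset()
    det = LesionDetector(
        network=NetworkConfig(base_channels=8),
        train=TrainConfig(seed=0, max_epochs=50),
    )
    det.fit(X[:10], Y[:10], X_val=X[10:], y_val=Y[10:])
    return det, X, Y


def test_training_reaches_high_f1_on_easy_data(toy_fit):
    det, _, _ = toy_fit
    assert det.best_val_f1_ >= 0.8


def test_training_history_recorded(toy_fit):
    det, _, _ = toy_fit
    assert len(det.history_) == det.n_epochs_
    assert det.history_.train_loss.iloc[-1] < det.history_.train_loss.iloc[0]


def test_zero_epoch_budget_returns_initialization():
    X, Y = _easy_dataset(n=2)
    cfg = TrainConfig(seed=5, max_epochs=0)
    det = train({"train": (X, Y)}, NetworkConfig(base_channels=4), cfg)
    init = build_network(NetworkConfig(base_channels=4), seed=5)
    for p, q in zip(det.net_.params(), init.params()):
        np.testing.assert_array_equal(p.value, q.value)


def test_training_deterministic_same_seed():
    X, Y = _easy_dataset(n=6)
    kw = dict(
        network=NetworkConfig(base_channels=4),
        train=TrainConfig(seed=9, max_epochs=2),
    )
    d1 = LesionDetector(**kw).fit(X, Y)
    d2 = LesionDetector(**kw).fit(X, Y)
    for p, q in zip(d1.net_.params(), d2.net_.params()):
        np.testing.assert_array_equal(p.value, q.value)


def test_predict_invariant_to_gold_relabeling():
    """Training sees binary masks, so permuting gold component IDs
    cannot change the fitted detector."""
    X, Y = _easy_dataset(n=6)
    labels = []
    from skimage.measure import label as cc

    for y in Y:
        labels.append(cc(y, connectivity=2))
    relabeled = []
    for lab in labels:
        out = np.zeros_like(lab)
        n = lab.max()
        for k in range(1, n + 1):
            out[lab == k] = n + 1 - k
        relabeled.append(out)
    kw = dict(
        network=NetworkConfig(base_channels=4),
        train=TrainConfig(seed=2, max_epochs=2),
    )
    d1 = LesionDetector(**kw).fit(X, [l > 0 for l in labels])
    d2 = LesionDetector(**kw).fit(X, [l > 0 for l in relabeled])
    for p, q in zip(d1.net_.params(), d2.net_.params()):
        np.testing.assert_array_equal(p.value, q.value)


def test_train_requires_nonempty_dataset():
    with pytest.raises(ValueError):
        train({"train": (np.zeros((0, 8, 8)), np.zeros((0, 8, 8)))})


def test_checkpoint_round_trip(tmp_path, toy_fit):
    det, X, _ = toy_fit
    path = tmp_path / "model.npz"
    save_checkpoint(det, path)
    loaded = load_checkpoint(path)
    np.testing.assert_allclose(
        det.decision_function(X[:2]), loaded.decision_function(X[:2])
    )
    assert loaded.network == det.network


def test_sklearn_get_set_params():
    det = LesionDetector()
    params = det.get_params()
    assert "network" in params and "train" in params
    det2 = det.set_params(train=replace(det.train, seed=42))
    assert det2.train.seed == 42
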