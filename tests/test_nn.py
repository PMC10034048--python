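"""SE-Unet engine: contracts, hand-computed oracles, gradients, training."""

import math

import numpy as np
import pytest

from trihinge.errors import ConfigError, DimensionError
from trihinge.features import FeatureConfig, pad_and_block
from trihinge.nn import SEBlock, SEUnet, dice_loss, dice_loss_and_grad
from trihinge.nn.optim import exponential_lr
from trihinge.segmentation import ModelConfig, SEUnetSegmenter, build_model, predict_regions


def tiny_net(variant="se_unet", n_features=1, dropout=0.0, seed=0):
    return SEUnet(in_channels=3, depth=3, base_channels=4, se_reduction=4,
                  dropout=dropout, variant=variant, n_features=n_features, seed=seed)


# ---------------------------------------------------------------------------
# shape / softmax contracts
# ---------------------------------------------------------------------------

def test_output_shape_and_softmax_normalization(rng):
    net = SEUnet(in_channels=16, depth=5, base_channels=4, se_reduction=4, seed=0)
    x = rng.normal(size=(2, 16, 64, 64)).astype(np.float32)
    p = net.forward(x, training=False)
    assert p.shape == (2, 2, 64, 64)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert p.min() >= 0


def test_se_unet_parameter_count_audit():
    """SE cost = sum over SE blocks of 2*C*floor(C/r) + C + floor(C/r)."""
    depth, base, r = 4, 8, 4
    plain = SEUnet(in_channels=16, depth=depth, base_channels=base, variant="unet", seed=0)
    se = SEUnet(in_channels=16, depth=depth, base_channels=base, se_reduction=r,
                variant="se_unet", seed=0)
    ch = [base * 2**i for i in range(depth)]
    se_channels = ch[: depth - 1] + [ch[depth - 1]] + ch[depth - 2 :: -1]
    expected_extra = sum(2 * c * (c // r) + c + (c // r) for c in se_channels)
    assert se.n_parameters() - plain.n_parameters() == expected_extra


def test_fusion_with_one_stem_reduces_to_single_feature_plus_stem():
    single = tiny_net("se_unet")
    fused = tiny_net("se_unet_fusion", n_features=1)
    # stem: 3x3 conv 3->3 (+bias) and BN gamma/beta
    stem_params = 3 * 3 * 3 * 3 + 3 + 2 * 3
    assert fused.n_parameters() - single.n_parameters() == stem_params


def test_invalid_reduction_rejected():
    with pytest.raises(ConfigError):
        SEUnet(in_channels=16, depth=3, base_channels=8, se_reduction=16, seed=0)
    with pytest.raises(ConfigError):
        ModelConfig(base_channels=8, se_reduction=16).validate()


# ---------------------------------------------------------------------------
# SE block
# ---------------------------------------------------------------------------

def test_se_zero_input_gives_zero_output(rng):
    se = SEBlock(8, 4, rng)
    out = se.forward(np.zeros((2, 8, 5, 5), dtype=np.float32), training=False)
    assert np.all(out == 0)


def test_se_zero_weights_halve_input(rng):
    se = SEBlock(8, 4, rng)
    for p in (se.W1, se.W2, se.b1, se.b2):
        p.value[...] = 0
    x = rng.normal(size=(3, 8, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(se.forward(x, training=False), x / 2, atol=1e-6)


def test_se_hand_computed_toy(rng):
    """1x1 spatial, 2 channels, hand-set weights; expectation via arithmetic."""
    se = SEBlock(2, 1, rng)
    se.W1.value = np.array([[1.0, 0.0], [-1.0, 0.5]], dtype=np.float32)  # C -> C//r = 2
    se.b1.value = np.array([0.5, 0.0], dtype=np.float32)
    se.W2.value = np.array([[2.0, -1.0], [0.0, 1.0]], dtype=np.float32)
    se.b2.value = np.array([0.0, 0.25], dtype=np.float32)
    x = np.array([[[[1.0]], [[2.0]]]], dtype=np.float32)  # squeeze -> [1, 2]
    # z1 = [1*1 + 2*(-1) + 0.5, 1*0 + 2*0.5 + 0] = [-0.5, 1.0]; relu -> [0, 1]
    # z2 = [0*2 + 1*0 + 0, 0*(-1) + 1*1 + 0.25] = [0, 1.25]
    s = [1 / (1 + math.exp(0.0)), 1 / (1 + math.exp(-1.25))]
    expected = np.array([[[[1.0 * s[0]]], [[2.0 * s[1]]]]])
    np.testing.assert_allclose(se.forward(x, training=False), expected, rtol=1e-6)


def test_se_gates_in_unit_interval_and_shape_preserved(rng):
    se = SEBlock(6, 2, rng)
    x = rng.normal(size=(4, 6, 8, 8)).astype(np.float32) * 3
    y = se.forward(x, training=False)
    assert y.shape == x.shape
    nonzero = np.abs(x) > 1e-6
    ratio = np.abs(y[nonzero] / x[nonzero])
    assert ratio.min() > 0 and ratio.max() < 1


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def test_dice_perfect_and_disjoint():
    t = np.zeros((8, 8)); t[:4] = 1
    assert dice_loss(t, t) <= 1.0 / (2 * t.sum() + 1.0)
    disjoint = 1 - t
    # with eps = 1 smoothing: 1 - eps / (sum p + sum t + eps)
    assert dice_loss(disjoint, t) == pytest.approx(1.0 - 1.0 / (64 + 1), abs=1e-9)


def test_dice_half_overlap_eps_zero():
    pred = np.array([1.0, 1.0, 0.0, 0.0])
    target = np.array([1.0, 0.0, 1.0, 0.0])
    assert dice_loss(pred, target, eps=0.0) == pytest.approx(0.5)


def test_dice_range_and_binary_symmetry(rng):
    for _ in range(20):
        p = (rng.random(50) > 0.5).astype(float)
        t = (rng.random(50) > 0.5).astype(float)
        l1, l2 = dice_loss(p, t), dice_loss(t, p)
        assert 0.0 <= l1 <= 1.0
        assert l1 == pytest.approx(l2)


def test_dice_mask_excludes_padding():
    pred = np.array([1.0, 1.0, 1.0, 1.0])
    target = np.array([1.0, 1.0, 0.0, 0.0])
    mask = np.array([1.0, 1.0, 0.0, 0.0])
    assert dice_loss(pred, target, mask, eps=0.0) == pytest.approx(0.0)


def test_dice_shape_mismatch():
    with pytest.raises(DimensionError):
        dice_loss(np.zeros(3), np.zeros(4))


def test_dice_gradient_matches_finite_differences(rng):
    p = rng.random(30)
    t = (rng.random(30) > 0.5).astype(float)
    _, g = dice_loss_and_grad(p, t)
    for idx in (0, 11, 29):
        eps = 1e-6
        pp, pm = p.copy(), p.copy()
        pp[idx] += eps; pm[idx] -= eps
        num = (dice_loss(pp, t) - dice_loss(pm, t)) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# gradients through the full network
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant,m", [("se_unet", 1), ("unet", 1), ("se_unet_fusion", 2)])
def test_weight_gradients_match_finite_differences(variant, m):
    rng = np.random.default_rng(0)
    net = tiny_net(variant, n_features=m)
    x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
    xin = [x, rng.normal(size=(2, 3, 8, 8)).astype(np.float32)][:m]
    xin = xin if variant == "se_unet_fusion" else xin[0]
    y = (rng.random((2, 8, 8)) > 0.6).astype(np.float32)

    def loss():
        p = net.forward(xin, training=True)
        return dice_loss_and_grad(p[:, 1].astype(np.float64), y)

    _, g = loss()
    net.zero_grad()
    net.backward(g)
    # conv biases feeding straight into BN have ~zero true gradient; audit
    # weight matrices only. ReLU kinks and max-pool argmax switches make
    # single float32 finite differences noisy in early layers, so assert on
    # the error distribution rather than each coefficient.
    errs = []
    for p in net.params():
        if not p.name.endswith(".W") and not p.name.endswith("gamma"):
            continue
        flat, gflat = p.value.ravel(), p.grad.ravel()
        idx = flat.size // 2
        eps = 1e-2
        old = flat[idx]
        flat[idx] = old + eps; lp, _ = loss()
        flat[idx] = old - eps; lm, _ = loss()
        flat[idx] = old
        num = (lp - lm) / (2 * eps)
        errs.append(abs(num - gflat[idx]) / max(1e-8, abs(num) + abs(gflat[idx])))
    errs = np.asarray(errs)
    assert errs.size >= 10
    assert np.median(errs) < 0.05
    assert errs.max() < 0.5


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------

def test_lr_schedule_contract():
    assert exponential_lr(0.05, 0.96, 0) == pytest.approx(0.05)
    assert exponential_lr(0.05, 0.96, 7) == pytest.approx(0.05 * 0.96**7)


def _toy_training_set(rng, n_blocks=4, size=16, channels=6):
    x = rng.normal(size=(n_blocks, size, size, channels)).astype(np.float32)
    # separable rule: foreground where the mean feature is positive
    y = (x.mean(axis=-1) > 0).astype(np.float32)
    return x, y


def test_training_is_deterministic_for_fixed_seed(rng):
    x, y = _toy_training_set(rng)
    kw = dict(depth=3, base_channels=4, se_reduction=4, epochs=3, batch_size=2, seed=42)
    log1 = SEUnetSegmenter(**kw).fit(x, y).training_log_
    log2 = SEUnetSegmenter(**kw).fit(x, y).training_log_
    np.testing.assert_array_equal(log1.loss.to_numpy(), log2.loss.to_numpy())
    np.testing.assert_allclose(log1.lr, [0.05 * 0.96**e for e in range(3)])


def test_training_reduces_dice_loss(rng):
    x, y = _toy_training_set(rng, n_blocks=6)
    est = SEUnetSegmenter(depth=3, base_channels=8, se_reduction=4, epochs=8,
                          batch_size=3, seed=1).fit(x, y)
    losses = est.training_log_.loss.to_numpy()
    assert losses[-1] < losses[0] * 0.7
    assert est.n_params_ == est.net_.n_parameters()


def test_empty_training_set_rejected():
    est = SEUnetSegmenter(depth=3, base_channels=4, se_reduction=4)
    with pytest.raises((ConfigError, DimensionError)):
        est.fit(np.zeros((0, 16, 16, 4)), np.zeros((0, 16, 16)))


# ---------------------------------------------------------------------------
# prediction plumbing
# ---------------------------------------------------------------------------

def _forced_model(blocks, fg_logit):
    """A built model whose head emits a constant foreground logit."""
    cfg = ModelConfig(depth=3, base_channels=4, se_reduction=4, epochs=1, batch_size=1)
    model = build_model(cfg, in_channels=16)
    model.feature_names_ = blocks.feature_names
    head = model.net_.head
    head.W.value[...] = 0
    head.b.value[...] = [0.0, fg_logit]
    return model


def test_constant_foreground_model_labels_all_real_vertices(rng):
    mat = rng.random((5000, 16))
    blocks = pad_and_block(mat, FeatureConfig(k=15))
    model = _forced_model(blocks, fg_logit=10.0)
    labels = predict_regions(model, blocks)
    assert labels.shape == (5000,)
    assert np.all(labels == 1)  # pad slots dropped, none leak into the output


def test_threshold_one_gives_empty_prediction(rng):
    mat = rng.random((4096, 16))
    blocks = pad_and_block(mat, FeatureConfig(k=15))
    model = _forced_model(blocks, fg_logit=10.0)
    assert predict_regions(model, blocks, threshold=1.0).sum() == 0


def test_feature_order_mismatch_rejected(rng):
    mats = {"sulc": rng.random((256, 4)), "thick": rng.random((256, 4))}
    blocks = pad_and_block(mats, FeatureConfig(k=3, feature_names=("sulc", "thick")))
    model = _forced_model(blocks, 1.0)
    model.feature_names_ = ["thick", "sulc"]
    with pytest.raises(ConfigError, match="feature order"):
        predict_regions(model, blocks)
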