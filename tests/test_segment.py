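"""Losses, attention gates, soft voting, segmenter training, prediction path."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioseg import (EnsembleConfig, LossConfig, PhantomSpec, ProbMap, TrainConfig,
                     UNet, UNetConfig, bce_loss, build_attention_unet,
                     build_residual_unet, dice_loss, generate_dataset, hybrid_loss,
                     soft_vote, zscore_normalize)
from glioseg.errors import ConfigError
from glioseg.metrics import dice_coefficient
from glioseg.nn import Tensor
from glioseg.segment import AttentionGate, train_segmenter
from glioseg.train import EarlyStopper


# -- losses --------------------------------------------------------------------


def test_bce_closed_forms():
    y = np.array([1.0, 0.0, 1.0, 0.0])
    assert bce_loss(y, y) <= 1e-6
    assert abs(bce_loss(y, np.full(4, 0.5)) - np.log(2.0)) < 1e-9
    val = bce_loss(np.array([1.0, 0.0]), np.array([0.9, 0.2]))
    assert abs(val - (-0.5 * (np.log(0.9) + np.log(0.8)))) < 1e-9
    assert abs(val - 0.164252) < 1e-6


def test_dice_loss_conventions_and_hand_count():
    zero = np.zeros(16)
    assert dice_loss(zero, zero) == 0.0
    y = np.zeros(25)
    y[:10] = 1.0
    assert dice_loss(y, y, epsilon=1e-6) < 1e-4
    y4 = np.zeros(12)
    y4[:4] = 1
    p4 = np.zeros(12)
    p4[2:6] = 1  # overlap 2
    assert abs(dice_loss(y4, p4, epsilon=1e-6) - 0.5) < 1e-6


def test_hybrid_loss_endpoints_and_midpoint():
    rng = np.random.default_rng(0)
    y = (rng.random(30) > 0.6).astype(float)
    p = rng.random(30)
    assert hybrid_loss(y, p, LossConfig(alpha=1.0)) == bce_loss(y, p)
    assert hybrid_loss(y, p, LossConfig(alpha=0.0)) == dice_loss(y, p, 1e-6)
    mid = hybrid_loss(y, p, LossConfig(alpha=0.5))
    assert abs(mid - 0.5 * (bce_loss(y, p) + dice_loss(y, p, 1e-6))) < 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 20), alpha=st.floats(0.0, 1.0))
def test_hybrid_is_exact_affine_combination(seed, alpha):
    rng = np.random.default_rng(seed)
    y = (rng.random(20) > 0.5).astype(float)
    p = rng.random(20)
    cfg = LossConfig(alpha=alpha)
    expected = alpha * bce_loss(y, p) + (1 - alpha) * dice_loss(y, p, cfg.epsilon)
    assert abs(hybrid_loss(y, p, cfg) - expected) <= 1e-10


def test_dice_loss_complements_dice_coefficient_for_binary_predictions():
    rng = np.random.default_rng(4)
    for _ in range(20):
        y = (rng.random((12, 12)) > 0.7).astype(float)
        p = (rng.random((12, 12)) > 0.7).astype(float)
        if y.sum() + p.sum() == 0:
            continue
        loss = dice_loss(y, p, epsilon=1e-9)
        assert abs(loss - (1.0 - dice_coefficient(p, y))) < 1e-6


def test_loss_shape_mismatch_raises():
    with pytest.raises(ValueError):
        bce_loss(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 2)), np.zeros(4))


def test_losses_differentiable_for_training():
    rng = np.random.default_rng(5)
    y = Tensor((rng.random((2, 8, 8)) > 0.7).astype(float))
    logits = Tensor(rng.normal(size=(2, 8, 8)), requires_grad=True)
    loss = hybrid_loss(y, logits.sigmoid(), LossConfig())
    loss.backward()
    assert logits.grad is not None and np.all(np.isfinite(logits.grad))


# -- attention gate ---------------------------------------------------------------


def _gate_fixture():
    rng = np.random.default_rng(6)
    g = AttentionGate(4, 8, 2, np.random.default_rng(0))
    skip = Tensor(rng.normal(size=(1, 4, 8, 8)))
    gating = Tensor(rng.normal(size=(1, 8, 8, 8)))
    return g, skip, gating


def test_gate_zero_preactivation_halves_skip():
    g, skip, gating = _gate_fixture()
    g.psi.weight.data[:] = 0.0
    g.psi.bias.data[:] = 0.0
    out = g(skip, gating)
    np.testing.assert_allclose(out.data, skip.data / 2.0, atol=1e-12)


def test_gate_saturation_limits():
    g, skip, gating = _gate_fixture()
    g.psi.weight.data[:] = 0.0
    g.psi.bias.data[:] = 50.0  # w -> 1
    np.testing.assert_allclose(g(skip, gating).data, skip.data, atol=1e-9)
    g.psi.bias.data[:] = -50.0  # w -> 0
    np.testing.assert_allclose(g(skip, gating).data, 0.0, atol=1e-9)


def test_gate_weights_bounded():
    g, skip, gating = _gate_fixture()
    w = g.weights(skip, gating).data
    assert np.all(w >= 0.0) and np.all(w <= 1.0)


# -- architectures ------------------------------------------------------------------


def test_unet_init_deterministic_and_output_contract():
    cfg = UNetConfig(depth=2, base_channels=4)
    a = build_attention_unet(cfg, 3)
    b = build_attention_unet(cfg, 3)
    for (_, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
    pm = a.predict_proba(np.random.default_rng(1).normal(size=(16, 16)))
    assert pm.probs.shape == (16, 16)
    assert pm.probs.min() >= 0.0 and pm.probs.max() <= 1.0


def test_depth_one_unet_runs_on_8x8():
    model = UNet(UNetConfig(depth=1, base_channels=2, use_attention_gates=True), 0)
    pm = model.predict_proba(np.zeros((8, 8)))
    assert pm.probs.shape == (8, 8)


def test_unet_too_small_input_raises():
    model = UNet(UNetConfig(depth=3, base_channels=2), 0)
    with pytest.raises(ConfigError):
        model.predict_proba(np.zeros((4, 4)))


def test_residual_unet_differs_structurally():
    res = build_residual_unet(UNetConfig(depth=2, base_channels=4), 0)
    assert res.config.residual_encoder
    names = [n for n, _ in res.named_parameters()]
    assert any("short" in n for n in names)


def test_gae_encoder_transfer_copies_matching_kernels():
    from glioseg import GAEConfig, build_gae
    from glioseg.segment import init_encoder_from_gae

    gae = build_gae(GAEConfig(encoder_depth=3, base_channels=4, latent_channels=16,
                              attention_dim=4), 1)
    unet = UNet(UNetConfig(depth=3, base_channels=4), 2)
    copied = init_encoder_from_gae(unet, gae)
    assert copied == 3
    np.testing.assert_array_equal(unet.inc.conv.weight.data,
                                  gae.encoder_stages[0].conv.weight.data)


# -- soft vote -----------------------------------------------------------------------


def test_soft_vote_idempotent_mean_and_degenerate_weights():
    rng = np.random.default_rng(7)
    p = rng.random((8, 8))
    m1, m2 = ProbMap(p.copy()), ProbMap(p.copy())
    out = soft_vote([m1, m2], EnsembleConfig(weights=(0.5, 0.5)))
    np.testing.assert_allclose(out.probs, p, atol=1e-12)

    a, b = ProbMap(np.full((4, 4), 0.2)), ProbMap(np.full((4, 4), 0.8))
    np.testing.assert_allclose(
        soft_vote([a, b], EnsembleConfig(weights=(1.0, 1.0))).probs, 0.5, atol=1e-12)
    np.testing.assert_allclose(
        soft_vote([a, b], EnsembleConfig(weights=(1.0, 0.0))).probs, 0.2, atol=1e-12)


def test_soft_vote_bounded_by_member_envelope():
    rng = np.random.default_rng(8)
    maps = [ProbMap(rng.random((6, 6))) for _ in range(3)]
    out = soft_vote(maps, EnsembleConfig(weights=(0.2, 0.5, 0.3)))
    stack = np.stack([m.probs for m in maps])
    assert np.all(out.probs <= stack.max(axis=0) + 1e-12)
    assert np.all(out.probs >= stack.min(axis=0) - 1e-12)


def test_soft_vote_shape_mismatch_raises():
    with pytest.raises(ValueError):
        soft_vote([ProbMap(np.zeros((4, 4))), ProbMap(np.zeros((5, 5)))],
                  EnsembleConfig(weights=(0.5, 0.5)))


# -- training -------------------------------------------------------------------------


def test_early_stopper_patience_one_stops_after_second_epoch():
    stopper = EarlyStopper(patience=1)
    assert not stopper.update(1.0, epoch=0)
    assert stopper.update(1.1, epoch=1)  # strictly worsening -> stop at epoch 2
    assert stopper.best_epoch == 0


def test_early_stopper_resets_on_improvement():
    stopper = EarlyStopper(patience=2)
    values = [1.0, 0.9, 0.95, 0.85, 0.9, 0.95]
    stops = [stopper.update(v, e) for e, v in enumerate(values)]
    assert stops == [False, False, False, False, False, True]
    assert stopper.best == 0.85


def _phantom_training_set(n_subjects=17, seed=31):
    spec = PhantomSpec(image_size=64, n_subjects=n_subjects, slices_per_subject=3,
                       tumor_prevalence=0.6, seed=seed)
    samples, _ = generate_dataset(spec)
    x = np.stack([zscore_normalize(s.image)[0] for s in samples])
    y = np.stack([s.mask.astype(float) for s in samples])
    return x, y


def test_segmenter_reaches_high_dice_on_easy_phantoms():
    """~50 high-contrast phantoms, <= 10 epochs on CPU: train Dice >= 0.9."""
    x, y = _phantom_training_set()
    model = UNet(UNetConfig(depth=3, base_channels=8), 13)
    model, history = train_segmenter(
        model, x, y, TrainConfig(max_epochs=10, learning_rate=3e-3, seed=42),
        LossConfig())
    dices = [dice_coefficient(model.predict_proba(xi).binarize(0.5), yi)
             for xi, yi in zip(x, y)]
    assert np.mean(dices) >= 0.9


def test_segmenter_histories_reproducible():
    x, y = _phantom_training_set(n_subjects=4, seed=5)
    tc = TrainConfig(max_epochs=2, learning_rate=3e-3, seed=42)
    _, h1 = train_segmenter(UNet(UNetConfig(depth=2, base_channels=4), 1), x, y,
                            tc, LossConfig())
    _, h2 = train_segmenter(UNet(UNetConfig(depth=2, base_channels=4), 1), x, y,
                            tc, LossConfig())
    assert h1 == h2


def test_train_segmenter_rejects_bad_roi_mode():
    x, y = _phantom_training_set(n_subjects=4, seed=5)
    with pytest.raises(ConfigError):
        train_segmenter(UNet(UNetConfig(depth=2, base_channels=4), 1), x, y,
                        TrainConfig(max_epochs=1), LossConfig(), roi_mode="bogus")
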