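"""Input encoding, network construction and training behavior of the refiner."""

import numpy as np
import pytest

from perioloss.prior import TrainingExample
from perioloss.refiner import (
    RefinerConfig,
    build_refiner,
    encode_input,
    masked_mse,
    predict_keypoints,
    train_refiner,
)

TINY = dict(input_height=16, input_width=12, n_blocks=2, filters_per_block=(4, 6),
            batch_size=8, heatmap_sigma=1.5)


def _image(rng, h=32, w=24):
    return rng.random((h, w)).astype(np.float32) * 255


def test_encode_shape_and_standardization():
    cfg = RefinerConfig(**TINY)
    rng = np.random.default_rng(0)
    enc = encode_input(_image(rng), rng.random(12), cfg)
    assert enc.shape == (16, 12, 7)
    assert enc[:, :, 0].mean() == pytest.approx(0.0, abs=1e-5)
    assert enc[:, :, 0].std() == pytest.approx(1.0, abs=1e-4)


def test_heatmap_peaks_at_prior_keypoint():
    cfg = RefinerConfig(input_height=64, input_width=48, n_blocks=2,
                        filters_per_block=(4, 6), heatmap_sigma=2.0)
    rng = np.random.default_rng(1)
    prior = np.full(12, 0.5)
    prior[0], prior[1] = 0.25, 0.75  # mesial CEJ
    enc = encode_input(_image(rng, 64, 48), prior, cfg)
    peak = np.unravel_index(np.argmax(enc[:, :, 1]), enc[:, :, 1].shape)
    assert peak == (round(0.75 * 63), round(0.25 * 47))


def test_heatmap_mass_matches_gaussian_integral():
    """An interior unit-amplitude Gaussian integrates to ~2*pi*sigma^2."""
    cfg = RefinerConfig(input_height=64, input_width=48, n_blocks=2,
                        filters_per_block=(4, 6), heatmap_sigma=3.0)
    rng = np.random.default_rng(2)
    enc = encode_input(_image(rng, 64, 48), np.full(12, 0.5), cfg)
    expected = 2.0 * np.pi * cfg.heatmap_sigma**2
    for ch in range(1, 7):
        assert enc[:, :, ch].sum() == pytest.approx(expected, rel=0.05)


def test_same_seed_builds_identical_networks():
    a = build_refiner(RefinerConfig(**TINY, seed=3))
    b = build_refiner(RefinerConfig(**TINY, seed=3))
    for wa, wb in zip(a.get_weights(), b.get_weights()):
        np.testing.assert_array_equal(wa, wb)
    c = build_refiner(RefinerConfig(**TINY, seed=4))
    assert any(not np.array_equal(wa, wc) for wa, wc in zip(a.get_weights(), c.get_weights()))


def test_config_validation():
    with pytest.raises(ValueError):
        RefinerConfig(n_blocks=2, filters_per_block=(8,))
    with pytest.raises(ValueError):
        RefinerConfig(dropout_rate=1.0)


def test_fully_masked_examples_do_not_move_the_loss():
    rng = np.random.default_rng(5)
    pred, true = rng.random((6, 12)), rng.random((6, 12))
    mask = np.ones((6, 12), dtype=bool)
    sse, n = masked_mse(pred, true, mask)
    extra_pred = np.vstack([pred, rng.random((2, 12))])
    extra_true = np.vstack([true, rng.random((2, 12))])
    extra_mask = np.vstack([mask, np.zeros((2, 12), dtype=bool)])
    sse2, n2 = masked_mse(extra_pred, extra_true, extra_mask)
    assert sse2 == pytest.approx(sse) and n2 == n


def _triples(rng, n, cfg, copy_through=False):
    out = []
    for i in range(n):
        img = _image(rng, cfg.input_height, cfg.input_width)
        prior = rng.uniform(0.2, 0.8, 12)
        true = prior if copy_through else np.clip(prior + rng.normal(0, 0.08, 12), 0, 1)
        out.append(TrainingExample(f"m{i}", img, prior, true.copy()))
    return out


def test_training_reduces_loss_and_is_reproducible():
    cfg = RefinerConfig(**TINY, max_epochs=4, seed=6)
    rng = np.random.default_rng(6)
    triples = _triples(rng, 48, cfg)
    model, hist = train_refiner(build_refiner(cfg), triples, cfg)
    assert hist.train_mse[-1] < hist.train_mse[0]
    assert len(hist.train_mse) == len(hist.val_mse) == hist.stopped_epoch
    model2, hist2 = train_refiner(build_refiner(cfg), _triples(np.random.default_rng(6), 48, cfg), cfg)
    np.testing.assert_array_equal(hist.train_mse, hist2.train_mse)
    for wa, wb in zip(model.get_weights(), model2.get_weights()):
        np.testing.assert_array_equal(wa, wb)


def test_copy_through_task_is_learned_exactly():
    """When the target equals the prior, validation MSE collapses below 1e-3."""
    cfg = RefinerConfig(**TINY, max_epochs=3, seed=7)
    rng = np.random.default_rng(7)
    _, hist = train_refiner(build_refiner(cfg), _triples(rng, 48, cfg, copy_through=True), cfg)
    assert hist.val_mse[-1] < 1e-3


def test_early_stopping_halts_on_rising_validation_loss():
    cfg = RefinerConfig(**TINY, max_epochs=12, early_stop_patience=1,
                        learning_rate=0.5, seed=8)  # divergent step size
    rng = np.random.default_rng(8)
    _, hist = train_refiner(build_refiner(cfg), _triples(rng, 40, cfg), cfg)
    assert hist.stopped_epoch < cfg.max_epochs


def test_training_rejects_tiny_datasets():
    cfg = RefinerConfig(**TINY)
    with pytest.raises(ValueError):
        train_refiner(build_refiner(cfg), _triples(np.random.default_rng(9), 8, cfg), cfg)


def test_prediction_contract_and_determinism():
    cfg = RefinerConfig(**TINY, seed=10)
    model = build_refiner(cfg)
    rng = np.random.default_rng(10)
    img, prior = _image(rng), rng.random(12)
    p1 = predict_keypoints(model, img, prior)
    p2 = predict_keypoints(model, img, prior)
    np.testing.assert_array_equal(p1, p2)
    assert p1.shape == (12,)
    assert np.all((p1 >= 0.0) & (p1 <= 1.0))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_refined_keypoints_beat_prior_by_wide_margin(seed):
    """Refinement dominance: held-out keypoint error < 80% of the prior's.

    Parameter-recovery experiment on synthetic molars with localizable
    landmarks: the network, given the image, must localize keypoints clearly
    better than the statistical prior that only knows coordinate marginals.
    """
    from perioloss.annotations import orient_molar
    from perioloss.prior import (
        augment_training_set,
        fit_coordinate_distributions,
        sample_prior,
    )
    from perioloss.synthgen import SynthParams, generate_dataset

    train_m, _ = generate_dataset(SynthParams(seed=400 + seed), 300)
    train_m = [orient_molar(m) for m in train_m]
    test_m, _ = generate_dataset(SynthParams(seed=500 + seed), 100)
    test_m = [orient_molar(m) for m in test_m]
    vectors = np.array([m.keypoint_vector()[0] for m in train_m])
    prior = fit_coordinate_distributions(vectors)
    triples = augment_training_set(train_m, prior, k=10, seed=seed)
    cfg = RefinerConfig(input_height=32, input_width=24, filters_per_block=(16, 32, 64),
                        heatmap_sigma=2.0, max_epochs=15, early_stop_patience=4, seed=seed)
    model, _ = train_refiner(build_refiner(cfg), triples, cfg)

    prior_vecs = sample_prior(prior, len(test_m), seed=600 + seed)
    def mean_err(vecs):
        return np.mean([
            np.linalg.norm((v - m.keypoint_vector()[0]).reshape(6, 2), axis=1).mean()
            for m, v in zip(test_m, vecs)
        ])
    err_prior = mean_err(prior_vecs)
    err_refined = mean_err(
        [predict_keypoints(model, m.image, p) for m, p in zip(test_m, prior_vecs)]
    )
    assert err_refined < 0.8 * err_prior


def test_model_save_load_roundtrip(tmp_path):
    cfg = RefinerConfig(**TINY, seed=11)
    model = build_refiner(cfg)
    model.save(tmp_path / "model")
    from perioloss.refiner import SeparableConvRefiner

    loaded = SeparableConvRefiner.load(tmp_path / "model")
    rng = np.random.default_rng(11)
    img, prior = _image(rng), rng.random(12)
    np.testing.assert_array_equal(
        predict_keypoints(model, img, prior), predict_keypoints(loaded, img, prior)
    )
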