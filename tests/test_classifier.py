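"""CAE streams, feature fusion, bilinear pooling, refinement training."""

import numpy as np
import pytest

from gliomap import classifier as cm
from gliomap import preprocess as pp


# ---------------------------------------------------------------------------
# fusion operations
# ---------------------------------------------------------------------------

def test_aggregate_identity_and_square(rng):
    f1 = rng.normal(size=(4, 4, 8))
    assert np.array_equal(cm.aggregate(f1, np.ones_like(f1)), f1)
    assert np.allclose(cm.aggregate(f1, f1), f1 ** 2)
    assert np.allclose(cm.aggregate(np.array([[[1.0, 2.0]]]),
                                    np.array([[[3.0, 4.0]]])), [[[3.0, 8.0]]])
    with pytest.raises(ValueError):
        cm.aggregate(f1, f1[:2])


def test_bilinear_of_ones_counts_spatial_positions():
    H = cm.bilinear(np.ones((2, 2, 3)))
    assert H.shape == (3, 3)
    assert np.allclose(H, 4.0)
    assert np.allclose(cm.bilinear(np.zeros((2, 2, 3))), 0.0)


def test_bilinear_matches_bruteforce_double_sum(rng):
    """H = FᵀF equals sum over positions of outer products f f^T."""
    for _ in range(100):
        f = rng.normal(size=(2, 2, 3))
        H = cm.bilinear(f)
        brute = np.zeros((3, 3))
        for i in range(2):
            for j in range(2):
                brute += np.outer(f[i, j], f[i, j])
        assert np.allclose(H, brute, atol=1e-10)
        assert np.array_equal(H, H.T)
        assert np.all(np.linalg.eigvalsh(H) > -1e-9)  # PSD


def test_signed_sqrt_and_l2_normalize():
    h = np.array([4.0, -9.0, 0.0])
    assert np.allclose(cm.signed_sqrt(h), [2.0, -3.0, 0.0])
    n = cm.l2_normalize(np.array([3.0, 4.0]))
    assert np.allclose(n, [0.6, 0.8])


# ---------------------------------------------------------------------------
# CAE
# ---------------------------------------------------------------------------

def test_full_scale_encoder_and_decoder_dims(rng):
    """64x64x1 input -> 8x8x512 encoding -> 64x64x1 reconstruction."""
    spec = cm.CAESpec()
    assert spec.feature_size == 8 and spec.feature_channels == 512
    enc = cm.build_encoder(spec, np.random.default_rng(0))
    dec = cm.build_decoder(spec, np.random.default_rng(0))
    x = rng.random((1, 1, 64, 64)).astype(np.float32)
    f = enc.forward(x, train=False)
    assert f.shape == (1, 512, 8, 8)
    assert dec.forward(f, train=False).shape == (1, 1, 64, 64)


def test_pretrain_reduces_reconstruction_error(tiny_cohort):
    """Toy reconstruction pre-training at least halves the MSE."""
    _, patients = tiny_cohort
    ds = pp.build_slice_dataset(patients, k=4, out_size=16, seed=0)
    spec = cm.CAESpec.tiny(input_size=16, epochs=12, seed=0)
    cae = cm.pretrain_cae(ds.x_flair, spec)
    assert cae.trained and len(cae.history) == 12
    assert cae.history[-1]["mse"] < 0.5 * cae.history[0]["mse"]


def test_encode_contracts(tiny_cohort):
    _, patients = tiny_cohort
    ds = pp.build_slice_dataset(patients, k=2, out_size=16, seed=0)
    spec = cm.CAESpec.tiny(input_size=16, epochs=1, seed=0)
    cae = cm.pretrain_cae(ds.x_flair, spec)
    f = cm.encode(cae, ds.x_flair[0])
    assert f.shape == (4, 4, 16)
    assert np.array_equal(f, cm.encode(cae, ds.x_flair[0]))  # deterministic
    # zero input with fresh (zero-bias, zero-running-mean) encoder -> zeros
    enc = cm.build_encoder(spec, np.random.default_rng(1))
    z = enc.forward(np.zeros((1, 1, 16, 16), np.float32), train=False)
    assert np.allclose(z, 0.0)
    with pytest.raises(ValueError):
        cm.encode(cae, np.zeros((32, 32)))


def test_pretrain_rejects_bad_input():
    spec = cm.CAESpec.tiny(input_size=16)
    with pytest.raises(ValueError):
        cm.pretrain_cae(np.zeros((4, 32, 32), np.float32), spec)
    with pytest.raises(ValueError):
        cm.pretrain_cae(np.zeros((0, 16, 16), np.float32), spec)


# ---------------------------------------------------------------------------
# refinement + prediction
# ---------------------------------------------------------------------------

def test_refine_smoke_and_early_stopping_bookkeeping(tiny_cohort):
    _, patients = tiny_cohort
    ds = pp.build_slice_dataset(patients, k=4, out_size=16, seed=0)
    cfg = cm.RefineConfig(epochs=3, patience=3, seed=0)
    clf = cm.refine_train(None, None, ds, ds, config=cfg,
                          spec=cm.CAESpec.tiny(input_size=16))
    assert clf.trained
    assert 1 <= clf.best_epoch <= 3
    assert all(np.isfinite(h["train_loss"]) for h in clf.history)
    probs = cm.predict(clf, ds.x_t1ce[:5], ds.x_flair[:5])
    assert probs.shape == (5, 2)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    assert np.array_equal(probs, cm.predict(clf, ds.x_t1ce[:5], ds.x_flair[:5]))


def test_predict_requires_both_modalities(tiny_cohort):
    _, patients = tiny_cohort
    ds = pp.build_slice_dataset(patients, k=2, out_size=16, seed=0)
    cfg = cm.RefineConfig(epochs=1, patience=1, seed=0)
    clf = cm.refine_train(None, None, ds, ds, config=cfg,
                          spec=cm.CAESpec.tiny(input_size=16))
    with pytest.raises(ValueError):
        cm.predict(clf, ds.x_t1ce[:2], ds.x_flair[:1])


def test_trained_toy_model_fits_training_samples(tiny_cohort):
    """After fitting, most training slices get the right argmax."""
    _, patients = tiny_cohort
    ds = pp.build_slice_dataset(patients, k=4, out_size=16, seed=0)
    cfg = cm.RefineConfig(epochs=15, patience=15, augment=False, seed=0)
    clf = cm.refine_train(None, None, ds, ds, config=cfg,
                          spec=cm.CAESpec.tiny(input_size=16))
    pred = np.argmax(cm.predict(clf, ds.x_t1ce, ds.x_flair), axis=1)
    assert np.mean(pred == ds.y) > 0.8


def test_fusion_head_backward_matches_numeric_gradient(rng):
    head = cm.FusionHead(channels=3, hidden=8, dropout=0.0,
                         rng=np.random.default_rng(0))
    H = rng.normal(size=(2, 3, 3)).astype(np.float32)
    H = H @ H.transpose(0, 2, 1)  # PSD like a real bilinear map
    t = rng.normal(size=(2, 2)).astype(np.float32)

    def loss():
        return float(np.sum(head.forward(H.copy(), train=False) * t))

    head.forward(H.copy(), train=False)
    dH = head.backward(t)
    eps = 1e-3
    num = np.zeros_like(H)
    for idx in np.ndindex(H.shape):
        old = H[idx]
        H[idx] = old + eps
        lp = loss()
        H[idx] = old - eps
        lm = loss()
        H[idx] = old
        num[idx] = (lp - lm) / (2 * eps)
    assert np.abs(dH - num).max() < 5e-2
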