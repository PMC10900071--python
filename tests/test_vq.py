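import numpy as np
import pytest

from ltm_ood import (Codebook, VQConfig, VQVAE, ema_update, latent_shape,
                     quantize, reconstruction_mse_score, train_vqvae, vq_loss)
from ltm_ood.nn import Tensor

rng = np.random.default_rng(0)


@pytest.mark.parametrize("shape,levels,expected,seq_len", [
    ((176, 208, 176), 4, (11, 13, 11), 1573),
    ((28, 28), 2, (7, 7), 49),
    ((16, 16, 16), 0, (16, 16, 16), 4096),
    ((9, 12, 10), 2, (3, 3, 3), 27),      # padded up to multiples of 4
])
def test_latent_shape_arithmetic(shape, levels, expected, seq_len):
    dims, n = latent_shape(shape, levels)
    assert dims == expected
    assert n == seq_len


def _codebook(K, n):
    entries = rng.standard_normal((K, n))
    return Codebook(entries=entries, ema_counts=np.ones(K),
                    ema_sums=entries.copy())


def test_quantize_exact_entry_and_tie_break():
    cb = _codebook(8, 4)
    lat = np.stack([cb.entries[3], cb.entries[5]])[None]  # grid (1, 2, n)
    cg = quantize(lat, cb)
    assert cg.indices.tolist() == [[3, 5]]
    # two identical entries: the lower index wins
    cb2 = Codebook(entries=np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                   ema_counts=np.ones(3), ema_sums=np.zeros((3, 2)))
    cg2 = quantize(np.array([[[1.0, 0.1]]]), cb2)
    assert cg2.indices[0, 0] == 0


def test_quantize_matches_bruteforce_oracle():
    cb = _codebook(8, 6)
    lat = rng.standard_normal((10, 10, 6))
    got = quantize(lat, cb).indices
    for i in range(10):
        for j in range(10):
            d = [(np.sum((lat[i, j] - e) ** 2), k)
                 for k, e in enumerate(cb.entries.astype(np.float64))]
            best = min(d)[1]
            assert got[i, j] == best


def test_quantize_rejects_dimension_mismatch():
    with pytest.raises(ValueError):
        quantize(rng.standard_normal((2, 2, 5)), _codebook(4, 6))


def test_ema_update_decay_free_limit_gives_cluster_means():
    cb = _codebook(3, 2)
    lat = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 0.0], [6.0, 0.0]])
    assign = np.array([0, 0, 1, 1])
    out = ema_update(cb, lat, assign, decay=0.0, eps=1e-12)
    assert np.allclose(out.entries[0], [1.0, 1.0], atol=1e-5)
    assert np.allclose(out.entries[1], [5.0, 0.0], atol=1e-5)


def test_ema_update_leaves_unassigned_entry_unchanged():
    cb = _codebook(3, 2)
    before = cb.entries[2].copy()
    lat = np.array([[1.0, 1.0], [3.0, 3.0]])
    out = ema_update(cb, lat, np.array([0, 1]), decay=0.99)
    assert np.allclose(out.entries[2], before, atol=1e-4)


def test_ema_repeated_updates_converge_to_cluster_means():
    """Geometric decay: after t updates on a fixed batch the EMA statistics
    are within gamma^t of the batch statistics, so entries approach means."""
    cb = _codebook(2, 2)
    lat = np.array([[1.0, 2.0], [1.0, 2.0], [-3.0, 0.0]])
    assign = np.array([0, 0, 1])
    for _ in range(1000):
        cb = ema_update(cb, lat, assign, decay=0.99)
    assert np.allclose(cb.entries[0], [1.0, 2.0], atol=1e-3)
    assert np.allclose(cb.entries[1], [-3.0, 0.0], atol=1e-3)


def test_codebook_invariants():
    with pytest.raises(ValueError):
        Codebook(entries=np.ones((1, 4)), ema_counts=np.ones(1),
                 ema_sums=np.ones((1, 4)))
    with pytest.raises(ValueError):
        Codebook(entries=np.full((4, 2), np.nan), ema_counts=np.ones(4),
                 ema_sums=np.ones((4, 2)))


@pytest.fixture(scope="module")
def untrained_model():
    return VQVAE(VQConfig(levels=2, K=8, n=4, base_channels=2, seed=0))


def test_encode_decode_shapes_and_finiteness(untrained_model, small_volume):
    cg = untrained_model.encode(small_volume)
    assert cg.indices.shape == (4, 4, 4)
    recon = untrained_model.decode(cg)
    assert recon.intensities.shape == small_volume.intensities.shape
    assert np.all(np.isfinite(recon.intensities))


def test_encode_decode_with_padding(untrained_model):
    from ltm_ood.phantoms import Volume
    v = Volume(intensities=rng.random((9, 12, 10)).astype(np.float32))
    cg = untrained_model.encode(v)
    assert cg.indices.shape == (3, 3, 3)
    assert untrained_model.decode(cg).intensities.shape == (9, 12, 10)


def test_vq_loss_closed_forms_and_decomposition(untrained_model):
    x = rng.random((2, 1, 8, 8, 8)).astype(np.float32)
    cfg = VQConfig(loss_weights={"mse": 1.0, "spectral": 0.5, "perceptual": 0.0,
                                 "adversarial": 0.0, "commitment": 0.25})
    z = rng.standard_normal((2, 4, 2, 2, 2)).astype(np.float32)
    zq = z + 0.1
    # perfect reconstruction: mse and spectral both vanish
    parts = vq_loss(x, Tensor(x.copy()), Tensor(z), z, cfg)
    assert parts["mse"].item() == pytest.approx(0.0, abs=1e-7)
    assert parts["spectral"].item() == pytest.approx(0.0, abs=1e-7)
    # constant offset delta: mse = delta^2
    delta = 0.2
    parts = vq_loss(x, Tensor(x + delta), Tensor(z), zq, cfg)
    assert parts["mse"].item() == pytest.approx(delta ** 2, rel=1e-4)
    # total equals the weighted sum of the parts
    expected = sum(cfg.loss_weights[k] * parts[k].item()
                   for k in cfg.loss_weights)
    assert parts["total"].item() == pytest.approx(expected, rel=1e-6)
    # spectral is zero iff mse is zero
    assert parts["spectral"].item() > 0
    # mse-only weights: total == mse
    cfg2 = VQConfig(loss_weights={"mse": 1.0, "spectral": 0.0, "perceptual": 0.0,
                                  "adversarial": 0.0, "commitment": 0.0})
    parts2 = vq_loss(x, Tensor(x + delta), Tensor(z), zq, cfg2)
    assert parts2["total"].item() == pytest.approx(parts2["mse"].item(), rel=1e-6)


def test_reconstruction_mse_score_semantics(untrained_model, small_volume):
    out = reconstruction_mse_score(small_volume, untrained_model)
    assert out["normalised_defined"]
    assert out["normalised"] == pytest.approx(
        out["mse"] / small_volume.intensities.mean(), rel=1e-5)
    from ltm_ood.phantoms import Volume
    zero = Volume(intensities=np.zeros((8, 8, 8), dtype=np.float32))
    flagged = reconstruction_mse_score(zero, untrained_model)
    assert not flagged["normalised_defined"] and flagged["normalised"] is None


def test_constant_image_mse_closed_form():
    """Constant image of value m reconstructed as 0 has MSE m^2, normalised m."""
    m = 0.4
    x = np.full((8, 8, 8), m)
    mse = float(np.mean((x - 0.0) ** 2))
    assert mse == pytest.approx(m ** 2, rel=1e-6)
    assert mse / x.mean() == pytest.approx(m, rel=1e-6)


def test_training_beats_mean_image_baseline_and_uses_codebook():
    """A trained compressor must out-reconstruct the dataset-mean predictor
    (which ignores the input) and must spread load over several codes."""
    import ltm_ood as lt
    spec = lt.PhantomSpec(grid_shape=(16, 16, 16), lesion_count_range=(0, 1), seed=4)
    vols = lt.generate_cohort(spec, 16, base_seed=21)
    cfg = VQConfig(levels=1, K=128, n=8, base_channels=8, lr=3e-3,
                   final_up_kernel=3, epochs=150, warmup_epochs=75, seed=2)
    model = train_vqvae(vols, cfg)
    X = np.stack([v.intensities for v in vols])
    baseline = float(np.mean((X - X.mean(axis=0)) ** 2))
    recon = float(np.mean([np.mean((model.reconstruct(v) - v.intensities) ** 2)
                           for v in vols]))
    assert recon < baseline
    codes = np.concatenate([model.encode(v).indices.ravel() for v in vols])
    assert len(np.unique(codes)) >= 2      # no codebook collapse
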