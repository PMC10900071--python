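import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltm_ood import (CausalTransformer, TokenSequence, TransformerConfig,
                     flatten, sequence_loglik, spatial_likelihood_map, train_ar,
                     unflatten)
from ltm_ood.vq import CodeGrid

rng = np.random.default_rng(1)


def _grid(indices):
    idx = np.asarray(indices)
    return CodeGrid(indices=idx, latent_shape=idx.shape)


def test_flatten_raster_order_and_roundtrip():
    cg = _grid(np.arange(8).reshape(2, 2, 2))
    ts = flatten(cg, vocab=8)
    assert ts.tokens.tolist() == [0, 1, 2, 3, 4, 5, 6, 7]  # last axis fastest
    back = unflatten(ts)
    assert np.array_equal(back.indices, cg.indices)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_flatten_unflatten_identity_random_grids(seed):
    g = np.random.default_rng(seed)
    shape = tuple(int(s) for s in g.integers(1, 5, size=3))
    cg = _grid(g.integers(0, 7, size=shape))
    assert np.array_equal(unflatten(flatten(cg, vocab=7)).indices, cg.indices)


def test_flatten_differs_for_mirrored_grid():
    idx = np.arange(8).reshape(2, 2, 2)
    asym = flatten(_grid(idx), vocab=8).tokens
    mirrored = flatten(_grid(idx[::-1].copy()), vocab=8).tokens
    assert not np.array_equal(asym, mirrored)
    sym = np.zeros((2, 2, 2), dtype=int)
    assert np.array_equal(flatten(_grid(sym), vocab=1).tokens,
                          flatten(_grid(sym[::-1].copy()), vocab=1).tokens)


def test_token_sequence_validation():
    with pytest.raises(ValueError):
        TokenSequence(tokens=np.array([0, 1]), latent_shape=(3,), vocab=4)
    with pytest.raises(ValueError):
        TokenSequence(tokens=np.array([0, 4]), latent_shape=(2,), vocab=4)


def _uniform_model(vocab=4, seq_len=3):
    """A transformer forced to the uniform distribution: zero output head."""
    model = CausalTransformer(TransformerConfig(vocab=vocab, seq_len=seq_len,
                                                n_layers=1, n_heads=1,
                                                d_model=8, seed=0))
    model.head.w.data[:] = 0.0
    model.head.b.data[:] = 0.0
    model.trained = True
    return model


def test_uniform_model_closed_form_loglik():
    model = _uniform_model(vocab=4, seq_len=3)
    ts = TokenSequence(tokens=np.array([2, 0, 3]), latent_shape=(3,), vocab=4)
    lr = sequence_loglik(ts, model)
    assert lr.total_loglik == pytest.approx(3 * np.log(1 / 4), abs=1e-5)
    assert np.allclose(lr.per_token_logp, np.log(1 / 4), atol=1e-6)


def test_conditionals_normalise_and_sum_matches_total():
    model = CausalTransformer(TransformerConfig(vocab=6, seq_len=5, n_layers=2,
                                                n_heads=2, d_model=16, seed=3))
    toks = rng.integers(0, 6, size=(2, 5))
    probs = model.logits(toks).softmax(axis=-1).data
    assert np.allclose(probs.sum(-1), 1.0, atol=1e-5)
    ts = TokenSequence(tokens=toks[0], latent_shape=(5,), vocab=6)
    lr = sequence_loglik(ts, model)
    assert lr.total_loglik == pytest.approx(float(lr.per_token_logp.sum()), abs=1e-5)
    assert np.all(lr.per_token_logp <= 0)


def test_loglik_matches_prefix_by_prefix_oracle():
    """Batched likelihood equals feeding prefixes one at a time."""
    model = CausalTransformer(TransformerConfig(vocab=5, seq_len=6, n_layers=2,
                                                n_heads=2, d_model=16, seed=7))
    for _ in range(10):
        toks = rng.integers(0, 5, size=6)
        ts = TokenSequence(tokens=toks, latent_shape=(6,), vocab=5)
        lr = sequence_loglik(ts, model)
        total = 0.0
        for i in range(6):
            prefix = toks[:i + 1][None]
            lp = model.logits(prefix).log_softmax(axis=-1).data[0, i]
            total += lp[toks[i]]
        assert lr.total_loglik == pytest.approx(total, abs=1e-4)


def test_sequence_validation_against_model():
    model = _uniform_model(vocab=4, seq_len=3)
    with pytest.raises(ValueError):
        sequence_loglik(TokenSequence(tokens=np.array([0, 1]), latent_shape=(2,),
                                      vocab=4), model)
    with pytest.raises(ValueError):
        sequence_loglik(TokenSequence(tokens=np.array([0, 1, 9]), latent_shape=(3,),
                                      vocab=10), model)


def test_train_ar_rejects_inconsistent_inputs():
    a = TokenSequence(tokens=np.array([0, 1, 2]), latent_shape=(3,), vocab=4)
    b = TokenSequence(tokens=np.array([0, 1]), latent_shape=(2,), vocab=4)
    with pytest.raises(ValueError):
        train_ar([a, b])
    c = TokenSequence(tokens=np.array([0, 1, 2]), latent_shape=(3,), vocab=7)
    with pytest.raises(ValueError):
        train_ar([a, c])
    with pytest.raises(ValueError):
        train_ar([])


def test_training_is_seeded_and_deterministic():
    seqs = [TokenSequence(tokens=rng.integers(0, 4, 8), latent_shape=(8,), vocab=4)
            for _ in range(8)]
    cfg = TransformerConfig(vocab=4, seq_len=8, n_layers=1, n_heads=1,
                            d_model=16, epochs=3, seed=5)
    h1 = train_ar(seqs, cfg).history
    h2 = train_ar(seqs, cfg).history
    assert h1 == h2


def test_constant_sequences_learn_near_certainty():
    seqs = [TokenSequence(tokens=np.full(8, 2), latent_shape=(8,), vocab=4)
            for _ in range(16)]
    cfg = TransformerConfig(vocab=4, seq_len=8, n_layers=1, n_heads=1,
                            d_model=16, epochs=40, lr=3e-3, seed=5)
    model = train_ar(seqs, cfg)
    lr = sequence_loglik(seqs[0], model)
    assert lr.total_loglik > -0.2   # per-token logp approaches 0


def test_spatial_map_constant_shape_and_nearest_neighbour():
    from ltm_ood import LikelihoodResult
    c = -1.7
    lr = LikelihoodResult(total_loglik=8 * c,
                          per_token_logp=np.full(8, c), latent_shape=(2, 2, 2))
    m = spatial_likelihood_map(lr, 3)
    assert m.shape == (6, 6, 6)
    assert np.allclose(m, c)
    # voxel-by-voxel nearest-neighbour oracle on a random map
    vals = rng.standard_normal(8)
    lr2 = LikelihoodResult(total_loglik=float(vals.sum()),
                           per_token_logp=vals, latent_shape=(2, 2, 2))
    m2 = spatial_likelihood_map(lr2, 2)
    grid = vals.reshape(2, 2, 2)
    for x in range(4):
        for y in range(4):
            for z in range(4):
                assert m2[x, y, z] == grid[x // 2, y // 2, z // 2]
    with pytest.raises(ValueError):
        spatial_likelihood_map(lr2, 0)


def test_spatial_map_paper_scale_shape():
    from ltm_ood import LikelihoodResult
    lr = LikelihoodResult(total_loglik=0.0, per_token_logp=np.zeros(11 * 13 * 11),
                          latent_shape=(11, 13, 11))
    assert spatial_likelihood_map(lr, 16).shape == (176, 208, 176)
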