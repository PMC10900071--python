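"""Autoregressive likelihood of flattened code sequences.

The discrete code grid from the VQ stage is flattened in a fixed raster order
(axis 0 slowest, last axis fastest) and a causal transformer is trained to
predict each token from its predecessors, maximising the training data's
log-likelihood. Because the factorisation p(s) = prod_i p(s_i | s_<i) is
exact, the summed per-token log-probabilities give an exact log-likelihood in
nats, usable directly as an out-of-distribution score (low likelihood = OOD).

Per-token conditional log-probabilities can also be reshaped back onto the
latent grid and nearest-neighbour upsampled to image resolution, giving a
spatial map of where the model found the input surprising.

The raster order is part of the model artefact: likelihoods are
order-dependent, so it is fixed here and never configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .vq import CodeGrid

__all__ = [
    "TokenSequence", "LikelihoodResult", "TransformerConfig", "CausalTransformer",
    "flatten", "unflatten", "train_ar", "sequence_loglik", "spatial_likelihood_map",
]


@dataclass
class TokenSequence:
    """Flattened code grid: tokens in [0, vocab)."""

    tokens: np.ndarray
    latent_shape: tuple[int, ...]
    vocab: int

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.tokens.ndim != 1:
            raise ValueError("tokens must be 1D")
        if self.tokens.size != int(np.prod(self.latent_shape)):
            raise ValueError(
                f"length {self.tokens.size} != prod(latent_shape) "
                f"{int(np.prod(self.latent_shape))}")
        if self.tokens.size and (self.tokens.min() < 0 or self.tokens.max() >= self.vocab):
            raise ValueError("token outside [0, vocab)")


@dataclass
class LikelihoodResult:
    """Exact log-likelihood (nats) and its per-token decomposition."""

    total_loglik: float
    per_token_logp: np.ndarray
    latent_shape: tuple[int, ...]


def flatten(cg: CodeGrid, vocab: int | None = None) -> TokenSequence:
    """Raster-flatten a code grid (C order: axis 0 slowest, last axis fastest)."""
    idx = np.asarray(cg.indices)
    v = vocab if vocab is not None else int(idx.max()) + 1 if idx.size else 1
    return TokenSequence(tokens=idx.reshape(-1, order="C"),
                         latent_shape=tuple(cg.latent_shape), vocab=v)


def unflatten(ts: TokenSequence) -> CodeGrid:
    """Inverse of :func:`flatten`."""
    return CodeGrid(indices=ts.tokens.reshape(ts.latent_shape, order="C"),
                    latent_shape=tuple(ts.latent_shape))


@dataclass
class TransformerConfig:
    vocab: int = 32
    seq_len: int = 512
    n_layers: int = 4
    n_heads: int = 4
    d_model: int = 128
    lr: float = 5e-4
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0


class CausalTransformer(nn.Module):
    """Decoder-only transformer over vocabulary K+1 (one begin-of-sequence token).

    The BOS token is prepended so the first position has a well-defined
    conditional; logits are produced over the K real tokens only, so every
    modelled conditional normalises over the code vocabulary.
    """

    def __init__(self, cfg: TransformerConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.bos = cfg.vocab  # index of the begin-of-sequence token
        self.tok_emb = nn.Embedding(cfg.vocab + 1, cfg.d_model, rng)
        self.pos_emb = nn.Embedding(cfg.seq_len, cfg.d_model, rng)
        self.blocks = [nn.TransformerBlock(cfg.d_model, cfg.n_heads, rng)
                       for _ in range(cfg.n_layers)]
        self.ln_f = nn.LayerNorm(cfg.d_model)
        self.head = nn.Linear(cfg.d_model, cfg.vocab, rng)
        self.trained = False
        self.history: list[dict] = []

    def logits(self, tokens: np.ndarray) -> Tensor:
        """Next-token logits. tokens (B, T) in [0, vocab); output (B, T, vocab).

        Position t's logits condition on BOS and tokens < t.
        """
        tokens = np.asarray(tokens)
        B, T = tokens.shape
        if T > self.cfg.seq_len:
            raise ValueError(f"sequence length {T} exceeds model maximum "
                             f"{self.cfg.seq_len}")
        if tokens.size and tokens.max() >= self.cfg.vocab:
            raise ValueError("token id outside the model vocabulary")
        inputs = np.concatenate(
            [np.full((B, 1), self.bos, dtype=np.int64), tokens[:, :-1]], axis=1)
        x = self.tok_emb(inputs) + self.pos_emb(np.arange(T))
        for blk in self.blocks:
            x = blk(x)
        return self.head(self.ln_f(x))

    def log_probs(self, tokens: np.ndarray) -> Tensor:
        """Log of each modelled conditional p(s_i | s_<i); shape (B, T)."""
        lp = self.logits(tokens).log_softmax(axis=-1)
        return nn.gather_last(lp, np.asarray(tokens))


def train_ar(sequences: list[TokenSequence], cfg: TransformerConfig | None = None,
             verbose: bool = False) -> CausalTransformer:
    """Train the causal model by next-token cross-entropy (seeded, deterministic)."""
    if not sequences:
        raise ValueError("no training sequences")
    vocabs = {s.vocab for s in sequences}
    lengths = {s.tokens.size for s in sequences}
    if len(vocabs) != 1 or len(lengths) != 1:
        raise ValueError(f"inconsistent vocab ({vocabs}) or length ({lengths})")
    T = lengths.pop()
    if cfg is None:
        cfg = TransformerConfig(vocab=vocabs.pop(), seq_len=T)
    else:
        if cfg.vocab != next(iter(vocabs)) or cfg.seq_len != T:
            raise ValueError("config vocab/seq_len do not match the data")
    model = CausalTransformer(cfg)
    data = np.stack([s.tokens for s in sequences])
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    n = len(data)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            lp = model.log_probs(batch)
            loss = -lp.mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.history.append({"epoch": epoch, "nll_per_token": float(np.mean(losses))})
        if verbose:
            print(f"epoch {epoch}: nll/token {np.mean(losses):.4f}")
    model.trained = True
    return model


def sequence_loglik(ts: TokenSequence, model: CausalTransformer) -> LikelihoodResult:
    """Exact log-likelihood of one sequence under the trained model."""
    if ts.tokens.size != model.cfg.seq_len:
        raise ValueError(f"sequence length {ts.tokens.size} != model length "
                         f"{model.cfg.seq_len}")
    if ts.vocab > model.cfg.vocab:
        raise ValueError("sequence vocabulary exceeds the model's")
    with nn.no_grad():
        lp = model.log_probs(ts.tokens[None]).data[0]
    return LikelihoodResult(total_loglik=float(lp.sum()),
                            per_token_logp=lp.astype(np.float64),
                            latent_shape=tuple(ts.latent_shape))


def batch_logliks(sequences: list[TokenSequence], model: CausalTransformer,
                  batch_size: int = 16) -> list[LikelihoodResult]:
    """Likelihoods for many sequences, batched for speed."""
    out: list[LikelihoodResult] = []
    for start in range(0, len(sequences), batch_size):
        chunk = sequences[start:start + batch_size]
        toks = np.stack([s.tokens for s in chunk])
        with nn.no_grad():
            lp = model.log_probs(toks).data
        for s, row in zip(chunk, lp):
            out.append(LikelihoodResult(total_loglik=float(row.sum()),
                                        per_token_logp=row.astype(np.float64),
                                        latent_shape=tuple(s.latent_shape)))
    return out


def spatial_likelihood_map(lr: LikelihoodResult, upsample_factor: int) -> np.ndarray:
    """Per-token log-probabilities on the latent grid, upsampled to image space.

    Inverts the raster flattening, then nearest-neighbour upsamples by the
    integer factor along every latent axis.
    """
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    grid = np.asarray(lr.per_token_logp).reshape(lr.latent_shape, order="C")
    for axis in range(grid.ndim):
        grid = np.repeat(grid, upsample_factor, axis=axis)
    return grid
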