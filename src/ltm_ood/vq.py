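"""Vector-quantising autoencoder for 3D volumes.

A convolutional encoder downsamples the input by a factor of 2 per level and
maps each latent site to an n-vector; each vector is snapped to its nearest
codebook entry (L2), giving a grid of discrete code indices. A mirrored
decoder reconstructs the input from the quantised latents. The codebook is
learned with exponential-moving-average (EMA) re-estimation of the entries
from the latents assigned to them; encoder/decoder gradients cross the
quantisation step via the straight-through estimator.

The training loss is a weighted sum of voxel MSE, an L2 loss on the complex
Fourier transform of the reconstruction error ("spectral"), an optional
feature-space ("perceptual") term through a pluggable extractor, an optional
adversarial term from a patch discriminator, and the commitment term that
keeps encoder outputs close to their assigned codebook entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .phantoms import Volume

__all__ = [
    "Codebook", "CodeGrid", "VQConfig", "VQVAE", "PatchDiscriminator3d",
    "RandomConvFeatures", "latent_shape", "quantize", "ema_update", "vq_loss",
    "encode", "decode", "train_vqvae", "reconstruction_mse_score",
]


# ---------------------------------------------------------------------------
# codebook and code grids
# ---------------------------------------------------------------------------

@dataclass
class Codebook:
    """K learnable n-dimensional vectors plus EMA statistics."""

    entries: np.ndarray            # (K, n)
    ema_counts: np.ndarray         # (K,)
    ema_sums: np.ndarray           # (K, n)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.float32)
        if self.entries.ndim != 2 or self.entries.shape[0] < 2:
            raise ValueError("codebook needs K >= 2 entries of shape (K, n)")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("codebook entries must be finite")
        self.ema_counts = np.asarray(self.ema_counts, dtype=np.float64)
        self.ema_sums = np.asarray(self.ema_sums, dtype=np.float64)
        if np.any(self.ema_counts < 0):
            raise ValueError("ema_counts must be >= 0")

    @property
    def K(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def initialise(cls, K: int, n: int, rng: np.random.Generator,
                   samples: np.ndarray | None = None) -> "Codebook":
        """Init entries from sample latent vectors when available, else N(0, 0.1)."""
        if samples is not None and len(samples) >= K:
            idx = rng.choice(len(samples), size=K, replace=False)
            entries = np.asarray(samples[idx], dtype=np.float32)
        else:
            entries = (0.1 * rng.standard_normal((K, n))).astype(np.float32)
        return cls(entries=entries, ema_counts=np.ones(K),
                   ema_sums=entries.astype(np.float64).copy())

    @classmethod
    def from_kmeans(cls, samples: np.ndarray, K: int, rng: np.random.Generator,
                    iters: int = 15) -> "Codebook":
        """Seed the codebook with Lloyd k-means centroids of latent vectors."""
        pts = np.asarray(samples, dtype=np.float64)
        if len(pts) < K:
            raise ValueError("need at least K latent samples for k-means init")
        centres = pts[rng.choice(len(pts), size=K, replace=False)]
        for _ in range(iters):
            d2 = ((pts[:, None, :] - centres[None]) ** 2).sum(-1)
            assign = d2.argmin(1)
            for k in range(K):
                members = pts[assign == k]
                centres[k] = members.mean(0) if len(members) else \
                    pts[rng.integers(len(pts))]
        counts = np.bincount(assign, minlength=K).astype(np.float64) + 1.0
        return cls(entries=centres.astype(np.float32), ema_counts=counts,
                   ema_sums=centres * counts[:, None])


@dataclass
class CodeGrid:
    """Grid of integer codebook indices (the discrete latent representation)."""

    indices: np.ndarray
    latent_shape: tuple[int, ...]
    codebook_ref: str = ""
    source_shape: tuple[int, ...] | None = None  # pre-padding input shape

    def __post_init__(self):
        self.indices = np.asarray(self.indices)
        if tuple(self.indices.shape) != tuple(self.latent_shape):
            raise ValueError("indices shape does not match latent_shape")
        if self.indices.size and self.indices.min() < 0:
            raise ValueError("negative code index")


def latent_shape(input_shape: tuple[int, ...], levels: int) -> tuple[tuple[int, ...], int]:
    """Latent grid shape and flattened sequence length after ``levels`` stride-2 stages.

    Dimensions not divisible by 2**levels are zero-padded up to the next
    multiple before encoding, so each latent extent is ceil(dim / 2**levels).
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    f = 2 ** levels
    dims = tuple(int(-(-d // f)) for d in input_shape)
    return dims, int(np.prod(dims))


def _padded_shape(input_shape: tuple[int, ...], levels: int) -> tuple[int, ...]:
    f = 2 ** levels
    return tuple(int(-(-d // f)) * f for d in input_shape)


def quantize(latents: np.ndarray, cb: Codebook, codebook_ref: str = "") -> CodeGrid:
    """Snap each latent n-vector to its nearest codebook entry (squared L2).

    ``latents`` has shape (*grid, n). Ties break to the lowest index.
    """
    latents = np.asarray(latents)
    if latents.shape[-1] != cb.n:
        raise ValueError(f"latent dim {latents.shape[-1]} != codebook dim {cb.n}")
    grid_shape = latents.shape[:-1]
    flat = latents.reshape(-1, cb.n).astype(np.float64)
    # exact per-pair distances (argmin returns the first minimiser => lowest index)
    d2 = ((flat[:, None, :] - cb.entries[None].astype(np.float64)) ** 2).sum(axis=-1)
    idx = d2.argmin(axis=1).reshape(grid_shape)
    return CodeGrid(indices=idx, latent_shape=grid_shape, codebook_ref=codebook_ref)


def ema_update(cb: Codebook, latents: np.ndarray, assignments: np.ndarray,
               decay: float = 0.99, eps: float = 1e-5) -> Codebook:
    """EMA re-estimation of codebook entries from assigned latents.

    counts <- g*counts + (1-g)*batch_counts, sums likewise; entries are the
    Laplace-smoothed means sums / counts.
    """
    flat = np.asarray(latents).reshape(-1, cb.n).astype(np.float64)
    idx = np.asarray(assignments).reshape(-1)
    K = cb.K
    batch_counts = np.bincount(idx, minlength=K).astype(np.float64)
    batch_sums = np.zeros((K, cb.n))
    np.add.at(batch_sums, idx, flat)
    counts = decay * cb.ema_counts + (1 - decay) * batch_counts
    sums = decay * cb.ema_sums + (1 - decay) * batch_sums
    total = counts.sum()
    smoothed = (counts + eps) / (total + K * eps) * total
    entries = (sums / smoothed[:, None]).astype(np.float32)
    return Codebook(entries=entries, ema_counts=counts, ema_sums=sums)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class VQConfig:
    levels: int = 2
    K: int = 32
    n: int = 16
    base_channels: int = 4
    loss_weights: dict = field(default_factory=lambda: {
        "mse": 1.0, "spectral": 0.0, "perceptual": 0.0, "adversarial": 0.0,
        "commitment": 0.25,
    })
    ema_decay: float = 0.99
    ema_eps: float = 1e-5
    #: kernel of the convolution after the final (full-resolution) upsample;
    #: 1 = cheap channel mix (the 3x3x3 output conv still smooths), 3 = full
    #: spatial kernel (sharper reconstructions, ~2x the step cost)
    final_up_kernel: int = 1
    use_gan: bool = False
    lr: float = 3e-3
    batch_size: int = 8
    epochs: int = 10
    #: optional plain-autoencoder epochs before quantisation starts. 0 (the
    #: default) follows the plain EMA recipe: the codebook is initialised from
    #: encoder latent samples and quantisation is on from the first step.
    #: With warmup > 0 the codebook is instead seeded by k-means on the
    #: warmed-up latents — better reconstructions and code usage, but dim or
    #: rescaled inputs then tend to collapse onto one well-centred code,
    #: which blunts likelihood-based OOD detection (see docs/methods.md).
    warmup_epochs: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.levels < 0:
            raise ValueError("levels must be >= 0")
        if any(w < 0 for w in self.loss_weights.values()):
            raise ValueError("loss weights must be >= 0")


class _Encoder(nn.Module):
    def __init__(self, cfg: VQConfig, rng):
        c = cfg.base_channels
        self.conv_in = nn.Conv3d(1, c, 3, rng, padding=1)
        self.downs, self.res = [], []
        for i in range(cfg.levels):
            c_out = c * 2
            self.downs.append(nn.Conv3d(c, c_out, 4, rng, stride=2, padding=1))
            self.res.append(nn.ResidualBlock3d(c_out, 3, rng))
            c = c_out
        self.conv_out = nn.Conv3d(c, cfg.n, 1, rng)
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv_in(x).relu()
        for down, res in zip(self.downs, self.res):
            h = res(down(h).relu())
        return self.conv_out(h)


class _Decoder(nn.Module):
    def __init__(self, cfg: VQConfig, enc_channels: int, rng):
        c = enc_channels
        self.conv_in = nn.Conv3d(cfg.n, c, 1, rng)
        self.ups, self.res = [], []
        for i in range(cfg.levels):
            c_out = max(c // 2, cfg.base_channels)
            self.res.append(nn.ResidualBlock3d(c, 3, rng))
            kernel = cfg.final_up_kernel if i == cfg.levels - 1 else 3
            self.ups.append(nn.UpConv3d(c, c_out, kernel, rng))
            c = c_out
        self.conv_out = nn.Conv3d(c, 1, 3, rng, padding=1)
        # start near zero output: gentler early optimisation than Kaiming scale
        self.conv_out.w.data *= 0.1

    def forward(self, z: Tensor) -> Tensor:
        h = self.conv_in(z)
        for res, up in zip(self.res, self.ups):
            h = up(res(h)).relu()
        return self.conv_out(h)


class PatchDiscriminator3d(nn.Module):
    """Small stride-2 conv stack producing patch logits (hinge-GAN discriminator)."""

    def __init__(self, rng, base_channels: int = 4, levels: int = 2):
        c = base_channels
        self.convs = [nn.Conv3d(1, c, 4, rng, stride=2, padding=1)]
        for _ in range(levels - 1):
            self.convs.append(nn.Conv3d(c, c * 2, 4, rng, stride=2, padding=1))
            c *= 2
        self.head = nn.Conv3d(c, 1, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.head(h)


class RandomConvFeatures(nn.Module):
    """Fixed random-weight conv feature extractor.

    A synthetic stand-in for a pretrained perceptual network: random
    convolutional features still expose local structure, so an L2 distance in
    this space penalises structural mismatch differently from raw MSE.
    Weights are frozen at construction.
    """

    def __init__(self, seed: int = 0, channels: int = 8, layers: int = 2):
        rng = np.random.default_rng(seed)
        c_in, self.convs = 1, []
        for _ in range(layers):
            conv = nn.Conv3d(c_in, channels, 3, rng, stride=2, padding=1)
            conv.w.requires_grad = False
            conv.b.requires_grad = False
            self.convs.append(conv)
            c_in = channels

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        return h


class VQVAE(nn.Module):
    """Encoder + EMA codebook + decoder. Operates on (B, 1, D, H, W) arrays."""

    def __init__(self, cfg: VQConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = _Encoder(cfg, rng)
        self.decoder = _Decoder(cfg, self.encoder.out_channels, rng)
        self.codebook = Codebook.initialise(cfg.K, cfg.n, rng)
        self.history: list[dict] = []
        self.trained = False

    # -- array plumbing ----------------------------------------------------
    def _prepare(self, intensities: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        """Zero-pad a single volume up to a multiple of 2**levels, add B/C axes."""
        x = np.asarray(intensities, dtype=np.float32)
        src = x.shape
        target = _padded_shape(src, self.cfg.levels)
        pads = [(0, t - s) for s, t in zip(src, target)]
        if any(p != (0, 0) for p in pads):
            x = np.pad(x, pads)
        return x[None, None], src

    def encode_latents(self, batch: np.ndarray) -> Tensor:
        """Continuous encoder output, (B, n, d, h, w)."""
        return self.encoder(batch if isinstance(batch, Tensor) else Tensor(batch))

    def quantize_latents(self, z_e: Tensor) -> tuple[Tensor, np.ndarray]:
        """Quantise (B, n, d, h, w) latents; returns straight-through z_q and indices."""
        B, n = z_e.shape[0], z_e.shape[1]
        perm = z_e.data.transpose(0, 2, 3, 4, 1)              # (B, d, h, w, n)
        flat = perm.reshape(-1, n)
        d2 = (flat ** 2).sum(1, keepdims=True) \
            - 2.0 * flat @ self.codebook.entries.T \
            + (self.codebook.entries ** 2).sum(1)[None]
        idx = d2.argmin(axis=1).reshape(perm.shape[:-1])      # (B, d, h, w)
        zq = self.codebook.entries[idx].transpose(0, 4, 1, 2, 3)
        return nn.straight_through(z_e, zq), idx

    def decode_latents(self, z_q: Tensor) -> Tensor:
        return self.decoder(z_q)

    # -- public volume API ---------------------------------------------------
    def encode(self, v: Volume | np.ndarray) -> CodeGrid:
        intensities = v.intensities if isinstance(v, Volume) else v
        x, src = self._prepare(intensities)
        with nn.no_grad():
            z_e = self.encode_latents(x)
        perm = z_e.data[0].transpose(1, 2, 3, 0)              # (d, h, w, n)
        cg = quantize(perm, self.codebook, codebook_ref=f"vq-K{self.cfg.K}")
        cg.source_shape = src
        return cg

    def decode(self, cg: CodeGrid) -> Volume:
        zq = self.codebook.entries[cg.indices]                # (*latent, n)
        zq = zq.transpose(3, 0, 1, 2)[None]
        with nn.no_grad():
            recon = self.decode_latents(Tensor(zq)).data[0, 0]
        if cg.source_shape is not None:
            sl = tuple(slice(0, s) for s in cg.source_shape)
            recon = recon[sl]
        return Volume(intensities=recon, id=f"decoded|{cg.codebook_ref}")

    def reconstruct(self, v: Volume | np.ndarray) -> np.ndarray:
        return self.decode(self.encode(v)).intensities


def encode(v: Volume, model: VQVAE) -> CodeGrid:
    return model.encode(v)


def decode(cg: CodeGrid, model: VQVAE) -> Volume:
    return model.decode(cg)


# ---------------------------------------------------------------------------
# losses, training, scoring
# ---------------------------------------------------------------------------

def vq_loss(batch: np.ndarray, recon: Tensor, z_e: Tensor, zq_values: np.ndarray,
            cfg: VQConfig, feature_extractor=None,
            discriminator: PatchDiscriminator3d | None = None) -> dict:
    """Loss breakdown; 'total' is the loss-weight-weighted sum of the parts.

    Parts are reported unweighted: mse (voxel), spectral (Fourier L2 per
    voxel), perceptual (feature-space MSE; 0 when no extractor is set),
    commitment (mean squared latent-to-entry distance), adversarial
    (generator hinge term; 0 without a discriminator).
    """
    target = np.asarray(batch, dtype=np.float32)
    diff = recon - target
    parts: dict[str, Tensor | float] = {}
    parts["mse"] = (diff * diff).mean()
    w = cfg.loss_weights
    parts["spectral"] = (nn.spectral_l2(recon, target, axes=(2, 3, 4))
                         if w.get("spectral", 0) > 0 else Tensor(0.0))
    if feature_extractor is not None and w.get("perceptual", 0) > 0:
        f_r = feature_extractor(recon)
        f_t = feature_extractor(Tensor(target)).detach()
        pdiff = f_r - f_t
        parts["perceptual"] = (pdiff * pdiff).mean()
    else:
        parts["perceptual"] = Tensor(0.0)
    cdiff = z_e - np.asarray(zq_values, dtype=np.float32)
    parts["commitment"] = (cdiff * cdiff).mean()
    if discriminator is not None and w.get("adversarial", 0) > 0:
        parts["adversarial"] = -discriminator(recon).mean()
    else:
        parts["adversarial"] = Tensor(0.0)
    total = Tensor(0.0)
    for name, part in parts.items():
        total = total + w.get(name, 0.0) * part
    parts["total"] = total
    return parts


def train_vqvae(volumes: list[Volume], cfg: VQConfig | None = None,
                feature_extractor=None, verbose: bool = False) -> VQVAE:
    """Train a VQ autoencoder on a list of volumes (all the same shape)."""
    cfg = cfg or VQConfig()
    model = VQVAE(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    data = np.stack([np.asarray(v.intensities, dtype=np.float32) for v in volumes])
    target = _padded_shape(data.shape[1:], cfg.levels)
    pads = [(0, 0)] + [(0, t - s) for s, t in zip(data.shape[1:], target)]
    if any(p != (0, 0) for p in pads[1:]):
        data = np.pad(data, pads)
    data = data[:, None]  # (N, 1, D, H, W)

    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    disc = opt_d = None
    if cfg.use_gan and cfg.loss_weights.get("adversarial", 0) > 0:
        disc = PatchDiscriminator3d(np.random.default_rng(cfg.seed + 2))
        opt_d = nn.Adam(disc.parameters(), lr=cfg.lr)

    n = len(data)
    warmup = min(cfg.warmup_epochs, max(cfg.epochs - 1, 0))
    for epoch in range(cfg.epochs):
        if epoch == warmup:
            # quantisation starts here; codebook init from encoder latents
            with nn.no_grad():
                z0 = model.encode_latents(data[:min(n, 4 * cfg.batch_size)])
            samples = z0.data.transpose(0, 2, 3, 4, 1).reshape(-1, cfg.n)
            if warmup > 0:
                sub = samples[rng.choice(len(samples),
                                         size=min(len(samples), 2048),
                                         replace=False)]
                model.codebook = Codebook.from_kmeans(sub, cfg.K, rng)
            else:
                model.codebook = Codebook.initialise(cfg.K, cfg.n, rng,
                                                     samples=samples)
        order = rng.permutation(n)
        ep_losses: list[float] = []
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            z_e = model.encode_latents(batch)
            if epoch < warmup:
                recon = model.decode_latents(z_e)
                parts = vq_loss(batch, recon, z_e, z_e.data, cfg,
                                feature_extractor=feature_extractor,
                                discriminator=disc)
            else:
                z_q, idx = model.quantize_latents(z_e)
                recon = model.decode_latents(z_q)
                parts = vq_loss(batch, recon, z_e, z_q.data, cfg,
                                feature_extractor=feature_extractor,
                                discriminator=disc)
            opt.zero_grad()
            parts["total"].backward()
            opt.step()
            if epoch >= warmup:
                # EMA codebook update from this batch's latents
                perm = z_e.data.transpose(0, 2, 3, 4, 1)
                model.codebook = ema_update(model.codebook, perm, idx,
                                            decay=cfg.ema_decay, eps=cfg.ema_eps)
            if disc is not None:
                d_real = disc(Tensor(batch))
                d_fake = disc(Tensor(recon.data))
                d_loss = (1.0 - d_real).relu().mean() + (1.0 + d_fake).relu().mean()
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
            ep_losses.append(parts["mse"].item())
        model.history.append({"epoch": epoch, "mse": float(np.mean(ep_losses))})
        if verbose:
            print(f"epoch {epoch}: reconstruction mse {np.mean(ep_losses):.5f}")
    model.trained = True
    return model


def reconstruction_mse_score(v: Volume, model: VQVAE) -> dict:
    """Reconstruction MSE and its mean-intensity-normalised variant.

    The normalised variant divides the MSE by the image's mean intensity; it
    is None (with ``normalised_defined=False``) when the mean is zero.
    """
    recon = model.reconstruct(v)
    x = np.asarray(v.intensities, dtype=np.float64)
    mse = float(np.mean((recon.astype(np.float64) - x) ** 2))
    mean = float(x.mean())
    if mean == 0.0:
        return {"mse": mse, "normalised": None, "normalised_defined": False}
    return {"mse": mse, "normalised": mse / mean, "normalised_defined": True}
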