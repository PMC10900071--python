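"""Segmentation-uncertainty baselines: softmax, deep ensemble, MC dropout.

A small 3D U-Net segments lesions; three per-voxel certainty constructions
are provided for comparison against likelihood-based OOD filtering:

* ``softmax`` — the foreground softmax probability of a single network,
* ``ensemble_entropy`` — N independently trained networks; certainty is
  1 - H(p_bar) where p_bar is the mean class distribution across members,
* ``dropout_entropy`` — one network with dropout kept active at inference,
  aggregated over N stochastic passes the same way.

Per-lesion scores average the per-voxel certainty over each connected
component of the majority-vote binary prediction; components are labelled
true positive when at least half their voxels overlap ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor
from .nn.layers import concat_channels
from .phantoms import Volume

__all__ = [
    "SegModelConfig", "CertaintyMap", "LesionScore", "UNet3d",
    "train_segmentation", "predict_prob_stack", "voxel_certainty",
    "lesion_scores", "label_tp_fp", "fp_count",
]


@dataclass
class SegModelConfig:
    features_per_level: tuple[int, ...] = (8, 16, 32)
    dropout_p: float = 0.0
    loss: str = "dice"                      # 'dice' or 'cross_entropy'
    seed: int = 0
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 3

    def __post_init__(self):
        if not self.features_per_level:
            raise ValueError("features_per_level must be nonempty")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.loss not in ("dice", "cross_entropy"):
            raise ValueError("loss must be 'dice' or 'cross_entropy'")


@dataclass
class CertaintyMap:
    values: np.ndarray
    method: str  # 'softmax' | 'ensemble_entropy' | 'dropout_entropy'


@dataclass
class LesionScore:
    component_id: int
    voxel_set: np.ndarray          # (m, 3) coordinates
    confidence: float
    is_tp: bool | None = None


class _ConvBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng, dropout_p: float, drop_rng):
        self.conv = nn.Conv3d(c_in, c_out, 3, rng, padding=1)
        self.norm = nn.InstanceNorm3d()
        self.drop = nn.Dropout(dropout_p, drop_rng) if dropout_p > 0 else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(self.conv(x)).leaky_relu(0.1)
        return self.drop(h) if self.drop is not None else h


class UNet3d(nn.Module):
    """Small encoder-decoder with skip connections and 2-class output logits."""

    def __init__(self, cfg: SegModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.drop_rng = np.random.default_rng(cfg.seed + 10_000)
        feats = list(cfg.features_per_level)
        self.block_in = _ConvBlock(1, feats[0], rng, cfg.dropout_p, self.drop_rng)
        self.downs, self.enc_blocks = [], []
        for a, b in zip(feats[:-1], feats[1:]):
            self.downs.append(nn.Conv3d(a, b, 4, rng, stride=2, padding=1))
            self.enc_blocks.append(_ConvBlock(b, b, rng, cfg.dropout_p, self.drop_rng))
        self.ups, self.dec_blocks = [], []
        for a, b in zip(feats[:0:-1], feats[-2::-1]):
            self.ups.append(nn.UpConv3d(a, b, 3, rng))
            self.dec_blocks.append(_ConvBlock(2 * b, b, rng, cfg.dropout_p, self.drop_rng))
        self.head = nn.Conv3d(feats[0], 2, 1, rng)
        self.trained = False

    def set_mc_dropout(self, active: bool):
        def visit(m):
            if isinstance(m, nn.Dropout):
                m.force_active = active
            elif isinstance(m, nn.Module):
                for v in m.__dict__.values():
                    visit(v)
            elif isinstance(m, (list, tuple)):
                for v in m:
                    visit(v)
        visit(self)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = self.block_in(x)
        for down, block in zip(self.downs, self.enc_blocks):
            skips.append(h)
            h = block(down(h).leaky_relu(0.1))
        for up, block in zip(self.ups, self.dec_blocks):
            h = block(concat_channels(up(h), skips.pop()))
        return self.head(h)

    def predict_prob(self, v: Volume | np.ndarray) -> np.ndarray:
        """Foreground probability grid for one volume."""
        x = np.asarray(v.intensities if isinstance(v, Volume) else v,
                       dtype=np.float32)[None, None]
        with nn.no_grad():
            logits = self.forward(Tensor(x))
            probs = logits.softmax(axis=1)
        return probs.data[0, 1]


def _seg_loss(logits: Tensor, mask: np.ndarray, kind: str) -> Tensor:
    m = np.asarray(mask, dtype=np.float32)[:, None]  # (B,1,D,H,W)
    if kind == "cross_entropy":
        lp = logits.log_softmax(axis=1)
        return -(lp[:, 1:2] * m + lp[:, 0:1] * (1.0 - m)).mean()
    # soft Dice on the foreground probability
    p = logits.softmax(axis=1)[:, 1:2]
    eps = 1.0
    inter = (p * m).sum()
    return 1.0 - (2.0 * inter + eps) / (p.sum() + Tensor(m.sum()) + eps)


def train_segmentation(volumes: list[Volume], cfg: SegModelConfig | None = None,
                       verbose: bool = False) -> UNet3d:
    """Train one U-Net on volumes carrying lesion masks (AMSGrad Adam)."""
    cfg = cfg or SegModelConfig()
    for v in volumes:
        if v.lesion_mask is None:
            raise ValueError(f"volume {v.id!r} lacks a lesion_mask")
    model = UNet3d(cfg)
    data = np.stack([np.asarray(v.intensities, dtype=np.float32) for v in volumes])[:, None]
    masks = np.stack([v.lesion_mask for v in volumes]).astype(np.float32)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, amsgrad=True)
    n = len(data)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = model(Tensor(data[sel]))
            loss = _seg_loss(logits, masks[sel], cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        if verbose:
            print(f"epoch {epoch}: {cfg.loss} loss {np.mean(losses):.4f}")
    model.train(False)
    model.trained = True
    return model


def predict_prob_stack(v: Volume, models_or_passes, n_passes: int = 5,
                       mc_dropout: bool = False) -> np.ndarray:
    """N foreground-probability grids: one per ensemble member or dropout pass.

    Pass a list of models for an ensemble, or a single model with
    ``mc_dropout=True`` for N stochastic passes (dropout active at inference).
    A single model without MC dropout gives the N=1 softmax baseline.
    """
    if isinstance(models_or_passes, (list, tuple)):
        models = list(models_or_passes)
        if not models:
            raise ValueError("empty ensemble")
        if any(not m.trained for m in models):
            raise ValueError("all ensemble members must be trained")
        return np.stack([m.predict_prob(v) for m in models])
    model: UNet3d = models_or_passes
    if not model.trained:
        raise ValueError("model is not trained")
    if not mc_dropout:
        return model.predict_prob(v)[None]
    model.set_mc_dropout(True)
    try:
        stack = np.stack([model.predict_prob(v) for _ in range(n_passes)])
    finally:
        model.set_mc_dropout(False)
    return stack


def voxel_certainty(stack: np.ndarray, method: str = "ensemble_entropy") -> CertaintyMap:
    """Per-voxel certainty from a stack of N foreground-probability grids.

    For the entropy methods the N predictions are averaged into a mean class
    distribution (p_bar, 1 - p_bar) and certainty = 1 - H in nats, so full
    agreement at probability 1 gives certainty 1 and a 50/50 split gives
    1 - ln 2. For the softmax baseline the certainty is the foreground
    probability itself (N must be 1).
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim < 2:
        raise ValueError("stack must be (N, *grid)")
    if stack.min() < 0 or stack.max() > 1:
        raise ValueError("probabilities outside [0, 1]")
    if method == "softmax":
        if stack.shape[0] != 1:
            raise ValueError("softmax certainty is defined for a single network")
        return CertaintyMap(values=stack[0], method="softmax")
    if method not in ("ensemble_entropy", "dropout_entropy"):
        raise ValueError(f"unknown certainty method {method!r}")
    p = stack.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0))
    return CertaintyMap(values=1.0 - h, method=method)


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def _majority_vote(stack: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    votes = (np.asarray(stack) >= threshold).sum(axis=0)
    return votes > stack.shape[0] / 2.0


def lesion_scores(cert: CertaintyMap, stack: np.ndarray,
                  connectivity: int = 26, threshold: float = 0.5) -> list[LesionScore]:
    """Per-lesion confidence: mean certainty over each connected component.

    The binary prediction is the majority vote over the N thresholded
    probability grids; lesions are its connected components (26-neighbourhood
    by default).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    pred = _majority_vote(stack, threshold)
    labels, n = ndimage.label(pred, structure=_STRUCTURES[connectivity])
    out = []
    for comp in range(1, n + 1):
        voxels = np.argwhere(labels == comp)
        conf = float(cert.values[labels == comp].mean())
        out.append(LesionScore(component_id=comp, voxel_set=voxels, confidence=conf))
    return out


def label_tp_fp(scores: list[LesionScore], gt_mask: np.ndarray) -> list[LesionScore]:
    """Set is_tp: true iff >= 50% of the predicted component overlaps ground truth."""
    gt = np.asarray(gt_mask, dtype=bool)
    for s in scores:
        coords = tuple(s.voxel_set.T)
        overlap = gt[coords].sum() / len(s.voxel_set)
        s.is_tp = bool(overlap >= 0.5)
    return scores


def fp_count(v: Volume, models_or_passes, gt_mask: np.ndarray,
             method: str = "ensemble_entropy", n_passes: int = 5,
             mc_dropout: bool = False, connectivity: int = 26) -> int:
    """Number of false-positive lesions predicted on a volume."""
    stack = predict_prob_stack(v, models_or_passes, n_passes=n_passes,
                               mc_dropout=mc_dropout)
    cert = voxel_certainty(stack, method=method)
    scores = label_tp_fp(lesion_scores(cert, stack, connectivity=connectivity), gt_mask)
    return sum(1 for s in scores if not s.is_tp)
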