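"""Synthetic 3D head-like phantoms.

Real head-CT cohorts are rarely shareable, so every stage of this package is
exercised on seeded synthetic phantoms that reproduce the gross structure the
corruptions and models act on: a zero background, a bright ellipsoidal shell
standing in for the skull, a mid-intensity textured interior standing in for
brain tissue, and optional compact bright lesions with voxel-exact masks
(mimicking hyperdense haemorrhages). Intensities live in [0, 1], matching a
clamp-and-rescale CT preprocessing convention in which air maps to exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "Volume", "generate_phantom", "generate_cohort"]

#: axis ratios of the outer (skull) ellipsoid relative to half the grid extent
_BASE_AXIS_RATIOS = (0.8, 1.0, 0.8)
#: skull shell thickness in voxels at the default 32-cubed grid
_SHELL_THICKNESS = 2.0
#: jitter applied per seed to each semi-axis (fraction)
_AXIS_JITTER = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom family.

    Intensities are on the rescaled CT scale: the skull must be brighter than
    brain tissue, which must be brighter than the zero background.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    skull_intensity: float = 0.95
    brain_intensity: float = 0.45
    lesion_count_range: tuple[int, int] = (0, 0)
    lesion_intensity: float = 0.85
    texture_noise_sd: float = 0.04
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= 8, got {self.grid_shape}")
        if not (0.0 < self.brain_intensity < self.skull_intensity <= 1.0):
            raise ValueError(
                "intensities must satisfy 0 < brain_intensity < skull_intensity <= 1 "
                f"(got brain={self.brain_intensity}, skull={self.skull_intensity})")
        if not (0.0 < self.lesion_intensity <= 1.0):
            raise ValueError("lesion_intensity must be in (0, 1]")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid lesion_count_range {self.lesion_count_range}")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")


@dataclass
class Volume:
    """A 3D intensity grid with spacing metadata and optional masks."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None
    lesion_mask: np.ndarray | None = None
    id: str = ""

    def copy(self) -> "Volume":
        return Volume(
            intensities=self.intensities.copy(),
            spacing=self.spacing,
            brain_mask=None if self.brain_mask is None else self.brain_mask.copy(),
            lesion_mask=None if self.lesion_mask is None else self.lesion_mask.copy(),
            id=self.id,
        )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


def _ellipsoid_field(shape: tuple[int, int, int], semi_axes: np.ndarray) -> np.ndarray:
    """Normalised squared radius: <=1 inside the ellipsoid centred on the grid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    r2 = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, centre, semi_axes):
        r2 = r2 + ((g - c) / a) ** 2
    return r2


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Generate one phantom; a pure function of the spec (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)

    # outer (skull) ellipsoid: jittered semi-axes, kept off the grid boundary
    half = np.array(shape) / 2.0
    base = np.array(_BASE_AXIS_RATIOS) * (half - 1.5)
    jitter = 1.0 + _AXIS_JITTER * rng.uniform(-1.0, 1.0, size=3)
    outer = np.maximum(base * jitter, 3.0)
    inner = np.maximum(outer - _SHELL_THICKNESS, 2.0)

    r2_outer = _ellipsoid_field(shape, outer)
    r2_inner = _ellipsoid_field(shape, inner)
    skull = (r2_outer <= 1.0) & (r2_inner > 1.0)
    brain = r2_inner <= 1.0

    img = np.zeros(shape, dtype=np.float32)
    img[skull] = spec.skull_intensity

    # smooth texture inside the brain so the encoder has structure to model
    tissue = np.full(shape, spec.brain_intensity, dtype=np.float64)
    if spec.texture_noise_sd > 0:
        noise = rng.standard_normal(shape)
        tissue += spec.texture_noise_sd * ndimage.gaussian_filter(noise, sigma=1.0)
    img[brain] = np.clip(tissue, 0.0, 1.0)[brain].astype(np.float32)

    # compact bright lesions strictly inside the brain mask
    lesion_mask = np.zeros(shape, dtype=bool)
    lo, hi = spec.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    if n_lesions:
        interior = ndimage.binary_erosion(brain, iterations=2)
        coords = np.argwhere(interior)
        for _ in range(n_lesions):
            if len(coords) == 0:
                break
            centre = coords[rng.integers(len(coords))]
            radius = rng.uniform(1.5, max(2.0, min(shape) / 10.0))
            axes = radius * (1.0 + 0.3 * rng.uniform(-1, 1, size=3))
            grids = np.ogrid[tuple(slice(0, s) for s in shape)]
            r2 = np.zeros(shape, dtype=np.float64)
            for g, c, a in zip(grids, centre, axes):
                r2 = r2 + ((g - c) / max(a, 1.0)) ** 2
            blob = (r2 <= 1.0) & brain
            lesion_mask |= blob
        img[lesion_mask] = spec.lesion_intensity

    return Volume(
        intensities=img,
        spacing=spec.spacing,
        brain_mask=brain,
        lesion_mask=lesion_mask,
        id=f"phantom-{spec.seed}",
    )


def _derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-item seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: PhantomSpec, count: int, base_seed: int) -> list[Volume]:
    """Generate ``count`` phantoms with per-item seeds derived from ``base_seed``."""
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    volumes = []
    for i in range(count):
        vspec = replace(spec, seed=_derive_seed(base_seed, i))
        v = generate_phantom(vspec)
        v.id = f"phantom-{base_seed}-{i:04d}"
        volumes.append(v)
    return volumes
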