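"""Near-OOD corruption suite for 3D volumes.

Each corruption emulates a plausible real-world failure mode — acquisition
noise (zero-mean Gaussian with standard deviation ``sigma``), header errors
that mis-set the background value, orientation flips,
field-of-view truncation (chunk deletion), an upstream skull-strip that
should not have run, and global intensity rescaling. Flips are co-applied to
any masks so they stay aligned with the image; the other corruptions leave
masks untouched.

Axis convention: axis 0 = sagittal (L-R), axis 1 = coronal (A-P),
axis 2 = axial (I-S). A "sagittal" flip mirrors left-right, i.e. axis 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .phantoms import Volume

__all__ = [
    "CorruptionSpec", "CorruptedVolume", "apply_corruption", "default_suite",
    "corrupt_cohort", "FLIP_AXES",
]

log = logging.getLogger(__name__)

KINDS = ("noise", "background_value", "flip", "chunk_delete", "skull_strip",
         "intensity_scale")

FLIP_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}

#: default fraction of the axial extent removed by chunk deletion
DEFAULT_CHUNK_FRACTION = 0.2


@dataclass(frozen=True)
class CorruptionSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None  # noise only; derived from (source_id, spec) if unset

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown corruption kind {self.kind!r}")
        if self.kind == "noise" and "sigma" not in self.params:
            raise ValueError("noise corruption requires params['sigma'] "
                             "(standard deviation)")
        if self.kind == "background_value" and "value" not in self.params:
            raise ValueError("background_value corruption requires params['value']")
        if self.kind == "flip" and self.params.get("plane") not in FLIP_AXES:
            raise ValueError("flip corruption requires params['plane'] in "
                             f"{sorted(FLIP_AXES)}")
        if self.kind == "chunk_delete" and self.params.get("location") not in (
                "central", "upper"):
            raise ValueError("chunk_delete requires params['location'] in "
                             "{'central', 'upper'}")
        if self.kind == "intensity_scale" and "factor" not in self.params:
            raise ValueError("intensity_scale corruption requires params['factor']")

    @property
    def label(self) -> str:
        """Human-readable sub-class label, e.g. 'noise_sd0.1'."""
        k = self.kind
        if k == "noise":
            return f"noise_sd{self.params['sigma']:g}"
        if k == "background_value":
            return f"bg_value{self.params['value']:g}"
        if k == "flip":
            return f"flip_{self.params['plane']}"
        if k == "chunk_delete":
            return f"chunk_{self.params['location']}"
        if k == "intensity_scale":
            return f"scale{self.params['factor']:g}"
        return k


@dataclass
class CorruptedVolume:
    volume: Volume
    spec: CorruptionSpec
    source_id: str


def _derived_seed(source_id: str, spec: CorruptionSpec) -> int:
    """Stable seed < 2**31 from (source_id, corruption identity)."""
    payload = json.dumps([source_id, spec.kind, spec.params], sort_keys=True)
    digest = hashlib.blake2s(payload.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def apply_corruption(v: Volume, spec: CorruptionSpec,
                     source_id: str | None = None) -> CorruptedVolume:
    """Apply one corruption; the input volume is never modified in place."""
    if not np.all(np.isfinite(v.intensities)):
        raise ValueError("volume contains non-finite intensities")
    sid = source_id if source_id is not None else v.id
    out = v.copy()
    img = out.intensities

    if spec.kind == "noise":
        seed = spec.seed if spec.seed is not None else _derived_seed(sid, spec)
        rng = np.random.default_rng(seed)
        sd = float(spec.params["sigma"])
        # deliberately not clamped to [0,1]: clamping would censor strong noise
        out.intensities = img + rng.normal(0.0, sd, size=img.shape).astype(img.dtype)
    elif spec.kind == "background_value":
        b = float(spec.params["value"])
        out.intensities = np.where(img == 0.0, np.asarray(b, dtype=img.dtype), img)
    elif spec.kind == "flip":
        ax = FLIP_AXES[spec.params["plane"]]
        out.intensities = np.flip(img, axis=ax).copy()
        if out.brain_mask is not None:
            out.brain_mask = np.flip(out.brain_mask, axis=ax).copy()
        if out.lesion_mask is not None:
            out.lesion_mask = np.flip(out.lesion_mask, axis=ax).copy()
    elif spec.kind == "chunk_delete":
        f = float(spec.params.get("fraction", DEFAULT_CHUNK_FRACTION))
        extent = img.shape[2]
        size = int(np.floor(f * extent))
        if spec.params["location"] == "central":
            start = (extent - size) // 2
        else:  # upper: abuts the top of the axial axis
            start = extent - size
        out.intensities = img.copy()
        out.intensities[:, :, start:start + size] = 0.0
    elif spec.kind == "skull_strip":
        if v.brain_mask is None:
            raise ValueError("skull_strip requires a brain_mask on the volume")
        out.intensities = np.where(v.brain_mask, img, np.asarray(0.0, dtype=img.dtype))
    elif spec.kind == "intensity_scale":
        c = float(spec.params["factor"])
        out.intensities = img * np.asarray(c, dtype=img.dtype)
    else:  # pragma: no cover - guarded by CorruptionSpec
        raise ValueError(f"unknown corruption kind {spec.kind!r}")

    out.id = f"{sid}|{spec.label}"
    return CorruptedVolume(volume=out, spec=spec, source_id=sid)


def default_suite() -> list[CorruptionSpec]:
    """The 14 enumerated near-OOD corruption sub-classes.

    Three noise levels (sd 0.01, 0.1, 0.2), three background replacement
    values, three plane flips, two chunk deletions, one skull strip and two
    intensity scalings.
    """
    suite: list[CorruptionSpec] = []
    for sd in (0.01, 0.1, 0.2):
        suite.append(CorruptionSpec("noise", {"sigma": sd}))
    for b in (0.3, 0.6, 1.0):
        suite.append(CorruptionSpec("background_value", {"value": b}))
    for plane in ("sagittal", "coronal", "axial"):
        suite.append(CorruptionSpec("flip", {"plane": plane}))
    for loc in ("central", "upper"):
        suite.append(CorruptionSpec("chunk_delete", {"location": loc}))
    suite.append(CorruptionSpec("skull_strip"))
    for c in (0.1, 0.01):
        suite.append(CorruptionSpec("intensity_scale", {"factor": c}))
    return suite


def corrupt_cohort(cohort: list[Volume], suite: list[CorruptionSpec],
                   strict: bool = True) -> list[CorruptedVolume]:
    """Apply every corruption in ``suite`` to every volume in ``cohort``.

    With ``strict`` (default) any failing corruption aborts the batch;
    otherwise it is logged and skipped.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if not suite:
        raise ValueError("suite is empty")
    out: list[CorruptedVolume] = []
    for v in cohort:
        for spec in suite:
            try:
                out.append(apply_corruption(v, spec))
            except ValueError:
                if strict:
                    raise
                log.warning("skipping %s on %s", spec.label, v.id)
    return out
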