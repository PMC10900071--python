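"""NIfTI and manifest I/O.

Volumes and masks are written as .nii.gz with voxel spacing in the affine;
cohorts and scores travel as plain CSV manifests so downstream stages can be
run independently.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantoms import Volume
from .vq import CodeGrid

__all__ = [
    "save_volume", "load_volume", "write_cohort", "read_cohort_manifest",
    "save_code_grid", "load_code_grid", "write_scores_csv",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(v: Volume, path, mask_path=None, lesion_mask_path=None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(v.intensities, dtype=np.float32),
                             _affine(v.spacing)), str(path))
    if mask_path is not None and v.brain_mask is not None:
        nib.save(nib.Nifti1Image(v.brain_mask.astype(np.uint8), _affine(v.spacing)),
                 str(mask_path))
    if lesion_mask_path is not None and v.lesion_mask is not None:
        nib.save(nib.Nifti1Image(v.lesion_mask.astype(np.uint8), _affine(v.spacing)),
                 str(lesion_mask_path))


def load_volume(path, mask_path=None, lesion_mask_path=None, vol_id: str = "") -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    brain = lesion = None
    if mask_path is not None:
        brain = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if lesion_mask_path is not None:
        lesion = np.asarray(nib.load(str(lesion_mask_path)).dataobj) > 0
    return Volume(intensities=np.asarray(img.dataobj, dtype=np.float32),
                  spacing=spacing, brain_mask=brain, lesion_mask=lesion,
                  id=vol_id or Path(path).name.split(".")[0])


def write_cohort(volumes: list[Volume], out_dir, seeds: list[int] | None = None) -> Path:
    """Write volumes + masks and a manifest CSV (id, path, mask_path, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, v in enumerate(volumes):
        stem = v.id or f"vol-{i:04d}"
        vp = out_dir / f"{stem}.nii.gz"
        mp = out_dir / f"{stem}_brainmask.nii.gz" if v.brain_mask is not None else None
        lp = out_dir / f"{stem}_lesionmask.nii.gz" if v.lesion_mask is not None else None
        save_volume(v, vp, mask_path=mp, lesion_mask_path=lp)
        rows.append({"id": stem, "path": str(vp),
                     "mask_path": str(mp) if mp else "",
                     "lesion_mask_path": str(lp) if lp else "",
                     "seed": seeds[i] if seeds else ""})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort_manifest(manifest_path) -> list[Volume]:
    df = pd.read_csv(manifest_path, keep_default_na=False)
    vols = []
    for _, row in df.iterrows():
        vols.append(load_volume(row["path"],
                                mask_path=row["mask_path"] or None,
                                lesion_mask_path=row.get("lesion_mask_path") or None,
                                vol_id=str(row["id"])))
    return vols


def save_code_grid(cg: CodeGrid, path) -> None:
    """Integer code archive (.npz) with a JSON sidecar for the metadata."""
    path = Path(path)
    np.savez_compressed(path, indices=cg.indices.astype(np.int32))
    sidecar = {"latent_shape": list(cg.latent_shape),
               "codebook_ref": cg.codebook_ref,
               "source_shape": list(cg.source_shape) if cg.source_shape else None}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_code_grid(path) -> CodeGrid:
    path = Path(path)
    indices = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))["indices"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return CodeGrid(indices=indices, latent_shape=tuple(meta["latent_shape"]),
                    codebook_ref=meta.get("codebook_ref", ""),
                    source_shape=tuple(meta["source_shape"]) if meta.get("source_shape")
                    else None)


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)
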