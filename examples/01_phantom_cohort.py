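"""Generate a seeded cohort of synthetic head phantoms and write it as NIfTI.

Each phantom has a zero background, a bright ellipsoidal skull shell, a
textured mid-intensity brain interior, and (here) one or two bright lesions
with voxel-exact masks — the structure every later stage operates on.
"""

from ltm_ood import PhantomSpec, generate_cohort
from ltm_ood.nifti_io import write_cohort

spec = PhantomSpec(grid_shape=(32, 32, 32), lesion_count_range=(1, 2), seed=0)
cohort = generate_cohort(spec, count=8, base_seed=42)

manifest = write_cohort(cohort, "scratch/phantom_cohort")
print(f"wrote manifest: {manifest}")

for v in cohort[:3]:
    skull = (v.intensities > 0) & ~v.brain_mask
    print(f"{v.id}: intensities [{v.intensities.min():.2f}, "
          f"{v.intensities.max():.2f}], brain voxels {int(v.brain_mask.sum())}, "
          f"lesion voxels {int(v.lesion_mask.sum())}, "
          f"mean skull {v.intensities[skull].mean():.2f} "
          f"> mean brain {v.intensities[v.brain_mask].mean():.2f}")
# Intensities sit in [0, 1] like clamp-and-rescaled CT; skull is the brightest
# tissue and the background is exactly zero, which the corruptions rely on.
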