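"""Apply the 14-corruption near-OOD suite to one phantom.

Each corruption emulates a realistic pipeline failure (noise, background
value errors, flips, missing slices, unwanted skull-strip, intensity
rescaling). The printed ranges show how each one distorts the image while
the masks stay aligned.
"""

from ltm_ood import PhantomSpec, default_suite, apply_corruption, generate_phantom

v = generate_phantom(PhantomSpec(grid_shape=(32, 32, 32),
                                 lesion_count_range=(1, 1), seed=3))
print(f"source: range [{v.intensities.min():.2f}, {v.intensities.max():.2f}], "
      f"zero voxels {(v.intensities == 0).mean():.0%}")

for spec in default_suite():
    out = apply_corruption(v, spec).volume
    img = out.intensities
    print(f"{spec.label:>14}: range [{img.min():+.2f}, {img.max():.2f}], "
          f"zero voxels {(img == 0).mean():.0%}")
# Note how background_value removes all zeros, chunk deletion adds them, and
# intensity scaling compresses the whole range — each leaves a distinct
# signature for the OOD detector to find.
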