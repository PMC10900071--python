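"""Localise an anomaly with the spatial likelihood map.

The per-token conditional log-probabilities are reshaped onto the latent grid
and nearest-neighbour upsampled back to image resolution. For a volume with a
deleted central slab the map assigns clearly lower values inside the missing
region than outside, localising what made the volume improbable.
"""

import numpy as np

from ltm_ood import (CorruptionSpec, PhantomSpec, TransformerConfig, VQConfig,
                     apply_corruption, flatten, generate_cohort, sequence_loglik,
                     spatial_likelihood_map, train_ar, train_vqvae)

spec = PhantomSpec(grid_shape=(32, 32, 32), lesion_count_range=(0, 2), seed=1)
vols = generate_cohort(spec, count=60, base_seed=1)
vq = train_vqvae(vols, VQConfig(seed=1))
seqs = [flatten(vq.encode(v), vocab=32) for v in vols]
ar = train_ar(seqs, TransformerConfig(vocab=32, seq_len=512, n_layers=2,
                                      n_heads=2, d_model=64, epochs=8, seed=1))

probe = generate_cohort(spec, count=1, base_seed=55)[0]
chunked = apply_corruption(probe, CorruptionSpec(
    "chunk_delete", {"location": "central"})).volume

lr = sequence_loglik(flatten(vq.encode(chunked), vocab=32), ar)
m = spatial_likelihood_map(lr, upsample_factor=4)   # 8^3 latent -> 32^3 map
size, start = 6, 13                                  # the deleted slab (f=0.2)
inside = m[:, :, start:start + size].mean()
outside = np.concatenate([m[:, :, :start].ravel(),
                          m[:, :, start + size:].ravel()]).mean()
print(f"total log-likelihood: {lr.total_loglik:.1f} nats")
print(f"mean conditional log-probability inside deleted slab:  {inside:.2f}")
print(f"mean conditional log-probability outside deleted slab: {outside:.2f}")
# The deleted region is where the model is most surprised, so the map there
# is markedly lower — this is the overlay a reviewer would inspect.
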