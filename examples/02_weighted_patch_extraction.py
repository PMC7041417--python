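"""Build the weighted training patch inventory from one phantom case.

Shows the two patch sources: the equidistant seed grid (kept only where
more than 60% of the patch is brain) and the extra patches centred on a
random 30% of whole-tumor boundary voxels. The boundary patches oversample
exactly the interfaces a segmentation network misclassifies most.
"""

import gliounet as g
from gliounet.patch_sampler import (
    brain_fraction_filter,
    sample_boundary_patches,
    seed_grid,
    training_patch_inventory,
    wt_boundary_voxels,
)

vol, labels = g.generate_phantom(g.PhantomConfig(rng_seed=0))
mask = g.derive_brain_mask(vol)
norm = g.zscore_normalize(vol, mask)

grid = seed_grid(norm.shape, patch_size=32)
kept = brain_fraction_filter(grid, mask, threshold=0.6)
print(f"seed grid: {len(grid)} lattice patches, {len(kept)} pass the >60% brain filter")

boundary = wt_boundary_voxels(labels)
extra = sample_boundary_patches(boundary, norm.shape, fraction=0.3,
                                patch_size=32, rng_seed=0)
print(f"whole-tumor boundary: {len(boundary)} voxels; "
      f"30% draw -> {len(extra)} boundary-centred patches")

patches = training_patch_inventory(norm, labels, mask, patch_size=32,
                                   rng_seed=0, max_boundary_patches=50)
origins = [s.origin for s in patches.specs]
print(f"training inventory: {len(patches)} patches "
      f"({origins.count('grid-seed')} grid-seed, "
      f"{origins.count('boundary-weighted')} boundary-weighted, capped at 50)")
print("every patch carries 4 aligned channels plus its label block:",
      patches.images.shape, patches.labels.shape)
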