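"""Generate a synthetic glioma phantom and inspect its class imbalance.

Builds a 96^3 four-channel phantom (FLAIR, T1, T2, T1ce) with nested
necrosis / enhancing-rim / edema labels, then prints the per-class voxel
fractions. Real cohorts are dominated by non-tumor voxels (~99%); the
phantom reproduces that regime so the sampling machinery faces the same
imbalance problem.
"""

import gliounet as g

vol, labels = g.generate_phantom(g.PhantomConfig(rng_seed=0))
print(f"volume shape {vol.shape}, channels {list(vol.channels)}")

profile = g.imbalance_profile(labels)
names = {0: "background/healthy", 1: "necrosis", 2: "edema", 4: "enhancing"}
for value, frac in profile.items():
    print(f"  {names[value]:<20s} {100 * frac:6.2f}% of voxels")

regions = g.derive_regions(labels)
print(f"region sizes: ET={int(regions.ET.sum())}, TC={int(regions.TC.sum())}, "
      f"WT={int(regions.WT.sum())} voxels (ET ⊆ TC ⊆ WT)")
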