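"""Generate a labeled log phantom and inspect the HU normalization.

Builds a small synthetic spruce log (bark annulus, growth rings, two beetle
galleries, a shrinkage crack), prints its ground-truth volume budget, and
shows how Hounsfield Units map onto the unit interval used by the decay
classifier: air -> 0.0, water -> 0.4, and 1.0 corresponds to 250% of water
attenuation.
"""

from dataclasses import replace

from deadwoodct import normalize, relative_attenuation_percent, true_volume_summary
from deadwoodct.validation import BENCH_GEOMETRY
from deadwoodct.phantom import generate_phantom

spec = replace(BENCH_GEOMETRY, tunnel_count=2, crack_count=1, seed=11)
vol, labels = generate_phantom(spec)
summary = true_volume_summary(labels)

print(f"phantom grid {vol.shape}, voxel {vol.voxel_volume_mm3:.3f} mm^3")
print(f"true tunnel volume: {summary.tunnel_total_percent:.3f}% of the log")
print(f"crack voxels (not insect activity): {summary.crack_vox}")

norm = normalize(vol)
print(f"normalized range: [{norm.values.min():.3f}, {norm.values.max():.3f}]")
for v in (0.0, 0.4, 1.0):
    print(f"  normalized {v:.1f} -> {relative_attenuation_percent(v):.0f}% of water attenuation")
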