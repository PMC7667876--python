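"""Count FISH transcript spots per nuclear and cytoplasmic area.

Builds a cell scene with 45 nuclear and 5 cytoplasmic spots (the nuclear
retention pattern), outlines compartments by thresholding, counts maxima at a
noise tolerance, and compares three simulated conditions with Tukey's HSD.
"""
import numpy as np

from coldclock import fishquant, synthgen

scene = synthgen.simulate_fish_scene(n_nuclear=45, n_cyto=5, seed=1)
masks = fishquant.compartment_masks(scene["dapi"], scene["fish"])
spots = fishquant.find_maxima(scene["fish"], noise_tolerance=40)
counts = fishquant.count_by_compartment(spots, masks)

print(f"spots detected: {len(spots)} (planted: 50)")
print(f"nuclear {counts.nuclear} / cytoplasmic {counts.cytoplasmic} "
      f"(planted 45 / 5 -> nuclear retention)")
print(f"densities: {counts.nuclear_density:.4f} nuclear, "
      f"{counts.cytoplasmic_density:.4f} cytoplasmic spots per unit area")

rng = np.random.default_rng(1)
groups = {
    "37C": rng.normal(5, 1, 12),
    "18C": rng.normal(9, 1, 12),   # cold retains transcripts in the nucleus
    "rewarm": rng.normal(5.5, 1, 12),
}
print("\nTukey HSD on per-image nuclear densities across conditions:")
print(fishquant.tukey_hsd(groups).round(4).to_string(index=False))
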