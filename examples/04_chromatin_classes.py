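"""Segment a nucleus phantom into 7 density classes and place marker centroids.

Generates a 3D DAPI-like phantom with known class fractions, runs the mask +
Gaussian-mixture segmentation, and prints the chromatin:nuclear volume ratio,
the per-class enrichment of an interior marker (hnRNPC-like, placed in the
interchromatin space) and the surface-to-interior nearest-neighbour distance.
"""
import numpy as np

from coldclock import nucleome, synthgen

cfg = synthgen.NucleusPhantomConfig(
    class_fractions=(0.6, 0.1, 0.08, 0.08, 0.06, 0.05, 0.03),
    peripheral_thickening_um=0.3, seed=1,
)
dapi, truth, cents = synthgen.simulate_nucleus(cfg)

mask, volume = nucleome.nuclear_mask(dapi)
print(f"nuclear volume: {volume:.2f} um^3 (truth {truth.nuclear_volume_um3:.2f})")

cmap = nucleome.segment_classes(dapi, truth.mask, seed=0)
acc = (cmap.labels[truth.mask] == truth.labels[truth.mask]).mean()
print(f"7-class segmentation voxel accuracy: {100 * acc:.1f}%")
print(f"chromatin:nuclear ratio (classes 2-7 / 1-7): "
      f"{nucleome.chromatin_ratio(cmap):.3f} (truth 0.400)")

filtered = nucleome.quality_filter(cents["interior"], threshold=8.0)
print(f"interior centroids passing the quality threshold: "
      f"{len(filtered)}/{len(cents['interior'])}")

enr = nucleome.class_enrichment(filtered, cmap)
print("log2 enrichment per class (interior marker, + = enriched):")
print(enr.table.set_index("class")["log2_enrichment"].round(2).to_string())

d = nucleome.nearest_neighbor_distances(cents["surface"], filtered)
print(f"mean surface->interior nearest-neighbour distance: "
      f"{d.mean():.3f} um over {len(d)} surface centroids")
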