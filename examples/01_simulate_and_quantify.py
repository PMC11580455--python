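"""Simulate a field of rod cells and quantify their polar fluorescence.

Generates 40 cells whose fluorescent protein carries 35% of its signal in a
cluster at one pole and 15% at the other (a bipolar asymmetric pattern,
true omega = 0.4), renders them with camera noise, and runs the full
quantification: background estimation, per-cell medial axis and polar caps,
cluster detection (>= 3 pixels, component mean >= cytoplasmic mean + 2 SD),
pole assignment, asymmetry index and four-way classification.
"""

import polefrac as pf

spec = pf.SceneSpec(n_cells=40, image_shape=(900, 900), seed=42)
loc = pf.LocalizationSpec(pole1_fraction=0.35, pole2_fraction=0.15)
mask, image, truth = pf.generate_scene(spec, loc)

cells, skipped = pf.quantify_image(image, mask)

print(f"quantified {len(cells)} cells ({len(skipped)} excluded)")
print(cells.head(5).round(3).to_string(index=False))
print()
print("category counts (true pattern is bipolar asymmetric, omega = 0.4):")
print(cells.category.value_counts().to_string())
print()
print(f"mean omega           : {cells.omega.mean():.3f}   (truth 0.400)")
print(f"mean % at both poles : {(cells.pole1_pct + cells.pole2_pct).mean():.1f}"
      "   (truth 50.0 plus the diffuse signal under the cluster footprint)")
# pole1_pct/pole2_pct are percentages of total cell fluorescence found in
# the detected polar clusters; cytoplasmic_pct is the remainder, so the
# three always sum to 100 for every cell.
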