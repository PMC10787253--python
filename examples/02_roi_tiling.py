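"""Draw a polygon ROI and tile it with different inclusion rules.

A pentagon ROI is laid over a blank slide and covered with a 128-px tile
grid.  The counts show how the inclusion rule trades coverage against
purity: full containment keeps only tiles wholly inside the polygon,
while a 50% minimum overlap admits boundary tiles too.  Manual overrides
then force one tile in and one out, as an annotator would.
"""

import numpy as np

from histotile import (
    InclusionRule,
    SynthParams,
    apply_manual_overrides,
    create_roi,
    generate_candidate_tiles,
    generate_slide,
    polygon_area,
    select_tiles,
)

pyr, _ = generate_slide(
    SynthParams(base_size=(1024, 1024), downsamples=(1, 4),
                nuclei_density_map=np.zeros((1, 1)), seed=0)
)

roi = create_roi(
    [(100, 100), (800, 150), (900, 600), (450, 900), (120, 650)], "TUMOUR", 0
)
print(f"ROI '{roi.label}': {len(roi.vertices)} vertices, area {polygon_area(roi):,.0f} px^2")

candidates = generate_candidate_tiles(roi, side_px=128, level=0, pyr=pyr)
print(f"candidate grid: {len(candidates)} tiles of 128x128 px")

for rule in (InclusionRule("full_containment"), InclusionRule("min_overlap", 0.5)):
    kept = [t for t in select_tiles(candidates, rule) if t.included]
    name = rule.mode if rule.mode == "full_containment" else f"min_overlap {rule.min_overlap}"
    print(f"  {name}: {len(kept)} tiles included")

selected = select_tiles(candidates, InclusionRule("min_overlap", 0.5))
border = next(t for t in selected if not t.included and t.overlap_fraction > 0.1)
inner = next(t for t in selected if t.included)
edited = apply_manual_overrides(selected, add_ids=[border.tile_id], remove_ids=[inner.tile_id])
n_after = sum(t.included for t in edited)
print(f"after overrides (+1 border tile at {border.overlap_fraction:.2f} overlap, -1 inner): "
      f"{n_after} tiles included")
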