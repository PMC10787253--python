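"""Generate a synthetic H&E-like slide pyramid and read it back.

Builds a 1024x1024 three-level slide with 40% nuclei coverage, writes it
as a pyramidal TIFF, reopens it, and reads the same physical region at
two levels.  The printed downsamples/dimensions show the pyramid
structure; the per-level reads show how a level-0 origin plus a
level-local size address the same tissue at different resolutions.
"""

import numpy as np

from histotile import (
    SynthParams,
    generate_slide,
    level_for_magnification,
    open_slide,
    pixels_to_microns,
    read_region,
    write_pyramidal_tiff,
)

params = SynthParams(
    base_size=(1024, 1024),
    downsamples=(1, 4, 16),
    mpp=0.25,
    objective_power=40,
    nuclei_density_map=np.full((2, 2), 0.4),
    seed=11,
)
pyr, gt = generate_slide(params)
print(f"generated slide '{pyr.slide_id}': {pyr.n_levels} levels")
for k, (dims, ds) in enumerate(zip(pyr.level_dims, pyr.downsamples)):
    print(f"  level {k}: {dims[0]}x{dims[1]} px, downsample {ds:g}")
print(f"true nuclei coverage: {gt.nuclei_mask.mean():.3f} (target 0.40)")

path = "scratch_example_slide.tiff"
write_pyramidal_tiff(pyr, path)
reopened = open_slide(path)
print(f"reopened from TIFF: mpp={reopened.mpp_x} um/px, objective={reopened.objective_power}x")

# the same 512x512 um^2 region at full resolution and at 10x
level_10x = level_for_magnification(reopened, 10)
full = read_region(reopened, 0, (256, 256), (512, 512))
low = read_region(reopened, level_10x, (256, 256), (128, 128))
print(f"40x read: {full.width}x{full.height} px; 10x read (level {level_10x}): {low.width}x{low.height} px")
print(f"512 px at level 0 = {pixels_to_microns(reopened, 512, 0):g} um of tissue")
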