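"""Generate ground-truthed FLAIR and SWI phantoms and inspect them.

The structural phantom carries a hyperintense lesion six parenchyma-SDs
above the mean; the SWI phantom carries a fan of tubular veins with a
negative phase dip plus a smooth polynomial background field.
"""

import numpy as np

from mvq import (
    default_structural_spec,
    default_swi_spec,
    generate_structural_phantom,
    generate_swi_phantom,
)

structural = generate_structural_phantom(default_structural_spec(seed=0))
print("FLAIR phantom:", structural.flair.shape, "voxels at",
      structural.flair.spacing, "mm")
print(f"  brain parenchyma: {int(structural.brain_mask.sum())} voxels")
print(f"  lesion truth:     {int(structural.wmh_truth.sum())} voxels "
      f"({structural.wmh_truth.sum() * np.prod(structural.flair.spacing) / 1000:.2f} ml)")

swi = generate_swi_phantom(default_swi_spec(seed=0))
phase = np.angle(swi.gre.data)
print("SWI phantom:", swi.gre.shape, "voxels at", swi.gre.spacing, "mm")
print(f"  vein truth:       {int(swi.vein_truth.sum())} voxels")
print(f"  phase range:      [{phase.min():.2f}, {phase.max():.2f}] rad (wrapped)")
print(f"  midline plane x = {swi.midline_x}, basal-ganglia top slice = "
      f"{swi.basal_ganglia_top_slice}")
# The truth masks are what the segmentation stages are scored against:
# every downstream recovery number in this package is relative to them.
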