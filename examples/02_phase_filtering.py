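"""Homodyne high-pass filtering of SWI phase.

A 32 x 32 central spectral block defines the low-pass reference per axial
slice; the corrected phase removes the smooth background field while
keeping the focal negative dips of veins.
"""

import numpy as np

from mvq import PhantomSpec, VeinSpec, generate_swi_phantom, homodyne_highpass_filter

spec = PhantomSpec(
    shape=(128, 128, 6), spacing=(0.4688, 0.4688, 2.0),
    brain_radii_mm=(14.0, 14.0, 14.0), intracranial_margin_mm=1.0,
    ventricle_radii_mm=(2.0, 5.0, 5.0), ventricle_offset_mm=4.0,
    background_coeffs={(1, 0, 0): 0.8, (2, 0, 0): 0.6, (0, 2, 0): 0.4},
    veins=(VeinSpec(((-6.0, 10.0, 1.0), (6.0, 10.0, 1.0)), 0.5, 0.6),),
    seed=0,
)
bundle = generate_swi_phantom(spec)
fphase = homodyne_highpass_filter(bundle.gre, central_matrix=32)

raw = np.angle(bundle.gre.data)
brain = bundle.brain_mask
rms_before = np.sqrt((raw[brain] ** 2).mean())
rms_after = np.sqrt((fphase.data[brain] ** 2).mean())
print(f"brain phase RMS: {rms_before:.3f} rad before, {rms_after:.3f} rad after")
print(f"  -> {100 * (1 - rms_after / rms_before):.1f}% of the background field removed")
dip = fphase.data[bundle.vein_truth].min()
print(f"vein dip after filtering: {dip:.3f} rad (injected -0.600 rad)")
print(f"  -> {100 * -dip / 0.6:.0f}% of the vein contrast survives, so the "
      "2-SD-below-the-mean vein threshold still catches it")
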