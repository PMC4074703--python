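import numpy as np
import pytest

from mvq.phantom import (
    default_structural_spec,
    default_swi_spec,
    generate_structural_phantom,
    generate_swi_phantom,
)
from mvq.phase import homodyne_highpass_filter
from mvq.volumetrics import select_periventricular_slab


@pytest.fixture(scope="session")
def structural_bundle():
    return generate_structural_phantom(default_structural_spec(seed=42))


@pytest.fixture(scope="session")
def swi_bundle():
    return generate_swi_phantom(default_swi_spec(seed=42))


@pytest.fixture(scope="session")
def filtered_phase(swi_bundle):
    return homodyne_highpass_filter(swi_bundle.gre)


@pytest.fixture(scope="session")
def slab_mask(swi_bundle):
    slab = select_periventricular_slab(
        swi_bundle.ventricle_mask, swi_bundle.basal_ganglia_top_slice
    )
    mask = np.zeros_like(swi_bundle.brain_mask)
    mask[:, :, list(slab)] = swi_bundle.brain_mask[:, :, list(slab)]
    return mask
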