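import numpy as np
import pytest

from callusqct import (
    CallusCompartmentSpec,
    PhantomSpec,
    estimate_bone_axis,
    generate_phantom,
    segment,
)


def small_spec(**overrides) -> PhantomSpec:
    """Desk-scale phantom: 30 mm shaft segment at 0.3 mm pitch (~0.45 Mvox)."""
    kwargs = dict(
        shaft_outer_diameter=10.0,
        shaft_inner_diameter=6.0,
        shaft_length=30.0,
        voxel_pitch=0.3,
        lateral_margin=5.0,
        callus_compartments=[
            CallusCompartmentSpec("cis", 0.4, 720.0, 10.0),
            CallusCompartmentSpec("trans", 0.6, 715.0, 10.0),
        ],
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = small_spec()
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noiseless_masks(noiseless_phantom):
    _, vol, _ = noiseless_phantom
    return segment(vol)


@pytest.fixture(scope="session")
def bone_axis(noiseless_masks):
    return estimate_bone_axis(noiseless_masks)
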