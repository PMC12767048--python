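import numpy as np
import pytest
from scipy import ndimage

from vasculomap import (
    BinaryMask,
    PhantomScene,
    VesselSpec,
    make_region_set,
    make_scene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(48, 48), sigma=3.0, pixel_size_um=2.0) -> BinaryMask:
    """Random smooth blob mask: thresholded filtered noise."""
    field = ndimage.gaussian_filter(rng.random(shape), sigma)
    thr = np.quantile(field, rng.uniform(0.4, 0.8))
    return BinaryMask(values=field > thr, pixel_size_um=pixel_size_um)


def horizontal_vessel(
    row_um=101.0, x0_um=40.0, x1_um=460.0, width_um=30.0, velocity=20.0,
    direction="descending",
) -> VesselSpec:
    """Horizontal vessel; the default centerline sits on a pixel-center row
    (odd µm at 2 µm/pixel) so odd pixel widths rasterize exactly."""
    return VesselSpec(
        endpoints=((row_um, x0_um), (row_um, x1_um)),
        width_um=width_um,
        velocity_mm_s=velocity,
        axial_direction=direction,
    )


@pytest.fixture
def simple_scene() -> PhantomScene:
    """One 30 µm wide horizontal vessel at 20 mm/s on a 256x256 grid."""
    return make_scene([horizontal_vessel()], (256, 256), pixel_size_um=2.0)


@pytest.fixture
def band_regions():
    return make_region_set((300, 300), pixel_size_um=2.0)
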