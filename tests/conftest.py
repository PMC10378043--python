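import numpy as np
import pytest

from ventrimetry.core_io import LabelVolume, VolumeGrid, load_reference_table
from ventrimetry.phantom import PhantomSpec, make_phantom

#: compact geometry used by most unit tests; widths must stay modest to fit
SMALL = dict(shape=(96, 96, 48), dgm_slice=24)


@pytest.fixture(scope="session")
def small_phantom():
    """Default-anatomy phantom on a compact grid (plexus + CSP present)."""
    spec = PhantomSpec(**SMALL, right_width_mm=7.0, left_width_mm=7.0, seed=11)
    return spec, *make_phantom(spec)


@pytest.fixture(scope="session")
def asymmetric_phantom():
    """Rotated, asymmetric phantom: right 12 mm, left 8 mm at 30 degrees."""
    spec = PhantomSpec(**SMALL, right_width_mm=12.0, left_width_mm=8.0,
                       in_plane_rotation_deg=30.0, seed=21)
    return spec, *make_phantom(spec)


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


def label_volume_from(labels, spacing=(0.5, 0.5, 0.5), orientation="RAS"):
    return LabelVolume(np.asarray(labels), spacing, orientation)


def uniform_intensity_like(mask2d, value=100.0, spacing=(0.5, 0.5, 0.5)):
    """A one-slice intensity volume matching a 2D mask's grid."""
    data = np.full(mask2d.shape + (1,), float(value), dtype=np.float32)
    return VolumeGrid(data, spacing, "RAS")
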