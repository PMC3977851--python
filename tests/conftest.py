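import pytest

from wbdwi.phantom import Lesion, PhantomSpec
from wbdwi.volumes_io import VoxelGeometry


@pytest.fixture
def geometry():
    return VoxelGeometry(spacing_mm=(4.0, 4.0, 6.0), phase_encode_axis="row")


@pytest.fixture
def noiseless_single_lesion_spec():
    """Small two-station phantom, one centered ellipsoid, no noise, no corruption."""
    spec = PhantomSpec(
        station_shape=(16, 64, 64),
        n_stations=2,
        snr_low=0.0,
        snr_high=0.0,
        seed=0,
    )
    ez, ey, ex = spec.extent_mm
    spec.lesions = [
        Lesion(center_mm=(0.35 * ez, 0.5 * ey, 0.5 * ex), semi_axes_mm=(20.0, 15.0, 15.0))
    ]
    return spec
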