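import numpy as np
import pytest

from visor.geometry import AcquisitionGeometry
from visor.phantom import (NoiseSpec, PhantomSpec, CellSpec, render_phantom,
                           soma_field_preset)


@pytest.fixture(scope="session")
def default_geometry():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def unit_pixel_geometry():
    """Geometry with exactly 0.5 µm pixels and 5 µm frame step at 45°."""
    return AcquisitionGeometry(objective_mag=10.0, tube_focal_mm=180.0,
                               camera_pixel_um=5.0, scan_rate_hz=200.0,
                               stage_speed_um_s=1000.0, frame_shape=(60, 80))


@pytest.fixture(scope="session")
def single_soma_phantom():
    spec = PhantomSpec(volume_shape_um=(80.0, 80.0, 60.0),
                       spacing_um=(1.0, 1.0, 2.0),
                       cells=[CellSpec((40.0, 36.0, 30.0), (6.0,) * 3, 2000.0)],
                       background_level=100.0,
                       noise=NoiseSpec(poisson=False, read_sigma=0.0))
    vols, gt = render_phantom(spec)
    return spec, vols, gt


@pytest.fixture(scope="session")
def soma_field():
    """200-cell noiseless soma field (seed 0) with ground truth."""
    spec = soma_field_preset(n_cells=200, seed=0)
    vols, gt = render_phantom(spec)
    return spec, vols, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
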