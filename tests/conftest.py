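import numpy as np
import pytest

from nigrastar.phantom import Box, EchoTrain, PhantomSpec, RoiSpec


@pytest.fixture(scope="session")
def echoes() -> EchoTrain:
    return EchoTrain.default()


@pytest.fixture(scope="session")
def te_ms(echoes) -> np.ndarray:
    return np.asarray(echoes.echo_times)


def single_roi_spec(n_voxels_box=(25, 20, 10), mean=30.4, sd=0.0, s0=1000.0):
    """One-box phantom spec with a 2-voxel air margin around the ROI."""
    size = tuple(n_voxels_box)
    grid = tuple(s + 4 for s in size)
    roi = RoiSpec(label=1, name="SN", geometry=Box((2, 2, 2), size),
                  r2star_mean=mean, r2star_sd=sd, s0_mean=s0)
    return PhantomSpec(grid_shape=grid, rois=(roi,))


@pytest.fixture()
def cube_spec():
    return single_roi_spec((10, 10, 10), mean=34.9, sd=0.0)
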