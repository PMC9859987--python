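import numpy as np
import pytest

from seridose import DifferentialDVH, DoseGrid, SerialityParams, StructureMask
from seridose.seriality import load_default_params


@pytest.fixture(scope="session")
def organ_params() -> dict[str, SerialityParams]:
    return load_default_params()


@pytest.fixture(scope="session")
def bladder(organ_params) -> SerialityParams:
    return organ_params["bladder"]


@pytest.fixture(scope="session")
def rectum(organ_params) -> SerialityParams:
    return organ_params["rectum"]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_ddvh(doses, frac_volumes, organ_volume_cc=100.0) -> DifferentialDVH:
    return DifferentialDVH(
        bin_dose=np.asarray(doses, dtype=float),
        frac_volume=np.asarray(frac_volumes, dtype=float),
        organ_volume_cc=organ_volume_cc,
    )


def random_smooth_grid(rng, shape=(12, 12, 12), spacing=(3.0, 3.0, 3.0), dmax=72.0) -> DoseGrid:
    """Smooth non-negative dose field with values well away from bin edges."""
    from scipy import ndimage

    vals = ndimage.gaussian_filter(rng.random(shape), sigma=1.5)
    vals = vals - vals.min()
    vals = dmax * vals / vals.max()
    return DoseGrid(vals, spacing)


@pytest.fixture
def small_grid_and_mask(rng):
    grid = random_smooth_grid(rng)
    mask_vals = np.zeros(grid.shape, dtype=bool)
    mask_vals[3:9, 3:9, 3:9] = True
    mask = StructureMask(mask_vals, "organ", grid.spacing)
    return grid, mask
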