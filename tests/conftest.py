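import numpy as np
import pytest

import hydrofractal as hf


@pytest.fixture(scope="session")
def water_spectrum():
    """Noise-free single-Debye pure-water spectrum, 100 MHz - 65 GHz."""
    return hf.synthesize_spectrum(hf.debye_water_model(), 1e8, 6.5e10, 100, 0.0)


@pytest.fixture(scope="session")
def line_image():
    """512x512 binary image with a solid 2-pixel line through the centre."""
    return hf.make_box_model("line", 512, 2)


@pytest.fixture(scope="session")
def chain_grid():
    """Voxelised chain of 100 spheres, spacing 1.5, radius 20, voxel 0.5."""
    return hf.make_sphere_chain(hf.SphereChainSpec(100, 1.5, 20.0, 0.5))


@pytest.fixture(scope="session")
def chain_counts(chain_grid):
    return hf.box_count(chain_grid)


@pytest.fixture(scope="session")
def blob_image():
    """Sparse random disks: small holes everywhere, every coarse box hit.

    Emulates a binarised fibrous-tissue micrograph: at large box sizes
    every box contains foreground (slope 2), at small sizes the white
    gaps lower the apparent dimension.
    """
    rng = np.random.default_rng(7)
    size = 512
    yy, xx = np.mgrid[0:size, 0:size]
    occ = np.zeros((size, size), dtype=bool)
    for _ in range(300):
        cy, cx = rng.integers(0, size, 2)
        r = rng.integers(4, 14)
        occ |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return hf.BinaryImage2D(occupancy=occ)


def brute_force_box_count(occ: np.ndarray, size: int) -> int:
    """Independent oracle: explicit loop over all boxes of one size."""
    shape = occ.shape
    count = 0
    if occ.ndim == 2:
        for i0 in range(0, shape[0], size):
            for i1 in range(0, shape[1], size):
                if occ[i0 : i0 + size, i1 : i1 + size].any():
                    count += 1
    else:
        for i0 in range(0, shape[0], size):
            for i1 in range(0, shape[1], size):
                for i2 in range(0, shape[2], size):
                    if occ[i0 : i0 + size, i1 : i1 + size, i2 : i2 + size].any():
                        count += 1
    return count
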