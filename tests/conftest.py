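import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from aneuhemo.fields import LabeledImageVolume
from aneuhemo.synthetic import make_sphere_surface, make_tet_ball


@pytest.fixture(scope="session")
def small_sphere():
    return make_sphere_surface(1.0, subdivisions=2)


@pytest.fixture(scope="session")
def fine_sphere():
    return make_sphere_surface(1.0, subdivisions=4)


@pytest.fixture(scope="session")
def coarse_ball():
    return make_tet_ball(1.0, target_edge=0.25)


@pytest.fixture(scope="session")
def medium_ball():
    return make_tet_ball(1.0, target_edge=0.125)


@pytest.fixture(scope="session")
def fine_ball():
    """~65k-cell ball resolving sigma >= 0.15 blobs (edge ~ sigma/2)."""
    return make_tet_ball(1.0, target_edge=0.075)


@pytest.fixture(scope="session")
def blob_pair_summary(fine_ball):
    """Two static blobs 8 sigma apart, analyzed with a speckle-proof filter."""
    from aneuhemo.synthetic import VortexBlob, make_vortex_velocity_series
    from aneuhemo.vortex import analyze_vortex_series

    blobs = [
        VortexBlob(center=[0.6, 0.0, 0.0], sigma=0.15, omega=8.0),
        VortexBlob(center=[-0.6, 0.0, 0.0], sigma=0.15, omega=8.0),
    ]
    field, truth = make_vortex_velocity_series(fine_ball, blobs, phases=4)
    # threshold at 1e-3 * omega^2: far below the core plateau (~omega^2),
    # far above interpolation-roundoff speckle (~1e-7 * omega^2)
    return analyze_vortex_series(field, threshold=1e-3 * 64.0, min_cells=32), truth


@pytest.fixture(scope="session")
def blob_single_summary(fine_ball):
    from aneuhemo.synthetic import VortexBlob, make_vortex_velocity_series
    from aneuhemo.vortex import analyze_vortex_series

    blob = VortexBlob(center=[0.0, 0.0, 0.0], sigma=0.2, omega=6.0)
    field, _ = make_vortex_velocity_series(fine_ball, [blob], phases=4)
    return analyze_vortex_series(field, threshold=1e-3 * 36.0, min_cells=32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_roi_image(rng, shape=(6, 5, 4), n_values=6, spacing=(1.0, 1.0, 1.0)):
    """Small random integer-valued image with a random non-trivial mask."""
    voxels = rng.integers(0, n_values, size=shape).astype(float)
    mask = rng.random(shape) < 0.7
    mask.flat[rng.integers(0, mask.size)] = True  # never empty
    return LabeledImageVolume(voxels, spacing, {"roi": mask})
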