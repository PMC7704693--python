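import numpy as np
import pytest

from kwia.geometry import ProjectionGeometry, forward_project_parallel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture(scope="session")
def small_parallel_geometry():
    """A modest parallel geometry: 144 detectors at 1 mm, 160 views over 180deg."""
    return ProjectionGeometry("parallel", 144, 1.0, 320)


def make_disk(n=128, radius_mm=40.0, mu=0.02, pixel_spacing=1.0, soft_edge=False):
    """Centered uniform disk attenuation map (optionally smoothed edge)."""
    c = (n - 1) / 2.0
    y, x = np.mgrid[:n, :n]
    r = np.sqrt(((x - c) ** 2 + (y - c) ** 2)) * pixel_spacing
    if soft_edge:
        img = mu / (1.0 + np.exp((r - radius_mm) / (0.75 * pixel_spacing)))
    else:
        img = np.where(r <= radius_mm, mu, 0.0)
    return img


@pytest.fixture(scope="session")
def disk_image():
    return make_disk()


@pytest.fixture(scope="session")
def disk_sinogram(disk_image, small_parallel_geometry):
    return forward_project_parallel(disk_image, 1.0, small_parallel_geometry)


@pytest.fixture(scope="session")
def study_geometry():
    """The full acquisition geometry of the shipped phantom studies."""
    return ProjectionGeometry("parallel", 728, 0.75, 1152)


@pytest.fixture(scope="session")
def study_disk(study_geometry):
    """40 mm disk and its sinogram at the full study geometry."""
    img = make_disk(n=256, radius_mm=40.0, mu=0.02, pixel_spacing=0.75)
    sino = forward_project_parallel(img, 0.75, study_geometry)
    return img, sino
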