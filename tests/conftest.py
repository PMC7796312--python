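import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colorfaf.imaging_io import FundusImage, ImageMetadata

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_uniform_image(
    r: int,
    g: int,
    b: int = 0,
    shape: tuple[int, int] = (61, 61),
    um_per_pixel: float = 100.0,
    laterality: str = "OD",
    eye_id: str = "test",
) -> FundusImage:
    """A constant-channel fundus image with the fovea at the raster center."""
    px = np.zeros((*shape, 3), dtype=np.uint8)
    px[:, :, 0] = r
    px[:, :, 1] = g
    px[:, :, 2] = b
    meta = ImageMetadata(
        eye_id=eye_id,
        fovea_center=((shape[0] - 1) / 2, (shape[1] - 1) / 2),
        um_per_pixel=um_per_pixel,
        laterality=laterality,
        disc_side="right" if laterality == "OD" else "left",
    )
    return FundusImage(pixels=px, metadata=meta)


@pytest.fixture
def uniform_image():
    """Foveal-values image: R=26, G=17 everywhere, 61x61 px at 100 µm/px."""
    return make_uniform_image(26, 17)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
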