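import numpy as np
import pytest

from petalmorph.segmentation import BinaryMask, Contour, RasterImage
from petalmorph.synthetic_fixtures import PetalSpec, make_petal_polygon, rasterize


def disc_mask(radius_px: int, pixel_size_cm: float = 0.01) -> BinaryMask:
    """Digital disc: pixel centers strictly inside the circle."""
    n = 2 * radius_px + 10
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    inside = (yy + 0.5 - c) ** 2 + (xx + 0.5 - c) ** 2 < radius_px**2
    return BinaryMask(inside, pixel_size_cm)


def disc_image(radius_px: int, red: int = 200, bg: int = 10,
               dpi: float = 254.0) -> tuple[RasterImage, np.ndarray]:
    mask = disc_mask(radius_px)
    img = np.full(mask.pixels.shape + (3,), bg, dtype=np.uint8)
    img[..., 0][mask.pixels] = red
    return RasterImage(img, dpi=dpi), mask.pixels


def square_contour(side: float = 1.0) -> Contour:
    return Contour(np.array([[0, 0], [side, 0], [side, side], [0, side]], float))


@pytest.fixture(scope="session")
def default_petal():
    """One smooth petal polygon with its exact ground-truth record."""
    return make_petal_polygon(PetalSpec())


@pytest.fixture(scope="session")
def serrated_petal():
    return make_petal_polygon(PetalSpec(serration_amplitude=0.2, serration_count=8))


@pytest.fixture(scope="session")
def rasterized_petal(default_petal):
    poly, truth = default_petal
    img, mask = rasterize(poly, dpi=170)
    return img, mask, truth
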