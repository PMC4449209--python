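"""Shared fixtures: small phantom stacks and slide-like test rasters."""

import math

import numpy as np
import pytest
from scipy import ndimage

import histo3d as h3
from histo3d.image import SectionImage


@pytest.fixture(scope="session")
def small_phantom():
    """A small 3-section phantom with moderate rigid jitter (shared across
    tests; treat as read-only)."""
    spec = h3.PhantomSpec(
        n_sections=3,
        extents_um=(800.0, 800.0),
        max_translation_um=30.0,
        max_rotation_deg=3.0,
        seed=5,
    )
    stack, gt = h3.generate_phantom(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def unperturbed_phantom():
    # footprint large enough that each pair yields well over 100 matches, so
    # the best-100 cut can reject the spurious matches of unpaired nuclei
    spec = h3.PhantomSpec(
        n_sections=3,
        extents_um=(1200.0, 1200.0),
        max_translation_um=0.0,
        max_rotation_deg=0.0,
        seed=9,
    )
    stack, gt = h3.generate_phantom(spec)
    return spec, stack, gt


def make_slide_raster(n: int = 200, spacing: float = 1.0) -> SectionImage:
    """A slide-like grayscale test image: asymmetric dark blobs on a white
    background, mildly smoothed so MSE landscapes are well-behaved."""
    img = np.full((n, n), 255.0)
    yy, xx = np.mgrid[0:n, 0:n]
    scale = n / 200.0
    for (cy, cx, r, v) in [
        (70, 80, 30, 140),
        (120, 130, 22, 170),
        (60, 140, 12, 120),
        (140, 70, 16, 190),
        (100, 100, 45, 225),
    ]:
        cy, cx, r = cy * scale, cx * scale, r * scale
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img = np.where(d2 < r * r, np.minimum(img, v + 20 * np.exp(-d2 / (r * r))), img)
    img = ndimage.gaussian_filter(img, 2)
    return SectionImage(np.stack([img] * 3, -1).astype(np.uint8), spacing=spacing)


@pytest.fixture()
def slide_raster():
    return make_slide_raster()


def rigid(theta_deg=0.0, tx=0.0, ty=0.0, center=None):
    return h3.AffineTransform2D.from_rotation(
        math.radians(theta_deg), center=center, translation=(tx, ty)
    )


def random_affine(rng, max_dev=0.2, max_t=20.0):
    m = np.eye(2) + rng.uniform(-max_dev, max_dev, (2, 2))
    t = rng.uniform(-max_t, max_t, 2)
    return h3.AffineTransform2D(m, t)
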