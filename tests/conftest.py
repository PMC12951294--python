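"""Shared fixtures: small geometries and smooth phantoms used across tests."""

import numpy as np
import pytest

from patdiff.fbp import ReconGrid
from patdiff.geometry import RingGeometry
from patdiff.image import PressureImage


@pytest.fixture(scope="session")
def small_ring() -> RingGeometry:
    """128-element full ring, otherwise the reference acquisition values."""
    return RingGeometry(n_elements=128)


@pytest.fixture(scope="session")
def small_grid() -> ReconGrid:
    return ReconGrid((64, 64), 64 * 0.3)


def gaussian_blob(shape=(64, 64), spacing_mm=0.3, center_mm=(0.0, 0.0),
                  sigma_mm=2.0, amplitude=200.0) -> PressureImage:
    """Smooth rotationally symmetric blob; analytic, no rasterization noise."""
    img = PressureImage(np.zeros(shape), spacing_mm)
    X, Y = img.pixel_coordinates()
    r2 = (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2
    img.pixels = amplitude * np.exp(-r2 / (2.0 * sigma_mm**2))
    return img


@pytest.fixture(scope="session")
def centered_blob() -> PressureImage:
    return gaussian_blob()
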