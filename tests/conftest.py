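"""Shared fixtures: small deterministic phantoms and geometries."""

import numpy as np
import pytest

from difftomo.core import ImagingGeometry, RefractiveIndexMap


@pytest.fixture(scope="session")
def geom4():
    """Water-immersion geometry, wavelength 4 px, refocused (l_D = 0)."""
    return ImagingGeometry(wavelength=4.0, medium_index=1.333)


def weak_disk(grid_size: int, radius_px: float, delta_n: float = 1e-3,
              geometry: ImagingGeometry | None = None) -> RefractiveIndexMap:
    """Centered homogeneous disk of RI contrast ``delta_n`` over water."""
    geom = geometry or ImagingGeometry(wavelength=4.0, medium_index=1.333)
    c = grid_size // 2
    z, x = np.meshgrid(*[np.arange(grid_size) - c] * 2, indexing="ij")
    n = np.full((grid_size, grid_size), geom.medium_index)
    n[z ** 2 + x ** 2 <= radius_px ** 2] += delta_n
    return RefractiveIndexMap(n=n, geometry=geom)


def weak_ball(grid_size: int, radius_px: float, delta_n: float = 1e-3,
              geometry: ImagingGeometry | None = None) -> RefractiveIndexMap:
    """Centered homogeneous sphere of RI contrast ``delta_n`` over water."""
    geom = geometry or ImagingGeometry(wavelength=4.0, medium_index=1.333)
    c = grid_size // 2
    z, y, x = np.meshgrid(*[np.arange(grid_size) - c] * 3, indexing="ij")
    n = np.full((grid_size,) * 3, geom.medium_index)
    n[z ** 2 + y ** 2 + x ** 2 <= radius_px ** 2] += delta_n
    return RefractiveIndexMap(n=n, geometry=geom)
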