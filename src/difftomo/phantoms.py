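"""Three-compartment cell phantoms for diffraction-tomography benchmarks.

The phantom emulates a single suspended cell: a cytoplasm sphere (disk in
2D) containing an off-center ellipsoidal nucleus which in turn contains a
small spherical nucleolus.  Compartment refractive indices default to
literature values for biological cells in aqueous medium:
medium 1.333, cytoplasm 1.365, nucleus 1.360, nucleolus 1.387, with a
cell diameter of 17 wavelengths.

Geometry is specified in wavelength units and rasterized onto a unit-pixel
grid; a voxel takes the refractive index of the innermost compartment that
contains its center (piecewise-constant ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .core import ImagingGeometry, RefractiveIndexMap, WATER_RI

__all__ = ["PhantomSpec", "make_cell_phantom_2d", "make_cell_phantom_3d",
           "ri_series"]


@dataclass(frozen=True)
class PhantomSpec:
    """Compartment geometry (in wavelength units) and refractive indices.

    Vector parameters are stored in (x, y, z) order; the 2D phantom lives
    in the (x, z) plane and uses those two components.
    """

    diameter: float = 17.0                 # 2a, cytoplasm diameter [lambda]
    n_medium: float = WATER_RI
    n_cytoplasm: float = 1.365
    n_nucleus: float = 1.360
    n_nucleolus: float = 1.387
    # nucleus ellipse/ellipsoid, relative to the cell radius a
    nucleus_semiaxes: Tuple[float, float, float] = (0.6, 0.5, 0.5)   # (x,y,z)/a
    nucleus_offset: Tuple[float, float, float] = (-0.1, 0.0, 0.08)   # (x,y,z)/a
    # nucleolus sphere/disk; center defaults to (2,2,2) lambda for the
    # default 17-lambda cell and scales with the cell radius otherwise
    nucleolus_radius: float = 0.10                                    # /a
    nucleolus_center: Tuple[float, float, float] | None = None        # [lambda]

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        for name in ("n_medium", "n_cytoplasm", "n_nucleus", "n_nucleolus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self._check_nesting()

    @property
    def radius(self) -> float:
        """Cell radius a [lambda]."""
        return self.diameter / 2.0

    @property
    def nucleolus_center_wl(self) -> np.ndarray:
        """Nucleolus center (x, y, z) in wavelengths.

        Defaults to (2, 2, 2) lambda scaled by diameter/17 so the phantom
        geometry is self-similar across cell sizes.
        """
        if self.nucleolus_center is not None:
            return np.asarray(self.nucleolus_center, dtype=float)
        return np.full(3, 2.0) * (self.diameter / 17.0)

    def _check_nesting(self) -> None:
        """Nucleolus strictly inside nucleus strictly inside cytoplasm."""
        a = self.radius
        semi = a * np.asarray(self.nucleus_semiaxes)
        off = a * np.asarray(self.nucleus_offset)
        # nucleus inside cytoplasm sphere: |off| + max semi-axis < a
        if np.linalg.norm(off) + semi.max() >= a:
            raise ValueError("nucleus is not strictly inside the cytoplasm")
        # nucleolus inside nucleus ellipsoid: sample the sphere surface
        c = self.nucleolus_center_wl
        r = self.nucleolus_radius * a
        rng = np.random.default_rng(12345)
        v = rng.normal(size=(4096, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        p = c + r * v
        q = (((p - off) / semi) ** 2).sum(axis=1)
        if q.max() >= 1.0:
            raise ValueError("nucleolus is not strictly inside the nucleus")


def _require_fit(spec: PhantomSpec, wavelength_px: float, grid_size: int) -> None:
    if spec.diameter * wavelength_px >= grid_size:
        raise ValueError(
            f"cell diameter {spec.diameter} lambda = "
            f"{spec.diameter * wavelength_px:.1f} px exceeds grid {grid_size}")


def _rasterize(coords, spec: PhantomSpec, wavelength_px: float) -> np.ndarray:
    """Innermost-compartment rasterization on centered pixel coordinates.

    ``coords`` is a tuple of broadcastable (x, z) or (x, y, z) arrays in
    wavelength units, measured from the grid center.
    """
    a = spec.radius
    if len(coords) == 2:
        x, z = coords
        semi = a * np.asarray(spec.nucleus_semiaxes)[[0, 2]]
        off = a * np.asarray(spec.nucleus_offset)[[0, 2]]
        nuc_q = (((x - off[0]) / semi[0]) ** 2 + ((z - off[1]) / semi[1]) ** 2)
        nl = spec.nucleolus_center_wl[[0, 2]]
        nl_r2 = (x - nl[0]) ** 2 + (z - nl[1]) ** 2
        cyt_r2 = x ** 2 + z ** 2
    else:
        x, y, z = coords
        semi = a * np.asarray(spec.nucleus_semiaxes)
        off = a * np.asarray(spec.nucleus_offset)
        nuc_q = (((x - off[0]) / semi[0]) ** 2 + ((y - off[1]) / semi[1]) ** 2
                 + ((z - off[2]) / semi[2]) ** 2)
        nl = spec.nucleolus_center_wl
        nl_r2 = (x - nl[0]) ** 2 + (y - nl[1]) ** 2 + (z - nl[2]) ** 2
        cyt_r2 = x ** 2 + y ** 2 + z ** 2

    n = np.full(np.broadcast_shapes(*(c.shape for c in coords)),
                spec.n_medium, dtype=float)
    n[cyt_r2 <= a ** 2] = spec.n_cytoplasm
    n[nuc_q <= 1.0] = spec.n_nucleus
    n[nl_r2 <= (spec.nucleolus_radius * a) ** 2] = spec.n_nucleolus
    return n


def _axis(grid_size: int, wavelength_px: float) -> np.ndarray:
    return (np.arange(grid_size) - grid_size // 2) / wavelength_px


def make_cell_phantom_2d(grid_size: int, wavelength_px: float,
                         spec: PhantomSpec | None = None) -> RefractiveIndexMap:
    """Rasterize the 2D cell phantom onto a ``grid_size x grid_size`` map.

    Array layout is (z, x); the cell is centered on the rotation axis at
    index ``grid_size // 2``.
    """
    spec = spec or PhantomSpec()
    _require_fit(spec, wavelength_px, grid_size)
    ax = _axis(grid_size, wavelength_px)
    z, x = np.meshgrid(ax, ax, indexing="ij")
    n = _rasterize((x, z), spec, wavelength_px)
    geom = ImagingGeometry(wavelength=wavelength_px, medium_index=spec.n_medium)
    return RefractiveIndexMap(n=n, geometry=geom)


def make_cell_phantom_3d(grid_size: int, wavelength_px: float,
                         spec: PhantomSpec | None = None) -> RefractiveIndexMap:
    """Rasterize the 3D cell phantom onto a cubic (z, y, x) volume."""
    spec = spec or PhantomSpec()
    _require_fit(spec, wavelength_px, grid_size)
    ax = _axis(grid_size, wavelength_px)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    n = _rasterize((x, y, z), spec, wavelength_px)
    geom = ImagingGeometry(wavelength=wavelength_px, medium_index=spec.n_medium)
    return RefractiveIndexMap(n=n, geometry=geom)


#: refractive-index series endpoints for the contrast sweep
_RI_SERIES_LO = (1.334, 1.334, 1.334)
_RI_SERIES_HI = (1.455, 1.435, 1.543)


def ri_series(t: float) -> PhantomSpec:
    """Phantom spec with compartment RIs interpolated along the contrast axis.

    At ``t=0`` all compartments sit just above water (1.334); at ``t=1``
    cytoplasm/nucleus/nucleolus reach (1.455, 1.435, 1.543).  The medium
    stays at 1.333 throughout.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    cyt, nuc, nll = (lo + t * (hi - lo)
                     for lo, hi in zip(_RI_SERIES_LO, _RI_SERIES_HI))
    return replace(PhantomSpec(), n_cytoplasm=cyt, n_nucleus=nuc,
                   n_nucleolus=nll)
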