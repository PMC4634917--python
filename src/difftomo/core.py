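"""Domain types and sinogram validation for full-view diffraction tomography.

Conventions
-----------
* All lengths are in detector pixels; the wavelength is supplied in pixels
  (``lambda_px = wavelength_nm / pixel_size_nm`` for physical data).
* 2D arrays are indexed ``(z, x)``; 3D arrays ``(z, y, x)``.  The incident
  plane wave travels along +z, the detector line/plane is spanned by x
  (and y), and the specimen rotates about the y axis.
* The rotation axis passes through index ``N // 2`` on each axis.
* Detector fields are stored background-normalized, ``u / u0``, so a
  field identically 1 means "no specimen".
* Time convention ``exp(+i k_m z)`` for the incident wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "ImagingGeometry",
    "ComplexSinogram",
    "ObjectFunctionMap",
    "RefractiveIndexMap",
    "ErrorReport",
    "validate_sinogram",
    "wavenumbers",
]

#: default immersion-medium refractive index (water at visible wavelengths)
WATER_RI = 1.333

ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class ImagingGeometry:
    """Acquisition geometry of a plane-wave tomography setup.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength in detector pixels.
    medium_index : float
        Refractive index n_m of the immersion medium.
    pixel_size : float
        Detector pixel pitch; fixed at 1 (grid-native units).
    detector_distance : float
        Distance l_D from the rotation center to the detector plane along
        the propagation axis, in pixels.  0 after numerical refocusing to
        the specimen center.
    """

    wavelength: float
    medium_index: float = WATER_RI
    pixel_size: float = 1.0
    detector_distance: float = 0.0

    def __post_init__(self):
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if self.pixel_size != 1.0:
            raise ValueError("pixel_size is fixed at 1 (grid-native units)")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2*pi/lambda [rad/px]."""
        return 2.0 * np.pi / self.wavelength

    @property
    def km(self) -> float:
        """Medium wavenumber n_m * k0 [rad/px]."""
        return self.medium_index * self.k0


def wavenumbers(geometry: ImagingGeometry) -> Tuple[float, float]:
    """Return ``(k0, km)`` of a geometry."""
    return geometry.k0, geometry.km


def _check_square(arr: np.ndarray, name: str) -> None:
    if arr.ndim not in (2, 3):
        raise ValueError(f"{name} must be 2D or 3D, got ndim={arr.ndim}")
    if len(set(arr.shape)) != 1:
        raise ValueError(
            f"{name} must be on a square/cubic grid, got shape {arr.shape}")


@dataclass
class ObjectFunctionMap:
    """Scattering potential f(r) = k_m^2 [(n/n_m)^2 - 1] on a square/cubic grid."""

    f: np.ndarray
    geometry: ImagingGeometry

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=complex)
        _check_square(self.f, "f")


@dataclass
class RefractiveIndexMap:
    """Refractive-index distribution n(r) on a square/cubic grid."""

    n: np.ndarray
    geometry: ImagingGeometry

    def __post_init__(self):
        self.n = np.asarray(self.n)
        _check_square(self.n, "n")
        if np.any(self.n.real < 0):
            raise ValueError("refractive index must have non-negative real part")

    @property
    def ndim(self) -> int:
        return self.n.ndim


@dataclass
class ComplexSinogram:
    """Background-normalized complex detector fields for a full 360-degree turn.

    ``fields`` has shape (N_angles, Nx) in 2D or (N_angles, Ny, Nx) in 3D and
    stores u/u0 per rotational position.  Use :func:`validate_sinogram` to
    construct a checked instance.
    """

    fields: np.ndarray
    angles: np.ndarray
    geometry: ImagingGeometry
    delta_phi: float = field(init=False)

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=complex)
        self.angles = np.asarray(self.angles, dtype=float)
        _validate(self.fields, self.angles)
        self.delta_phi = 2.0 * np.pi / len(self.angles)

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def _validate(fields: np.ndarray, angles: np.ndarray) -> None:
    if fields.ndim not in (2, 3):
        raise ValueError("fields must be (N, Nx) or (N, Ny, Nx)")
    if angles.ndim != 1:
        raise ValueError("angles must be 1-D")
    n = len(angles)
    if fields.shape[0] != n:
        raise ValueError(
            f"angle count ({n}) does not match field count ({fields.shape[0]})")
    if not np.all(np.isfinite(fields)):
        raise ValueError("fields contain NaN/Inf values")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles contain NaN/Inf values")
    if n < 1:
        raise ValueError("need at least one angle")
    if np.any(angles < -ANGLE_TOL) or np.any(angles >= 2 * np.pi):
        raise ValueError("angles must lie in [0, 2*pi)")
    if n > 1:
        diffs = np.diff(angles)
        if np.any(diffs <= 0):
            raise ValueError("angles must be strictly increasing")
        dphi = 2.0 * np.pi / n
        dev = np.max(np.abs(diffs - dphi))
        if dev > ANGLE_TOL:
            raise ValueError(
                "unequal spacing: angles must be equally distributed over "
                f"[0, 2*pi); max deviation from 2*pi/N is {dev:.3e} rad")


def validate_sinogram(fields: np.ndarray, angles: np.ndarray,
                      geometry: ImagingGeometry) -> ComplexSinogram:
    """Validate and wrap a full-view, dense, equispaced sinogram.

    Rejects non-finite values, mismatched angle/field counts and angle sets
    that are not equally distributed over [0, 2*pi) (within 1e-9 rad).
    """
    return ComplexSinogram(fields=fields, angles=angles, geometry=geometry)


def full_turn_angles(n: int) -> np.ndarray:
    """``n`` angles equally distributed over [0, 2*pi)."""
    if n < 1:
        raise ValueError("need at least one angle")
    return 2.0 * np.pi * np.arange(n) / n


@dataclass
class ErrorReport:
    """Reconstruction-quality metrics over the inscribed volume."""

    e_rms: float
    e_tv: float
    mask_voxels: int
    normalization: float

    def __post_init__(self):
        if self.e_rms < 0 or self.e_tv < 0:
            raise ValueError("error metrics must be non-negative")
        if self.mask_voxels <= 0:
            raise ValueError("mask must contain at least one voxel")

    def as_dict(self) -> dict:
        return {"e_rms": self.e_rms, "e_tv": self.e_tv,
                "mask_voxels": self.mask_voxels,
                "normalization": self.normalization}
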