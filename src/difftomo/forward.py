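"""Scalar forward models: ray-integral, Born and Rytov sinogram simulation.

These simulators generate the benchmark data for the reconstruction
algorithms.  Within scalar first-order scattering theory they are exact up
to rasterization and quadrature:

* :func:`radon_forward` integrates the refractive-index excess along
  straight rays (projection/OPT model).
* :func:`born_forward` evaluates the scattered field via the Fourier
  diffraction theorem: the 1D (2D: detector line) or 2D (3D: detector
  plane) spectrum of the scattered field equals the object spectrum sampled
  on the Ewald arc/cap, weighted by i/(2*gamma) and propagated to the
  detector.  The axial spectral sample is computed by an exact nonuniform
  DFT along z, so no interpolation in Fourier space is involved.
* :func:`born_forward_bruteforce` sums the free-space Green's function over
  all voxels -- an O(N_detector * N_voxels) oracle that pins every FFT and
  normalization convention of the fast path.
* :func:`rytov_forward` exponentiates the Born-predicted complex phase,
  u/u0 = exp(b_born), which is the field a first-order-in-phase (Rytov)
  specimen would produce; optional circular complex Gaussian noise emulates
  coherent detection noise.

The detector is an ideal field sensor capturing every propagating mode
(numerical aperture 1); evanescent frequencies (k_perp >= k_m) are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import hankel1

from . import _fft
from .core import (ComplexSinogram, ImagingGeometry, ObjectFunctionMap,
                   RefractiveIndexMap)

__all__ = ["ScatteringData", "radon_forward", "born_forward",
           "born_forward_bruteforce", "rytov_forward", "object_from_ri"]


@dataclass
class ScatteringData:
    """Per-angle complex scattering data plus its approximation tag.

    ``data`` holds u/u0 - 1 for the Born approximation, the complex Rytov
    phase ln|u/u0| + i*unwrapped arg(u/u0) for Rytov, or the real unwrapped
    phase for Radon.  Shape follows the sinogram convention
    (N_angles, [Ny,] Nx).
    """

    data: np.ndarray
    angles: np.ndarray
    geometry: ImagingGeometry
    approximation: str

    def __post_init__(self):
        if self.approximation not in ("born", "rytov", "radon"):
            raise ValueError(f"unknown approximation {self.approximation!r}")
        self.data = np.asarray(self.data)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.shape[0] != len(self.angles):
            raise ValueError("angle count does not match data planes")

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def object_from_ri(ri_map: RefractiveIndexMap,
                   geometry: ImagingGeometry | None = None) -> ObjectFunctionMap:
    """Scattering potential f = k_m^2 ((n/n_m)^2 - 1) of an RI map."""
    geom = geometry or ri_map.geometry
    nm = geom.medium_index
    f = geom.km ** 2 * ((np.asarray(ri_map.n, dtype=complex) / nm) ** 2 - 1.0)
    return ObjectFunctionMap(f=f, geometry=geom)


def _check_angles(angles) -> np.ndarray:
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("angle list is empty")
    return angles


def radon_forward(ri_map: RefractiveIndexMap, angles,
                  geometry: ImagingGeometry | None = None) -> np.ndarray:
    """Straight-ray phase projections Phi = k0 * integral of (n - n_m) dz.

    Rotates the map by -phi (about the y axis in 3D) for each projection
    angle and integrates along the propagation axis z.  Returns the real
    phase sinogram of shape (N_angles, [Ny,] Nx).
    """
    angles = _check_angles(angles)
    geom = geometry or ri_map.geometry
    n = np.asarray(ri_map.n.real, dtype=float)
    dn = n - geom.medium_index
    out = np.empty((len(angles),) + n.shape[1:], dtype=float)
    for i, phi in enumerate(angles):
        rot = _fft.rotate(dn, -phi, cval=0.0)
        out[i] = geom.k0 * rot.sum(axis=0)
    return out


def _gamma(km: float, k_perp_sq: np.ndarray):
    """Axial wavenumber sqrt(km^2 - k_perp^2) and the propagating-mode mask."""
    mask = k_perp_sq < km ** 2
    gamma = np.sqrt(np.maximum(km ** 2 - k_perp_sq, 0.0))
    return gamma, mask


def _check_sampling(geometry: ImagingGeometry) -> None:
    if geometry.km >= np.pi:
        raise ValueError(
            "medium wavenumber k_m >= pi rad/px: the field is not resolvable "
            "on a unit-pixel grid; use wavelength > 2 * medium_index pixels")


def born_forward(object_map: ObjectFunctionMap, angles,
                 geometry: ImagingGeometry | None = None,
                 pad_factor: int = 2) -> ScatteringData:
    """First-order (Born) scattered fields b = u/u0 - 1 on the detector.

    For each angle the object is rotated into the illumination frame, its
    transverse spectrum is computed per depth slice by FFT, and the Ewald
    arc/cap sample f_hat(k_perp, gamma - k_m) is accumulated by an exact
    DFT along z.  The detector spectrum is

        b_hat(k_perp) = i/(2*gamma) * exp(i(gamma - k_m) l_D)
                        * f_hat(k_perp, gamma - k_m)

    for propagating modes, zero otherwise (NA = 1 cutoff).
    """
    angles = _check_angles(angles)
    geom = geometry or object_map.geometry
    _check_sampling(geom)
    f = np.asarray(object_map.f, dtype=complex)
    km, ld = geom.km, geom.detector_distance
    ndim = f.ndim
    n = f.shape[0]
    npad = _fft.pad_length(n, pad_factor)
    kx = _fft.kgrid(npad)
    if ndim == 2:
        k_perp_sq = kx ** 2
        det_axes = (1,)
    else:
        ky = _fft.kgrid(npad)
        k_perp_sq = ky[:, None] ** 2 + kx[None, :] ** 2
        det_axes = (1, 2)
    gamma, mask = _gamma(km, k_perp_sq)
    zc = (np.arange(n) - n // 2).reshape((n,) + (1,) * len(det_axes))
    # exp(-i (gamma - km) z) for the axial nonuniform DFT
    axial = np.exp(-1j * (gamma - km)[None] * zc)
    with np.errstate(divide="ignore", invalid="ignore"):
        weight = np.where(mask, 1j / (2.0 * gamma)
                          * np.exp(1j * (gamma - km) * ld), 0.0)

    out = np.empty((len(angles),) + f.shape[1:], dtype=complex)
    for i, phi in enumerate(angles):
        rot = _fft.rotate(f, -phi, cval=0.0)
        for ax in det_axes:
            rot = _fft.pad_centered(rot, ax, npad)
        spec = _fft.ft_centered(rot, axes=det_axes)        # (Nz, [Ky,] Kx)
        b_hat = weight * (spec * axial).sum(axis=0)
        b = _fft.ift_centered(b_hat, axes=tuple(range(b_hat.ndim)))
        for ax in range(b.ndim):
            b = _fft.crop_centered(b, ax, n)
        out[i] = b
    return ScatteringData(data=out, angles=angles, geometry=geom,
                          approximation="born")


def born_forward_bruteforce(object_map: ObjectFunctionMap, angle: float,
                            geometry: ImagingGeometry | None = None
                            ) -> np.ndarray:
    """Direct Green's-function summation of the Born scattered field.

    Evaluates u_B(r_D) = sum_voxels G(r_D - r') f(r') u0(r') for one
    projection angle and returns the background-normalized field
    u_B/u0(l_D) on the detector line/plane.  The free-space Green's
    function is (i/4) H0^(1)(k_m r) in 2D and exp(i k_m r)/(4 pi r) in 3D.
    Cost is O(N_detector * N_voxels); intended for small grids as an
    oracle for :func:`born_forward`.  Voxels coincident with a detector
    point are skipped (principal-value treatment of the singularity).
    """
    geom = geometry or object_map.geometry
    f = np.asarray(object_map.f, dtype=complex)
    km, ld = geom.km, geom.detector_distance
    n = f.shape[0]
    rot = _fft.rotate(f, -float(angle), cval=0.0)
    c = n // 2
    if f.ndim == 2:
        zi, xi = np.nonzero(rot)
        fv = rot[zi, xi]
        zv, xv = zi - c, xi - c
        xd = np.arange(n) - c
        dx = xd[:, None] - xv[None, :]
        dz = ld - zv[None, :]
        r = np.hypot(dx, dz)
        g = np.where(r > 0, 0.25j * hankel1(0, km * np.maximum(r, 1e-12)), 0.0)
        u = (g * (fv * np.exp(1j * km * zv))[None, :]).sum(axis=1)
    else:
        zi, yi, xi = np.nonzero(rot)
        fv = rot[zi, yi, xi]
        zv, yv, xv = zi - c, yi - c, xi - c
        xd = np.arange(n) - c
        yd = np.arange(n) - c
        dx = xd[None, :, None] - xv[None, None, :]
        dy = yd[:, None, None] - yv[None, None, :]
        dz = ld - zv[None, None, :]
        r = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
        g = np.where(r > 0,
                     np.exp(1j * km * r) / (4.0 * np.pi * np.maximum(r, 1e-12)),
                     0.0)
        u = (g * (fv * np.exp(1j * km * zv))[None, None, :]).sum(axis=2)
    return u * np.exp(-1j * km * ld)


def rytov_forward(object_map: ObjectFunctionMap, angles,
                  geometry: ImagingGeometry | None = None,
                  noise_sigma: float = 0.0,
                  rng: np.random.Generator | int | None = None,
                  pad_factor: int = 2) -> ComplexSinogram:
    """Simulate detector fields u/u0 = exp(b_born) (Rytov-consistent).

    The complex exponential of the first-order scattering prediction is the
    field of a specimen that satisfies the Rytov linearization exactly; it
    also reduces to the Born field in the weak-scattering limit.  Optional
    circular complex Gaussian noise of standard deviation ``noise_sigma``
    is added to u/u0 (seeded via ``rng``; off by default).
    """
    born = born_forward(object_map, angles, geometry, pad_factor=pad_factor)
    fields = np.exp(born.data)
    if noise_sigma > 0.0:
        gen = (rng if isinstance(rng, np.random.Generator)
               else np.random.default_rng(rng))
        noise = gen.normal(scale=noise_sigma / np.sqrt(2.0),
                           size=fields.shape + (2,))
        fields = fields + noise[..., 0] + 1j * noise[..., 1]
    geom = geometry or object_map.geometry
    return ComplexSinogram(fields=fields, angles=born.angles, geometry=geom)
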