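"""Backpropagation (Born/Rytov) and filtered backprojection (Radon).

Backpropagation is the diffraction-tomography analog of filtered
backprojection.  With background-normalized scattering data d(angle, x[,y])
(Born: u/u0 - 1; Rytov: the complex Rytov phase), the object function is
recovered as

    f(r) = (-i k_m / N_angles) * sum_angles R_phi {
               IFT_perp [ |k_x| M(k_perp < k_m)
                          * d_hat(k_perp) * exp(i (gamma - k_m)(z' - l_D)) ] }

where d_hat is the detector-axis Fourier transform of the data,
gamma = sqrt(k_m^2 - k_perp^2), z' the depth in the rotated frame measured
from the rotation center, M the NA=1 low-pass, and R_phi the real-space
rotation of the per-angle contribution into the laboratory frame.  The
ramp |k_x| is applied along the detector axis perpendicular to the single
rotation axis y only; the constant -i k_m / N_angles is the discrete form
of the angular-quadrature weight (including the factor 1/2 for the double
Fourier-space coverage of a full 360-degree turn) under unit-pixel FFT
conventions.

The same accumulation loop with a trivial depth kernel and real data
implements filtered backprojection; dividing by k0 maps the backprojected
optical path back to refractive index.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _fft
from .core import (ImagingGeometry, ObjectFunctionMap, RefractiveIndexMap,
                   validate_sinogram)
from .forward import ScatteringData, _gamma

__all__ = ["BackpropagationPlan", "backpropagate_2d", "backpropagate_3d",
           "filtered_backprojection", "object_to_ri", "inscribed_mask"]


def _ramp_filter(n_pad: int) -> np.ndarray:
    """Band-limited discrete ramp (Ram-Lak) transfer function, in rad/px.

    Computed as the DFT of the exact impulse response of the Nyquist-limited
    ramp |k|; unlike the naive ``abs(kgrid(n))`` it has a small positive DC
    weight, which removes the mean-level (DC-bin) bias of the discrete
    filtered backprojection/backpropagation sums.  Even in k by
    construction.
    """
    from scipy import fft as sfft
    m = sfft.fftfreq(n_pad, 1.0 / n_pad).astype(int)
    h = np.zeros(n_pad)
    h[m == 0] = np.pi / 2.0
    odd = (m % 2) != 0
    h[odd] = -2.0 / (np.pi * m[odd] ** 2)
    return np.real(sfft.fft(h))


@dataclass
class BackpropagationPlan:
    """Precomputed frequency grids, filters and kernels for one geometry.

    Deterministic for fixed (shape, geometry, pad_factor); the global
    normalization constant is -i k_m / N_angles (see module docstring).
    """

    n: int                    # detector length (= grid size)
    n_pad: int
    ndim: int                 # 2 or 3 (reconstruction dimensionality)
    geometry: ImagingGeometry
    kx: np.ndarray = dc_field(init=False)
    ky: np.ndarray | None = dc_field(init=False)
    gamma: np.ndarray = dc_field(init=False)
    lowpass: np.ndarray = dc_field(init=False)
    ramp: np.ndarray = dc_field(init=False)
    kernel: np.ndarray = dc_field(init=False)   # (Nz, [Ky,] Kx) depth kernel

    def __post_init__(self):
        km, ld = self.geometry.km, self.geometry.detector_distance
        self.kx = _fft.kgrid(self.n_pad)
        ramp_1d = _ramp_filter(self.n_pad)
        if self.ndim == 2:
            self.ky = None
            k_perp_sq = self.kx ** 2
            ramp = ramp_1d
        else:
            self.ky = _fft.kgrid(self.n_pad)
            k_perp_sq = self.ky[:, None] ** 2 + self.kx[None, :] ** 2
            ramp = ramp_1d[None, :] * np.ones((self.n_pad, 1))
        self.gamma, self.lowpass = _gamma(km, k_perp_sq)
        self.ramp = np.where(self.lowpass, ramp, 0.0)
        zc = (np.arange(self.n) - self.n // 2).reshape(
            (self.n,) + (1,) * (self.ndim - 1))
        self.kernel = np.where(
            self.lowpass[None],
            np.exp(1j * (self.gamma - km)[None] * (zc - ld)), 0.0)

    @property
    def norm_constant(self) -> complex:
        """Per-angle weight excluding the 1/N_angles angular average."""
        return -1j * self.geometry.km


def _plan(data_shape, ndim: int, geometry: ImagingGeometry,
          pad_factor: int) -> BackpropagationPlan:
    n = data_shape[-1]
    return BackpropagationPlan(n=n, n_pad=_fft.pad_length(n, pad_factor),
                               ndim=ndim, geometry=geometry)


def _check_tag(data: ScatteringData) -> None:
    if data.approximation == "radon":
        raise ValueError("radon-tagged phase data: use filtered_backprojection")
    if data.approximation not in ("born", "rytov"):
        raise ValueError(f"unknown approximation {data.approximation!r}")


def _check_full_view(angles: np.ndarray) -> None:
    # reuse sinogram validation for the full-view equispacing contract
    validate_sinogram(np.zeros((len(angles), 1), dtype=complex), angles,
                      ImagingGeometry(wavelength=1.0))


def backpropagate_2d(data: ScatteringData,
                     geometry: ImagingGeometry | None = None,
                     pad_factor: int = 2) -> ObjectFunctionMap:
    """Backpropagate 2D scattering data (N_angles, Nx) to f on an Nx^2 grid."""
    _check_tag(data)
    _check_full_view(data.angles)
    geom = geometry or data.geometry
    d = np.asarray(data.data, dtype=complex)
    if d.ndim != 2:
        raise ValueError("expected 2D sinogram data (N_angles, Nx)")
    plan = _plan(d.shape, 2, geom, pad_factor)
    n, npad = plan.n, plan.n_pad
    accum = np.zeros((n, n), dtype=complex)
    filt = plan.ramp * plan.kernel                       # (Nz, Kx)
    for i, phi in enumerate(data.angles):
        line = _fft.pad_centered(d[i], 0, npad)
        d_hat = _fft.ft_centered(line, axes=0)
        contrib = _fft.ift_centered(d_hat[None, :] * filt, axes=1)
        contrib = _fft.crop_centered(contrib, 1, n)
        accum += _fft.rotate(contrib, phi, cval=0.0)
    f = plan.norm_constant / data.n_angles * accum
    return ObjectFunctionMap(f=f, geometry=geom)


def backpropagate_3d(data: ScatteringData,
                     geometry: ImagingGeometry | None = None,
                     pad_factor: int = 2) -> ObjectFunctionMap:
    """Backpropagate 3D scattering data (N_angles, Ny, Nx) to f on an Nx^3 grid.

    The detector spectrum is 2D, gamma depends on (k_y, k_x), but the ramp
    filter involves |k_x| only because the specimen rotates about the
    single y axis; the per-angle volume contribution is rotated about y.
    """
    _check_tag(data)
    _check_full_view(data.angles)
    geom = geometry or data.geometry
    d = np.asarray(data.data, dtype=complex)
    if d.ndim != 3:
        raise ValueError("expected 3D sinogram data (N_angles, Ny, Nx)")
    if d.shape[1] != d.shape[2]:
        raise ValueError("detector planes must be square")
    plan = _plan(d.shape, 3, geom, pad_factor)
    n, npad = plan.n, plan.n_pad
    accum = np.zeros((n, n, n), dtype=complex)
    filt = plan.ramp[None] * plan.kernel                 # (Nz, Ky, Kx)
    for i, phi in enumerate(data.angles):
        plane = _fft.pad_centered(_fft.pad_centered(d[i], 0, npad), 1, npad)
        d_hat = _fft.ft_centered(plane, axes=(0, 1))
        contrib = _fft.ift_centered(d_hat[None] * filt, axes=(1, 2))
        contrib = _fft.crop_centered(_fft.crop_centered(contrib, 1, n), 2, n)
        accum += _fft.rotate(contrib, phi, cval=0.0)
    f = plan.norm_constant / data.n_angles * accum
    return ObjectFunctionMap(f=f, geometry=geom)


def filtered_backprojection(phase_sinogram: np.ndarray,
                            geometry: ImagingGeometry,
                            pad_factor: int = 2) -> RefractiveIndexMap:
    """Inverse Radon transform of an unwrapped phase sinogram.

    Ramp-filters each projection, backprojects along straight rays over the
    full turn (weight delta_phi / (4 pi), the 360-degree double-coverage
    form of the classical filtered backprojection), divides by k0 and adds
    the medium index.  3D sinograms (N_angles, Ny, Nx) are processed
    slice-by-slice along y.
    """
    g = np.asarray(phase_sinogram)
    if np.iscomplexobj(g):
        raise ValueError("phase sinogram must be real (unwrapped phase)")
    if g.ndim not in (2, 3):
        raise ValueError("expected (N_angles, Nx) or (N_angles, Ny, Nx)")
    angles = _full_view_angles_for(g.shape[0])
    n = g.shape[-1]
    if g.ndim == 3 and g.shape[1] != g.shape[2]:
        raise ValueError("detector planes must be square")
    npad = _fft.pad_length(n, pad_factor)
    ramp = _ramp_filter(npad)
    vol_shape = (n,) * g.ndim
    accum = np.zeros(vol_shape, dtype=float)
    for i, phi in enumerate(angles):
        proj = _fft.pad_centered(g[i], -1, npad)
        q_hat = _fft.ft_centered(proj, axes=proj.ndim - 1) * ramp
        q = _fft.ift_centered(q_hat, axes=proj.ndim - 1).real
        q = _fft.crop_centered(q, q.ndim - 1, n)
        smear = np.broadcast_to(q[None], vol_shape)
        accum += _fft.rotate(smear, phi, cval=0.0)
    dphi = 2.0 * np.pi / g.shape[0]
    h = accum * dphi / (4.0 * np.pi)
    n_map = geometry.medium_index + h / geometry.k0
    n_map = np.clip(n_map, 0.0, None)
    return RefractiveIndexMap(n=n_map, geometry=geometry)


def _full_view_angles_for(n_angles: int) -> np.ndarray:
    if n_angles < 1:
        raise ValueError("empty sinogram")
    return 2.0 * np.pi * np.arange(n_angles) / n_angles


def object_to_ri(object_map: ObjectFunctionMap,
                 geometry: ImagingGeometry | None = None) -> RefractiveIndexMap:
    """Refractive index n = n_m sqrt(1 + f/k_m^2) from the object function.

    The square root is taken on the complex field; consumers use the real
    part for the metrics.  Where 1 + Re(f)/k_m^2 < 0 (unphysical strong
    negative contrast, possible in noisy reconstructions) the radicand is
    clamped to 0 and the flagged voxel count is recorded on the returned
    map as ``clamped_voxels``.
    """
    geom = geometry or object_map.geometry
    radicand = 1.0 + object_map.f / geom.km ** 2
    bad = radicand.real < 0
    n_bad = int(np.sum(bad))
    if n_bad:
        radicand = np.where(bad, radicand - radicand.real, radicand)
    n = geom.medium_index * np.sqrt(radicand)
    ri = RefractiveIndexMap(n=n, geometry=geom)
    ri.clamped_voxels = n_bad
    return ri


def inscribed_mask(shape) -> np.ndarray:
    """Boolean mask of the inscribed circle/sphere of radius N/2.

    Only points inside this region receive contributions from every
    projection of a full-view sinogram; the quality metrics sum over it.
    """
    shape = tuple(shape)
    if len(shape) not in (2, 3) or len(set(shape)) != 1:
        raise ValueError("shape must be square (2D) or cubic (3D)")
    n = shape[0]
    axes = [np.arange(n) - n // 2 for _ in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    r2 = sum(g ** 2 for g in grids)
    return r2 <= (n / 2.0) ** 2
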