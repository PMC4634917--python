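"""Sinogram preprocessing: refocusing, autofocus, unwrapping, data filters.

This is the step that turns background-normalized complex detector fields
u/u0 into the quantity each reconstruction algorithm inverts:

* Born:  b     = u/u0 - 1
* Rytov: phi_R = ln|u/u0| + i * unwrap(arg(u/u0))
* Radon: Phi   = unwrap(arg(u/u0))            (amplitude discarded)

plus numerical refocusing by angular-spectrum propagation and an
amplitude-gradient autofocus, mirroring the acquisition protocol in which
the detector field (recorded about one wavelength behind the specimen) is
refocused to the rotation center before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.restoration import unwrap_phase as _skimage_unwrap

from . import _fft
from .core import ComplexSinogram, ImagingGeometry
from .forward import ScatteringData, _gamma

__all__ = ["UnwrapResult", "propagate", "autofocus", "unwrap_phase_2d",
           "unwrap_phase_1d", "to_born_data", "to_rytov_data",
           "to_radon_data"]


def propagate(field: np.ndarray, distance: float,
              geometry: ImagingGeometry, pad_factor: int = 2) -> np.ndarray:
    """Angular-spectrum free-space propagation over ``distance`` pixels.

    Multiplies the field spectrum by exp(i * gamma * d) with
    gamma = sqrt(k_m^2 - k_perp^2); evanescent components are zeroed, so
    propagation is unitary on the propagating subspace and
    ``propagate(propagate(u, d), -d) == u`` for band-limited input.
    """
    field = np.asarray(field, dtype=complex)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if field.ndim not in (1, 2):
        raise ValueError("field must be 1D or 2D")
    km = geometry.km
    shape = field.shape
    pads = [_fft.pad_length(n, pad_factor) for n in shape]
    # split off the constant background (a plane wave, propagated exactly):
    # zero-padding the compact residual then avoids the amplitude step at
    # the pad boundary that would otherwise ring through the whole window
    if field.ndim == 1:
        border = np.concatenate([field[:2], field[-2:]])
    else:
        border = np.concatenate([field[0], field[-1], field[:, 0],
                                 field[:, -1]])
    bg = complex(np.median(border.real), np.median(border.imag))
    out = field - bg
    for ax, npad in enumerate(pads):
        out = _fft.pad_centered(out, ax, npad)
    axes = tuple(range(out.ndim))
    spec = _fft.ft_centered(out, axes=axes)
    if out.ndim == 1:
        k_perp_sq = _fft.kgrid(pads[0]) ** 2
    else:
        ky = _fft.kgrid(pads[0])
        kx = _fft.kgrid(pads[1])
        k_perp_sq = ky[:, None] ** 2 + kx[None, :] ** 2
    gamma, mask = _gamma(km, k_perp_sq)
    spec = np.where(mask, spec * np.exp(1j * gamma * distance), 0.0)
    out = _fft.ift_centered(spec, axes=axes)
    for ax, n in enumerate(shape):
        out = _fft.crop_centered(out, ax, n)
    return out + bg * np.exp(1j * km * distance)


@dataclass
class AutofocusResult:
    distance: float
    field: np.ndarray
    warning: bool          # metric was not unimodal on the coarse grid

    def __iter__(self):
        return iter((self.distance, self.field))


def _amplitude_gradient(field: np.ndarray) -> float:
    """Sum of forward-difference gradient magnitudes of |field|."""
    amp = np.abs(field)
    total = 0.0
    for ax in range(amp.ndim):
        total += np.abs(np.diff(amp, axis=ax)).sum()
    return float(total)


def autofocus(field: np.ndarray, geometry: ImagingGeometry,
              search_interval: Tuple[float, float],
              n_coarse: int = 50) -> AutofocusResult:
    """Find the propagation distance minimizing the amplitude gradient.

    A focused field of a mostly-transparent specimen has the flattest
    amplitude; the metric sum |grad |u|| over all pixels is evaluated on a
    coarse grid of ``n_coarse`` candidate distances and the bracket around
    the best candidate is refined by bounded scalar minimization to a
    tolerance of lambda/100.  If the coarse metric has several local
    minima, the global grid minimum is used and ``warning`` is set.
    """
    field = np.asarray(field, dtype=complex)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    lo, hi = map(float, search_interval)
    if not hi > lo:
        raise ValueError("search interval must have positive length")
    ds = np.linspace(lo, hi, n_coarse)
    vals = np.array([_amplitude_gradient(propagate(field, d, geometry))
                     for d in ds])
    ibest = int(np.argmin(vals))
    interior = np.flatnonzero((np.diff(np.sign(np.diff(vals))) > 0))
    warning = len(interior) > 1
    blo = ds[max(ibest - 1, 0)]
    bhi = ds[min(ibest + 1, n_coarse - 1)]
    res = minimize_scalar(
        lambda d: _amplitude_gradient(propagate(field, d, geometry)),
        bounds=(blo, bhi), method="bounded",
        options={"xatol": geometry.wavelength / 100.0})
    best = float(res.x)
    if vals[ibest] < res.fun:        # guard against a flat refinement bracket
        best = float(ds[ibest])
    return AutofocusResult(distance=best,
                           field=propagate(field, best, geometry),
                           warning=warning)


@dataclass
class UnwrapResult:
    """Unwrapped phase with quality diagnostics.

    ``reliability`` is the inverse second-difference quality measure of the
    sorting-by-reliability unwrapper (higher = more trustworthy);
    ``residue_count`` counts 2x2 plaquettes whose wrapped phase circulation
    is non-zero (the unwrapping obstructions).
    """

    phase: np.ndarray
    reliability: np.ndarray
    residue_count: int


def _wrap(p: np.ndarray) -> np.ndarray:
    return (p + np.pi) % (2.0 * np.pi) - np.pi


def _border_offset(unwrapped: np.ndarray, wrapped_like: bool = False) -> np.ndarray:
    """Shift by a 2*pi multiple so the median border phase is in (-pi, pi]."""
    if unwrapped.ndim == 1:
        border = np.concatenate([unwrapped[:2], unwrapped[-2:]])
    else:
        border = np.concatenate([unwrapped[0], unwrapped[-1],
                                 unwrapped[:, 0], unwrapped[:, -1]])
    med = np.median(border)
    k = np.floor((med + np.pi) / (2.0 * np.pi))
    return unwrapped - 2.0 * np.pi * k


def _reliability(wrapped: np.ndarray) -> np.ndarray:
    """Per-pixel second-difference reliability (interior pixels; edges 0)."""
    d = np.zeros_like(wrapped, dtype=float)
    h = _wrap(wrapped[1:-1, :-2] - wrapped[1:-1, 1:-1]) \
        + _wrap(wrapped[1:-1, 2:] - wrapped[1:-1, 1:-1])
    v = _wrap(wrapped[:-2, 1:-1] - wrapped[1:-1, 1:-1]) \
        + _wrap(wrapped[2:, 1:-1] - wrapped[1:-1, 1:-1])
    d1 = _wrap(wrapped[:-2, :-2] - wrapped[1:-1, 1:-1]) \
        + _wrap(wrapped[2:, 2:] - wrapped[1:-1, 1:-1])
    d2 = _wrap(wrapped[:-2, 2:] - wrapped[1:-1, 1:-1]) \
        + _wrap(wrapped[2:, :-2] - wrapped[1:-1, 1:-1])
    dsum = np.sqrt(h ** 2 + v ** 2 + d1 ** 2 + d2 ** 2)
    d[1:-1, 1:-1] = 1.0 / (dsum + 1e-12)
    return d


def _residues(wrapped: np.ndarray) -> int:
    loop = (_wrap(wrapped[:-1, 1:] - wrapped[:-1, :-1])
            + _wrap(wrapped[1:, 1:] - wrapped[:-1, 1:])
            + _wrap(wrapped[1:, :-1] - wrapped[1:, 1:])
            + _wrap(wrapped[:-1, :-1] - wrapped[1:, :-1]))
    return int(np.sum(np.abs(loop) > np.pi))


def unwrap_phase_2d(wrapped: np.ndarray) -> UnwrapResult:
    """Quality-guided 2D phase unwrapping (reliability-sorted region merging).

    Returns the unwrapped phase (identical to the input modulo 2*pi at
    every pixel, with the global 2*pi multiple fixed so the median border
    phase lies in (-pi, pi]), the reliability map, and the residue count.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if wrapped.ndim != 2:
        raise ValueError("wrapped phase must be 2D")
    unwrapped = np.asarray(_skimage_unwrap(wrapped))
    unwrapped = _border_offset(unwrapped)
    return UnwrapResult(phase=unwrapped,
                        reliability=_reliability(wrapped),
                        residue_count=_residues(wrapped))


def unwrap_phase_1d(wrapped: np.ndarray, axis: int = -1) -> np.ndarray:
    """Cumulative 1D unwrapping along ``axis`` with the border-offset fix."""
    unwrapped = np.unwrap(np.asarray(wrapped, dtype=float), axis=axis)
    # fix the global 2*pi multiple per line using the line borders
    first = np.take(unwrapped, [0, 1], axis=axis)
    last = np.take(unwrapped, [-2, -1], axis=axis)
    med = np.median(np.concatenate([first, last], axis=axis),
                    axis=axis, keepdims=True)
    k = np.floor((med + np.pi) / (2.0 * np.pi))
    return unwrapped - 2.0 * np.pi * k


def to_born_data(sinogram: ComplexSinogram) -> ScatteringData:
    """Born scattering data b = u/u0 - 1."""
    return ScatteringData(data=sinogram.fields - 1.0, angles=sinogram.angles,
                          geometry=sinogram.geometry, approximation="born")


def _unwrapped_arg(fields: np.ndarray) -> np.ndarray:
    """Per-projection unwrapped phase: 1D along x for 2D sinograms, the
    reliability-sorted 2D algorithm for 3D sinograms."""
    phase = np.angle(fields)
    if fields.ndim == 2:
        return unwrap_phase_1d(phase, axis=-1)
    return np.stack([unwrap_phase_2d(p).phase for p in phase])


def to_rytov_data(sinogram: ComplexSinogram) -> ScatteringData:
    """Rytov data phi_R = ln|u/u0| + i * unwrapped arg(u/u0)."""
    amp = np.abs(sinogram.fields)
    nz = int(np.sum(amp == 0))
    if nz:
        raise ValueError(
            f"{nz} zero-modulus pixels: Rytov data requires |u/u0| > 0")
    data = np.log(amp) + 1j * _unwrapped_arg(sinogram.fields)
    return ScatteringData(data=data, angles=sinogram.angles,
                          geometry=sinogram.geometry, approximation="rytov")


def to_radon_data(sinogram: ComplexSinogram) -> np.ndarray:
    """Unwrapped phase sinogram (projection tomography input)."""
    amp = np.abs(sinogram.fields)
    nz = int(np.sum(amp == 0))
    if nz:
        raise ValueError(
            f"{nz} zero-modulus pixels: phase is undefined there")
    return _unwrapped_arg(sinogram.fields)
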