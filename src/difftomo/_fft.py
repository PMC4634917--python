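"""Centered FFT helpers, zero-padding and center-fixed rotations.

All spatial coordinates are measured from the grid center ``c = N // 2``
(the rotation-axis position), while :mod:`numpy`/:mod:`scipy` FFTs reference
index 0.  The helpers below absorb the phase ramps so that the discrete
transforms approximate the continuous ones with the centered convention:

    FT[g](k)  = sum_j g[j] * exp(-i k (j - c))        (Delta x = 1 px)
    IFT[G](j) = (1/N) sum_k G[k] * exp(+i k (j - c))

which, with k = 2*pi*fftfreq(N), are a numerically exact inverse pair and
match the continuous FT / (1/2pi) inverse-FT integrals on the unit-pixel
grid.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft
from scipy import ndimage


def kgrid(n: int) -> np.ndarray:
    """Angular spatial frequencies (rad/px) of an ``n``-point FFT."""
    return 2.0 * np.pi * sfft.fftfreq(n)


def _center_phase(n: int, sign: float) -> np.ndarray:
    return np.exp(sign * 1j * kgrid(n) * (n // 2))


def ft_centered(a: np.ndarray, axes) -> np.ndarray:
    """FFT with the spatial origin at index ``n // 2`` on each axis."""
    axes = np.atleast_1d(axes)
    out = sfft.fftn(a, axes=tuple(axes))
    for ax in axes:
        shape = [1] * out.ndim
        shape[ax] = out.shape[ax]
        out = out * _center_phase(out.shape[ax], +1.0).reshape(shape)
    return out


def ift_centered(A: np.ndarray, axes) -> np.ndarray:
    """Inverse of :func:`ft_centered`."""
    axes = np.atleast_1d(axes)
    out = np.asarray(A, dtype=complex)
    for ax in axes:
        shape = [1] * out.ndim
        shape[ax] = out.shape[ax]
        out = out * _center_phase(out.shape[ax], -1.0).reshape(shape)
    return sfft.ifftn(out, axes=tuple(axes))


def pad_length(n: int, factor: int = 2) -> int:
    """FFT-friendly padded length >= factor * n."""
    return sfft.next_fast_len(factor * n)


def pad_centered(a: np.ndarray, axis: int, n_pad: int) -> np.ndarray:
    """Zero-pad ``axis`` to ``n_pad`` keeping index ``n//2`` at ``n_pad//2``."""
    n = a.shape[axis]
    before = n_pad // 2 - n // 2
    width = [(0, 0)] * a.ndim
    width[axis] = (before, n_pad - n - before)
    return np.pad(a, width)


def crop_centered(a: np.ndarray, axis: int, n: int) -> np.ndarray:
    """Undo :func:`pad_centered`."""
    n_pad = a.shape[axis]
    before = n_pad // 2 - n // 2
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(before, before + n)
    return a[tuple(sl)]


def _rotation_matrix(ndim: int, angle: float) -> np.ndarray:
    """Rotation acting on the (z, x) index plane; identity on y for 3D.

    2D arrays are (z, x); 3D arrays are (z, y, x).  ``rotate`` with angle
    ``+phi`` composed with ``-phi`` is the identity (up to interpolation).
    """
    c, s = np.cos(angle), np.sin(angle)
    m = np.eye(ndim)
    # axes: z is 0, x is last
    m[0, 0] = c
    m[0, -1] = -s
    m[-1, 0] = s
    m[-1, -1] = c
    return m


def rotate(a: np.ndarray, angle: float, cval: float = 0.0,
           order: int = 1) -> np.ndarray:
    """Rotate an image/volume about the grid center (3D: about the y axis).

    The center is ``N // 2`` on each axis (not the ``(N-1)/2`` convention of
    :func:`scipy.ndimage.rotate`), matching the rotation-axis convention of
    the sinogram contract.  Complex arrays are rotated component-wise.
    """
    center = np.array([n // 2 for n in a.shape], dtype=float)
    mat = _rotation_matrix(a.ndim, angle)
    offset = center - mat @ center
    kwargs = dict(order=order, mode="constant", cval=cval)
    if np.iscomplexobj(a):
        return (ndimage.affine_transform(a.real, mat, offset=offset, **kwargs)
                + 1j * ndimage.affine_transform(a.imag, mat, offset=offset,
                                                **kwargs))
    return ndimage.affine_transform(a, mat, offset=offset, **kwargs)
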