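"""Normalized RMS and total-variation reconstruction-error metrics.

Both metrics compare a reconstruction n_rec (real part) against the ground
truth phantom n_ph over the inscribed circular/spherical volume only, since
points outside it do not receive contributions from all projections:

    E_RMS = sqrt( sum_vol (n_ph - n_rec)^2 / sum_vol (n_ph - 1)^2 )
    E_TV  = sqrt( sum_vol TV_avg(n_ph - n_rec) / sum_vol (n_ph - 1)^2 )

with the axis-averaged TV norm

    TV_avg^2D = (|grad_x| + |grad_z|) / 2
    TV_avg^3D = (|grad_x| + |grad_y| + |grad_z|) / 3.

E_RMS quantifies the pointwise refractive-index error; E_TV the blurriness
of the difference field.  Both are 100% when the deviation (or its averaged
TV norm) matches the squared contrast of the phantom against vacuum, and
the shared normalization makes 2D and 3D values directly comparable.

Gradients use unit-pixel spacing (``np.gradient``: central differences,
one-sided at the grid edges) so a linear ramp has an exact gradient
everywhere and the 100%-anchor of the TV normalization holds exactly; they
are evaluated on the full grid before masking to avoid artificial
mask-boundary gradients.
"""

from __future__ import annotations

import numpy as np

from .core import ErrorReport
from .reconstruct import inscribed_mask

__all__ = ["rms_error", "tv_error", "error_report"]


def _prepare(n_ph, n_rec, mask):
    n_ph = np.asarray(n_ph, dtype=float)
    n_rec = np.asarray(np.real(n_rec), dtype=float)
    if n_ph.shape != n_rec.shape:
        raise ValueError("phantom and reconstruction shapes differ")
    if mask is None:
        mask = inscribed_mask(n_ph.shape)
    denom = float(np.sum((n_ph[mask] - 1.0) ** 2))
    if denom == 0.0:
        raise ValueError(
            "normalization sum (n_ph - 1)^2 vanishes: phantom is uniform 1")
    return n_ph, n_rec, mask, denom


def rms_error(n_ph, n_rec, mask: np.ndarray | None = None) -> float:
    """Normalized RMS error as a fraction (multiply by 100 for %)."""
    n_ph, n_rec, mask, denom = _prepare(n_ph, n_rec, mask)
    num = float(np.sum((n_ph[mask] - n_rec[mask]) ** 2))
    return float(np.sqrt(num / denom))


def _tv_avg(diff: np.ndarray) -> np.ndarray:
    grads = np.gradient(diff)
    if diff.ndim == 1:
        grads = [grads]
    return sum(np.abs(g) for g in grads) / diff.ndim


def tv_error(n_ph, n_rec, mask: np.ndarray | None = None) -> float:
    """Normalized total-variation error as a fraction."""
    n_ph, n_rec, mask, denom = _prepare(n_ph, n_rec, mask)
    tv = _tv_avg(n_ph - n_rec)
    return float(np.sqrt(float(np.sum(tv[mask])) / denom))


def error_report(n_ph, n_rec, mask: np.ndarray | None = None) -> ErrorReport:
    """Both metrics plus the mask size and normalization term."""
    n_ph_a, n_rec_a, mask, denom = _prepare(n_ph, n_rec, mask)
    return ErrorReport(
        e_rms=rms_error(n_ph_a, n_rec_a, mask),
        e_tv=tv_error(n_ph_a, n_rec_a, mask),
        mask_voxels=int(np.sum(mask)),
        normalization=denom)
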