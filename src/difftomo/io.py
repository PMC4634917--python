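"""HDF5 sinogram containers and TIFF volume export.

Container layout::

    /fields   complex array, (N_angles, Nx) or (N_angles, Ny, Nx)  (u/u0)
    /angles   float array, radians
    attrs:    wavelength_px, medium_index, detector_distance_px,
              approximation_tag, creator, version, seed

The round trip through :func:`write_sinogram` / :func:`read_sinogram` is
bit-identical.  TIFF export writes 32-bit float stacks (one page per
z-slice) with unscaled refractive-index values, for visualization in
standard image tools.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from . import __version__
from .core import ComplexSinogram, ImagingGeometry, validate_sinogram

__all__ = ["write_sinogram", "read_sinogram", "export_volume_tiff",
           "read_volume_tiff"]

_REQUIRED_ATTRS = ("wavelength_px", "medium_index", "detector_distance_px")


def write_sinogram(path, sinogram: ComplexSinogram,
                   approximation_tag: str = "field",
                   seed: int | None = None) -> Path:
    """Write a sinogram container; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("fields", data=sinogram.fields)
        h5.create_dataset("angles", data=sinogram.angles)
        geom = sinogram.geometry
        h5.attrs["wavelength_px"] = geom.wavelength
        h5.attrs["medium_index"] = geom.medium_index
        h5.attrs["detector_distance_px"] = geom.detector_distance
        h5.attrs["approximation_tag"] = approximation_tag
        h5.attrs["creator"] = "difftomo"
        h5.attrs["version"] = __version__
        h5.attrs["seed"] = -1 if seed is None else int(seed)
    return path


def read_sinogram(path) -> ComplexSinogram:
    """Read and validate a sinogram container."""
    with h5py.File(path, "r") as h5:
        for key in _REQUIRED_ATTRS:
            if key not in h5.attrs:
                raise ValueError(f"container is missing attribute {key!r}")
        for key in ("fields", "angles"):
            if key not in h5:
                raise ValueError(f"container is missing dataset {key!r}")
        fields = h5["fields"][...]
        angles = h5["angles"][...]
        geom = ImagingGeometry(
            wavelength=float(h5.attrs["wavelength_px"]),
            medium_index=float(h5.attrs["medium_index"]),
            detector_distance=float(h5.attrs["detector_distance_px"]))
    return validate_sinogram(fields, angles, geom)


def export_volume_tiff(path, ri_map, part: str | None = None) -> Path:
    """Write a refractive-index map as a float32 TIFF stack.

    Complex maps require an explicit ``part`` ("real" or "imag").
    """
    arr = ri_map.n if hasattr(ri_map, "n") else np.asarray(ri_map)
    if np.iscomplexobj(arr):
        if part not in ("real", "imag"):
            raise ValueError("complex map: pass part='real' or part='imag'")
        arr = getattr(arr, part)
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    return path


def read_volume_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path))
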