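"""Reconstruction-quality sweep drivers: projection count, RI contrast, size.

Each sweep simulates Rytov-consistent forward sinograms (one simulation per
condition), derives the Born, Rytov and Radon data from the same fields,
reconstructs with the matching inverter, and tabulates the normalized RMS
and TV errors.  Desk-scale defaults: 2D grids of 128 px, 3D grids of
48-64 px, wavelength 4 px; trends (error ordering, plateau position,
contrast and size dependence) are the quantities of interest at this
scale, not absolute error percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ImagingGeometry, RefractiveIndexMap, full_turn_angles
from .forward import object_from_ri, rytov_forward
from .metrics import rms_error, tv_error
from .phantoms import PhantomSpec, make_cell_phantom_2d, make_cell_phantom_3d, ri_series
from .preprocess import to_born_data, to_radon_data, to_rytov_data
from .reconstruct import (backpropagate_2d, backpropagate_3d,
                          filtered_backprojection, object_to_ri)

__all__ = ["SweepResult", "sweep_projections", "plateau_onset", "sweep_ri",
           "sweep_size", "reconstruct_all"]

APPROXIMATIONS = ("born", "rytov", "radon")


@dataclass
class SweepResult:
    """Tabular sweep output: one row per (variable, approximation, dims)."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def select(self, approximation: str, dims: int | None = None) -> pd.DataFrame:
        t = self.table
        sel = t[t.approximation == approximation]
        if dims is not None:
            sel = sel[sel.dims == dims]
        return sel.sort_values("variable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", lines=True)


def reconstruct_all(sinogram, phantom: RefractiveIndexMap,
                    approximations=APPROXIMATIONS) -> dict:
    """All requested inversions of one simulated sinogram -> metric rows."""
    geom = sinogram.geometry
    dims = phantom.ndim
    backpropagate = backpropagate_2d if dims == 2 else backpropagate_3d
    out = {}
    for approx in approximations:
        if approx == "born":
            rec = object_to_ri(backpropagate(to_born_data(sinogram), geom))
            nrec = rec.n.real
        elif approx == "rytov":
            rec = object_to_ri(backpropagate(to_rytov_data(sinogram), geom))
            nrec = rec.n.real
        elif approx == "radon":
            nrec = filtered_backprojection(to_radon_data(sinogram), geom).n
        else:
            raise ValueError(f"unknown approximation {approx!r}")
        out[approx] = (100.0 * rms_error(phantom.n, nrec),
                       100.0 * tv_error(phantom.n, nrec))
    return out


def _sweep(variables, phantoms, geometry, approximations, noise_sigma, seed,
           metadata) -> SweepResult:
    rows = []
    rng = np.random.default_rng(seed)
    for var, phantom in zip(variables, phantoms):
        obj = object_from_ri(phantom)
        n_ang = metadata.get("n_angles", 200)
        angles = full_turn_angles(int(var) if metadata["variable"] ==
                                  "n_projections" else n_ang)
        sino = rytov_forward(obj, angles, geometry, noise_sigma=noise_sigma,
                             rng=rng)
        for approx, (e_rms, e_tv) in reconstruct_all(
                sino, phantom, approximations).items():
            rows.append(dict(variable=var, approximation=approx,
                             dims=phantom.ndim, e_rms=e_rms, e_tv=e_tv))
    return SweepResult(table=pd.DataFrame(rows), metadata=metadata)


def sweep_projections(counts, phantom: RefractiveIndexMap,
                      geometry: ImagingGeometry | None = None,
                      approximations=APPROXIMATIONS,
                      noise_sigma: float = 0.0,
                      seed: int | None = None) -> SweepResult:
    """Error vs total number of projections, equally spaced over 360 degrees."""
    counts = list(counts)
    if sorted(counts) != counts:
        raise ValueError("counts must be sorted ascending")
    if any(c < 4 for c in counts):
        raise ValueError("projection counts below 4 are not supported")
    uniq = sorted(set(counts))
    if len(uniq) != len(counts):
        warnings.warn("duplicate projection counts removed", stacklevel=2)
        counts = uniq
    geom = geometry or phantom.geometry
    meta = dict(variable="n_projections", grid=phantom.n.shape[0],
                wavelength_px=geom.wavelength, seed=seed,
                noise_sigma=noise_sigma)
    return _sweep(counts, [phantom] * len(counts), geom, approximations,
                  noise_sigma, seed, meta)


def plateau_onset(sweep: SweepResult, threshold_pp: float = 1.0,
                  approximation: str = "rytov",
                  dims: int | None = None):
    """Projection count at which both error metrics stop improving.

    Returns ``(count, reached)``: the smallest sampled count from which
    every successive change of both E_RMS and E_TV stays below
    ``threshold_pp`` percentage points (absolute).  If the errors never
    settle, the largest sampled count is returned with ``reached=False``.
    """
    t = sweep.select(approximation, dims)
    if len(t) < 3:
        raise ValueError("need at least 3 sampled counts")
    counts = t.variable.to_numpy()
    d_rms = np.abs(np.diff(t.e_rms.to_numpy()))
    d_tv = np.abs(np.diff(t.e_tv.to_numpy()))
    ok = (d_rms < threshold_pp) & (d_tv < threshold_pp)
    # smallest index i >= 1 with ok[i-1:] all true
    for i in range(1, len(counts)):
        if ok[i - 1:].all():
            return int(counts[i]), True
    return int(counts[-1]), False


def sweep_ri(steps, geometry: ImagingGeometry | None = None, dims: int = 2,
             grid_size: int = 128, wavelength_px: float = 4.0,
             diameter_wl: float | None = None,
             n_angles: int = 200, approximations=APPROXIMATIONS,
             noise_sigma: float = 0.0, seed: int | None = None) -> SweepResult:
    """Error vs intracellular refractive-index contrast (series parameter t)."""
    steps = list(steps)
    if any(not 0 <= t <= 1 for t in steps):
        raise ValueError("steps must lie in [0, 1]")
    make = make_cell_phantom_2d if dims == 2 else make_cell_phantom_3d
    phantoms = []
    for t in steps:
        spec = ri_series(t)
        if diameter_wl is not None:
            spec = replace(spec, diameter=diameter_wl)
        phantoms.append(make(grid_size, wavelength_px, spec))
    geom = geometry or phantoms[0].geometry
    meta = dict(variable="ri_step", grid=grid_size, wavelength_px=wavelength_px,
                seed=seed, noise_sigma=noise_sigma, n_angles=n_angles)
    return _sweep(steps, phantoms, geom, approximations, noise_sigma, seed,
                  meta)


def sweep_size(diameters_wl, volume_extent_wl: float, dims: int = 2,
               wavelength_px: float = 4.0, n_angles: int = 200,
               approximations=APPROXIMATIONS, noise_sigma: float = 0.0,
               seed: int | None = None) -> SweepResult:
    """Error vs cell diameter at fixed simulation-volume extent."""
    diameters = list(diameters_wl)
    if any(d >= volume_extent_wl for d in diameters):
        raise ValueError("cell diameter must be smaller than the volume extent")
    grid_size = int(round(volume_extent_wl * wavelength_px))
    make = make_cell_phantom_2d if dims == 2 else make_cell_phantom_3d
    phantoms = [make(grid_size, wavelength_px,
                     replace(PhantomSpec(), diameter=d)) for d in diameters]
    geom = phantoms[0].geometry
    meta = dict(variable="diameter_wl", grid=grid_size,
                wavelength_px=wavelength_px, seed=seed,
                noise_sigma=noise_sigma, n_angles=n_angles)
    return _sweep(diameters, phantoms, geom, approximations, noise_sigma,
                  seed, meta)
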