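# Methods

## Physical model and conventions

The package works in grid-native units: all lengths in detector pixels
(pixel pitch ≡ 1), angles in radians, and the vacuum wavelength λ supplied
in pixels.  Arrays are indexed `(z, x)` in 2D and `(z, y, x)` in 3D; the
incident plane wave travels along +z with time convention `exp(+i k_m z)`,
the specimen rotates about y, and the rotation axis passes through index
`N // 2` on every axis (exact for even and odd N).  Detector fields are
stored background-normalized (u/u₀), so an empty field of view is
identically 1.

The scattering potential is `f = k_m² [(n/n_m)² − 1]` with
`k_m = 2π n_m / λ`.  Within first-order scattering the detector spectrum of
the scattered field at distance `l_D` from the rotation center is

    b̂(k⊥) = i/(2γ) · e^{i(γ−k_m) l_D} · f̂(k⊥, γ − k_m),
    γ = √(k_m² − k⊥²),

with evanescent components (k⊥ ≥ k_m) set to zero — an ideal field sensor
with numerical aperture 1.  Measurements refocused numerically to the
specimen center correspond to `l_D = 0`; the geometry carries `l_D`
explicitly and defaults to 0, since applying the angular-spectrum
propagator to data recorded behind the specimen reproduces exactly the
`l_D = 0` form of the equation above.

## Forward simulation

`born_forward` evaluates the Ewald-arc sample by rotating the object into
the illumination frame (real-space, linear interpolation), taking the
transverse FFT per depth slice, and summing the axial nonuniform DFT
exactly — there is no Fourier-domain interpolation in the forward
direction.  `rytov_forward` exponentiates the Born prediction,
`u/u₀ = exp(b)`, producing fields that satisfy the Rytov linearization
exactly; in the weak-scattering limit (|b| ≤ 10⁻³) Born and Rytov data
coincide to 10⁻⁶, which is asserted in tests.  `radon_forward` integrates
the refractive-index excess along straight rays.  Optional detection noise
is circular complex Gaussian on u/u₀, seeded, off by default.

`born_forward_bruteforce` sums the free-space Green's function
((i/4)H₀⁽¹⁾(k_m r) in 2D, e^{ik_m r}/(4πr) in 3D) over all excited voxels.
It is O(N_detector · N_voxels) and serves as the convention-pinning oracle:
the fast and brute-force fields agree within 1% relative L2 on 32–64 px
grids.  The residual lives almost entirely in grazing modes just below the
NA = 1 cutoff, where the 1/γ weight amplifies the k-space quadrature error;
generous padding (factor 4) keeps it below the 1% budget.

## Backpropagation

The discrete inversion accumulates, per angle: 1D/2D FFT of the (padded)
data, multiplication by the ramp filter and the depth kernel
`e^{i(γ−k_m)(z′−l_D)}` with the NA = 1 low-pass, inverse FFT per depth,
rotation of the contribution into the laboratory frame, and averaging over
angles with the analytically derived constant `−i k_m / N_angles` (which
absorbs the angular quadrature weight Δφ/2π, the Jacobian `k_m|k_x|/γ` of
the arc parametrization — whose `γ` cancels against the `i/2γ`
Green's-function weight — and the factor ½ for the double Fourier coverage
of a 360° turn).  In 3D the ramp is `|k_x|` only, because a single rotation
axis adds no `k_y` density; γ depends on both detector frequencies.

Two numerical choices matter:

- **Ramp filter.**  The naive `|k|` grid filter has a zero DC bin and
  biases the recovered contrast low by O(1/N) (weak-disk calibration ratio
  0.90 at N = 48).  The band-limited discrete ramp (DFT of the exact
  Nyquist-limited impulse response, the Ram-Lak construction) removes the
  bias; the weak-scattering calibration ratio is 0.96–0.98 across grid
  sizes and dimensionalities, inside the asserted [0.95, 1.05] band.  The
  same filter is used in filtered backprojection (weight Δφ/(4π) for the
  360° double-coverage form, divided by k₀, plus n_m).
- **Padding.**  Detector axes are zero-padded to
  `next_fast_len(2N)` before filtering and cropped after inversion,
  suppressing wrap-around of the convolution-like steps.  Padded lengths
  equal the next power of two for power-of-two N.

Per-angle accumulation uses real-space rotation with linear interpolation
about the fixed grid center, not Fourier regridding; rotations are the
dominant cost for 3D volumes.  The reconstruction `f` is complex; metrics
and refractive-index maps use `Re n` with
`n = n_m √(1 + f/k_m²)` (radicand clamped at 0 and the affected voxel
count reported).

## Preprocessing

Angular-spectrum propagation splits off the constant background (median of
the border pixels), propagates it analytically as the DC plane wave, and
zero-pads only the compact residual — otherwise the amplitude step at the
pad boundary rings through the window and corrupts the autofocus metric.
Autofocus minimizes Σ|∇|u|| (forward differences) over a 50-point coarse
grid followed by bounded scalar refinement to λ/100; a multi-minimum
metric sets a warning flag and returns the global grid minimum.  Recovery
of known defocus is accurate to ~λ/500 on smooth fields, asserted at λ/50.

Phase unwrapping for 3D sinograms uses the reliability-sorted,
noncontinuous-path 2D algorithm (via scikit-image), with the per-pixel
second-difference reliability map and the 2×2-plaquette residue count
exposed for diagnostics; 2D sinograms use cumulative 1D unwrapping along
the detector, so the known 1D breakdown for very large specimens is
reproducible.  The global 2π multiple is fixed by forcing the median
border phase into (−π, π], on the assumption that border pixels see
background.  Tie-breaking among equal reliabilities follows the engine's
stable order.

## Error metrics

E_RMS and E_TV both normalize by Σ(n_ph − 1)² over the inscribed
circle/sphere of radius N/2 (only that region receives contributions from
every projection).  The TV gradient uses unit-pixel spacing and
`np.gradient` (central differences, one-sided at edges): with this
convention a linear ramp has an exact gradient at every pixel, so the
analytic anchor — E_TV = 100% when the averaged TV norm equals the squared
phantom contrast everywhere — holds exactly, including for masks touching
the grid boundary.  Gradients are evaluated on the full grid before
masking to avoid artificial mask-edge gradients.  The shared normalization
makes 2D and 3D errors directly comparable; on matched phantoms the Rytov
E_RMS values agree within 5 percentage points.

## Phantoms

The three-compartment cell phantom uses literature refractive indices
(medium 1.333, cytoplasm 1.365, nucleus 1.360, nucleolus 1.387) and a
default diameter of 17 λ.  The published source fixes only the nucleolus
position (2λ, 2λ, 2λ from the center) and the outer diameter; the internal
geometry here is a repository convention, configurable in `PhantomSpec`:
nucleus semi-axes (0.6a, 0.5a, 0.5a) offset (−0.1a, 0, +0.08a) in
(x, y, z), nucleolus radius 0.10a.  (A 0.12a nucleolus at the fixed center
would protrude from this nucleus in 3D, violating strict nesting, hence
0.10a.)  The nucleolus center scales with the diameter so phantoms remain
self-similar in size sweeps.  Rasterization assigns each voxel the value of
the innermost compartment containing its center — a piecewise-constant
ground truth with no anti-aliasing, so tolerances of geometric tests
account for one-pixel edge jitter.  The contrast series interpolates
cytoplasm/nucleus/nucleolus linearly from (1.334, 1.334, 1.334) to
(1.455, 1.435, 1.543) at fixed medium 1.333.

## What the generator emulates — and what it does not

The simulated sinograms stand in for rigorous electromagnetic (FDTD)
simulations of a rotating cell.  They share the acquisition geometry
(dense, equispaced full-view projections, centered rotation axis,
background-corrected refocused fields, NA = 1) but are scalar and
first-order-consistent: `rytov_forward` data are *exactly* invertible by
the Rytov pipeline up to discretization, so absolute error levels here are
much lower than against independent full-wave data, and noise-free by
default.  Passing tests therefore demonstrate correctness and internal
consistency of the reconstruction algorithms and the qualitative orderings
(Rytov ≤ Born, Rytov ≤ Radon; errors growing with contrast and size), not
absolute error percentages against real measurements.

One consequence is quantitative: the plateau of the error-vs-projection-
count curve tracks the angular Nyquist requirement, roughly (π/2) × the
object size in pixels.  At the desk scale used here (17 λ cell at λ = 4 px
→ 68 px object, 128-px grid) the sweep settles at 100 projections, whereas
the same 17 λ cell sampled on a fine FDTD grid with coherent noise settles
near 160.  The sweep machinery, the 1 pp settling rule ("smallest sampled
count from which every successive change of both metrics stays below
threshold") and the conditions are fixed; the onset value scales with the
rasterization.

## Problem sizes

Default study sizes: 2D, 128-px grids with λ = 4 px and 200 projections;
3D, 48–64-voxel grids (a 12 λ cell on 64³ for the ordering and
dimensionality-comparison studies, since 17 λ at λ = 4 px does not fit a
64-voxel volume).  The full-scale 2D size sweep (volume extent 172 λ, cell
diameters up to ~100 λ, where 1D unwrapping eventually breaks down) is
available through `sweep_size` with larger extents but is not part of the
default presets.

## Known limitations

- Single-axis rotation leaves the missing-apple-core region of the object
  spectrum uncovered; 3D reconstructions are blurred along y near the
  rotation axis.  No regularization or artifact minimization is provided.
- Grazing spatial frequencies near the NA = 1 cutoff carry the largest
  forward-model discretization error (1/γ amplification).
- The Born inversion degrades with total phase delay, the Radon inversion
  with diffraction; both behave as expected but are provided as baselines,
  not recommended reconstruction paths.
- Sinograms must be equispaced over the full turn with a centered rotation
  axis; alignment and phase retrieval are upstream of this package.
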