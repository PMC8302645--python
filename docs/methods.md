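# Methods

This note documents the models, conventions and numerical choices behind
`crystalcal`, and what the synthetic tests do and do not demonstrate.

## Coordinate and unit conventions

Arrays are (Z, Y, X) with Z the optical axis, slowest-varying; physical
units are nanometres except cell heights (µm) and wavenumbers (cm⁻¹).
Voxel centres sit at `index × voxel + origin`.  The crystal growth
direction is Y.

## Crystal geometry

`LatticeSpec` describes hexagonal (111) layers stacked along Z:

- In-plane, an ideal hexagonal lattice with one nearest-neighbour (NN)
  direction along Y is built and its Y coordinates are scaled by an affine
  factor so that (a) the growth-axis NN distance equals `nn_growth` and
  (b) the growth/oblique NN distance *ratio* equals `compression`.
  `compression` is deliberately defined as the observable distance ratio —
  the quantity a tomographic analysis of such crystals reports — rather
  than the raw affine factor; the two differ because an affine Y-scaling by
  c changes oblique bonds too (an affine 0.96 yields only a 3.05 % distance
  anisotropy, while `compression=0.96` here yields exactly 4 %).  The
  internal affine factor is c·√(3/(4−c²)).
- Layers are stacked at the close-packing spacing √6/3 × `nn_growth` using
  the A/B/C offsets.  Stacking is either explicit or generated as random
  hexagonal close packing: the ABC cycle direction reverses per layer with
  probability `fault_prob` (one-parameter rhcp).
- Layer grids are de-sheared (row indices shifted) so each layer fills an
  approximately rectangular region; interior-particle selection can then
  use simple bounding-box margins.

The exact deformation mode of real vertically deposited crystals (affine
vs bond-selective) is not established; the affine model is the simplest
consistent choice and only the NN-distance ratio is asserted by tests.

## Optical kernels

The focal intensity patterns are low-order phenomenological models, not
diffraction integrals (out of scope):

- confocal / effective-STED PSFs and the excitation reflection pattern:
  anisotropic 3D Gaussians parameterised by lateral and axial FWHM;
- 2D-STED depletion doughnut: I(r) ∝ (r²/w²)·exp(−2r²/w²) laterally,
  Gaussian axially (exact null on axis);
- Z-STED depletion "bottle": two axially displaced Gaussians at
  ±`lobe_sep`/2 with top/bottom peak ratio `lobe_asymmetry` (a
  phenomenological stand-in for depth-induced spherical aberration),
  Gaussian laterally.

Kernels are evaluated on the voxel grid over ≥ 4 FWHM per axis and
normalised to unit sum.  Defaults follow the characterised modes of the
physical sample: confocal axial FWHM ≈ 600 nm, Z-STED ≈ 300 nm, lateral
≈ 230 nm.

## Rendering

Each core is a solid sphere of its core diameter (45 nm fluorescent, 80 nm
gold).  Rasterisation is partial-volume: fill fractions come from
sub-voxel sampling whose density adapts per axis (≥ ~16 samples across the
diameter, capped at 48 per voxel), because a fixed coarse grid quantises
the deposited mass of cores smaller than a voxel.  The sphere is
rasterised voxel-aligned and the residual sub-voxel offset applied as a
linear-interpolation shift; this preserves the centre of mass even when
the whole core fits inside one voxel (otherwise layer positions snap to
the grid and bias the axial fit by up to half a voxel).

Refractive-index mismatch enters as a single multiplicative axial scaling
factor s: true = apparent × s, so rendering maps z → z/s before
rasterisation.  Depth-dependent (nonlinear) scaling is out of scope and
the reports flag s as a constant-factor approximation.

Noise is Poisson on `photons_per_unit × intensity` (output in counts)
followed by additive Gaussian read noise; all randomness is explicit-seed
`numpy.random.default_rng`.

## Lateral calibration

A Hann window is applied before the 2D FFT (edge leakage otherwise biases
first-peak fits on small slices) and the power spectrum is blurred by 1 px
(configurable), matching the common practice for such measurements.
First-peak search runs along the scan-axis frequency profiles through the
origin: within [0.5×, 2×] an expected frequency when configured, otherwise
the first local maximum above both 5× the median spectral floor and 20 %
of the strongest non-DC value (the PSF envelope makes the fundamental the
strongest lattice peak, so the amplitude guard rejects leakage shoulders
without skipping it).  The ±f peak pair is refined by unweighted Gaussian
least squares over ±3 bins and averaged; Δ = 1/f with the fit sd
propagated first-order.  Fits are performed on the frequency axis (the
alternative — real-space profiles — is equivalent at this precision).

With growth along Y, alternating rows project to a Y period of
`nn_growth`/2 (hence σ_eff = 2·Δ_Y), while the X period is the row spacing
√3/2 × the *ideal* NN distance — compression does not shrink X, which is
why Δ_X is slightly larger than √3·Δ_Y.

## Axial calibration

The Z profile is the per-plane mean; peaks above 10 % of the dynamic range
are refined by Gaussian fits over ±(pitch/3).  Peak positions are fitted
linearly against layer index (rank order, with missing layers re-indexed
by rounded multiples of the median gap).  The outermost peaks see the tail
of only one neighbour and are pulled inward by ~10–15 nm at realistic peak
overlap; `calibrate_axial` therefore drops them when at least six peaks
remain.  The reported spacing uncertainty is the OLS slope standard error.

The physical workflow profiles a deconvolved stack; a raw confocal axial
FWHM of 600 nm would leave ~0.2 % layer contrast at a ~448 nm period,
which no profile fit can use.  The synthetic end-to-end checks therefore
render with an effective axial FWHM of 300 nm (the sharpened, deconvolved
or STED-like case); peak positions on any symmetric-PSF stack are
unbiased, which the recovery tests confirm.

## Axial scaling factor

The chain is: h_true from Fabry–Pérot fringes; stage miscalibration
m = h_empty/h_true − 1; corrected filled height h_filled/(1+m); and
s = h_true/h_corrected.  Fringe frequency is the periodogram peak refined
by maximising the continuous DTFT magnitude between neighbouring bins; the
sd follows the single-tone Cramér–Rao bound with the residual noise after
subtracting the fitted cosine.  The fringe model is two-beam cosine
interference, I(ν) = A(1 + V·cos(4πnhν)); only the fringe period carries
height information, so finesse effects are ignored.  Uncertainties are
propagated first-order and verified against a 10⁵-draw Monte Carlo within
10 % of the sd.  Note the full-precision chain for the reference inputs
(94.257/98.0/99.9 µm) gives s = 0.9810; reports round to 3 decimals.

## PSF extraction

Detection: local maxima above mean + 5 sd (configurable); shot noise can
split one bead into adjacent maxima, so maxima within 500 nm of a brighter
one are merged first; then candidates closer than `min_separation`
(default 1.5 µm) to another are both removed, and candidates within
`margin` (default half the extraction box) of a face are removed.  These
defaults quantify the qualitative "well separated, away from boundaries"
criteria and are documented rather than asserted.

Averaging aligns each subvolume by its intensity-weighted 5³-voxel
centroid using cubic-spline shifts (linear interpolation adds ~v²/6 of
variance per axis — several percent of lateral FWHM on 45–60 nm voxels).
The average is deconvolved by a partial-volume rasterised sphere of the
known 45 nm core with a Wiener filter, W = S*/(|S|² + ε·max|S|²),
ε = 10⁻³ by default; the result is clipped at zero, re-centred on its
maximum and unit-normalised.  FWHMs come from linear interpolation of the
half-maximum crossings of the axis profiles through the global maximum.

Z-STED lobe balance is the top/bottom peak ratio of the Z profile through
the lateral centre; collar optimisation brackets log(ratio) = 0 over the
collar range and solves it with Brent's method.

## Structure classification

`boop` computes Steinhardt q_l (l ∈ {4, 6}, 12 nearest neighbours) in both
the plain and the Lechner–Dellago neighbourhood-averaged form
(q_lm averaged over the particle and its neighbours before the rotation
invariant).  Reference values for perfect FCC (q4 = 0.1909, q6 = 0.5745)
and HCP (0.0972, 0.4848) are generated at first use from internal perfect
lattices rather than hard-coded, making classification immune to
spherical-harmonic normalisation conventions.

Classification assigns each particle to the nearest reference in the
(q4, q6) plane using the **plain** parameters: in a stacking-faulted
crystal every interior particle's 12-neighbour environment is exactly
FCC-like or HCP-like, so the plain invariant separates them cleanly,
whereas the averaged form mixes ~6/13 of a foreign environment into
particles whose both sandwich layers are of the other type and pushes them
across any boundary (an accuracy ceiling of ~97 % at 20 % fault
probability).  The averaged invariants remain available for noisy data.
Particles farther than 0.15 from both references, or with fewer than 8
neighbours, are labelled "other".

Bond anisotropy bins in-layer NN bonds by angle to the growth axis (≤ 15°
→ growth class) and reports 100·(1 − mean_growth/mean_oblique); layer
linearity clusters Z by the largest-gap rule and regresses mean layer
height on index.

## Problem sizes in the test suite

The end-to-end recovery uses an 8-layer, ~10 × 10 µm crystal rendered at
(100, 45, 45) nm voxels with ~400 peak counts (SNR ≈ 20); PSF round trips
use 12 beads per mode in a 4 × 8 × 8 µm volume at (50, 45, 45) nm voxels;
the rhcp classification ensemble uses 50 seeded 8-layer crystals; the
sparse-packing ratio check places 85 100 spheres in a (26 µm)³ box.  These
sizes give sub-percent statistical errors on every asserted quantity while
keeping the default suite lightweight.

## What the synthetic data does not show

The generator emulates geometry, optics and shot noise, not everything a
real sample exhibits: no particle polydispersity inside crystals, no grain
boundaries or drift, Gaussian PSF approximations instead of measured
aberrated patterns, a depth-independent scaling factor, and no bleaching
or background fluorescence.  Passing tests demonstrate the correctness of
the analysis chain under its stated model, not the performance on any
particular microscope.
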