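# Methods

This note documents the physical model, the numerical choices, and the
limits of what the bundled tests demonstrate.

## Phasor conventions and material model

All fields are time-harmonic phasors under the engineering `e^{+jωt}`
convention. A lossy dielectric has ε_c = ε₀ε_r − jσ/ω; the wavenumber
k = ω√(με_c) is taken on the branch Re k > 0, Im k < 0, so outgoing waves
`e^{−jkr}` decay whenever σ > 0. Tissue is non-magnetic (μ_r = 1)
throughout. SI units everywhere: positions in meters, moments in A·m²,
fields in V/m and A/m.

The dielectric table (`data/tissue_properties.csv`) lists ε_r and σ for
Brain, Skull, Muscle, Blood and Fat at 100 MHz, 1 GHz and 10 GHz. Between
rows the properties are interpolated log–log linearly (dispersion is smooth
on log axes); outside [100 MHz, 10 GHz] lookup refuses rather than
extrapolates. Full Cole–Cole/Debye dispersion and temperature dependence
are out of scope; users can override the table with a same-schema CSV.

Two penetration depths are deliberately exposed, because at microwave
frequencies tissue has loss tangent σ/ωε ≈ 0.1–1 — neither a good
conductor nor a good dielectric:

* `skin_depth_conductor`: δ = 1/√(πμσf), the classical good-conductor
  form (Brain at 1 GHz: 1.39 cm);
* `skin_depth_general`: 1/α with the exact attenuation constant
  α = ω√(με/2)·√(√(1+(σ/ωε)²) − 1) (Brain at 1 GHz: 2.91 cm), which is the
  decay constant the fields actually obey and the one used in all decay
  assertions.

The two agree within 1 % once σ/ωε ≳ 100. Neither reproduces some skin
depth figures quoted informally in the literature for brain tissue
(e.g. 4.1 cm at 1 GHz); those evidently derive from a different parameter
set, so no constant in this package is forced to match them.

## Analytic dipole fields

The closed-form E and H of a point magnetic dipole in an unbounded
homogeneous medium (the full near/intermediate/far expansion with complex
k) are the analytic dyadic Green's function used everywhere a homogeneous
medium is assumed. Correctness is established by oracles rather than by
inspection: fourth-order finite-difference curls verify both Maxwell curl
equations at random points to ~1e-11 relative, an independently coded
electric-dipole field verifies E–H duality (E of moment m equals −η times
the H of the dual current element jk·m), and the H-dyadic satisfies
reciprocity Ĝ(r₁,r₂) = Ĝ(r₂,r₁)ᵀ to round-off.

Evaluation inside a configurable exclusion radius of a source raises an
error; silently clipped singular values would corrupt the optimization
matrices built from these fields.

## Volume-integral-equation forward solver

Heterogeneous phantoms are handled by the electric-field volume integral
equation with the tissue as contrast χ = ε_c/ε_bg − 1 over an air
background: E = E_inc + k_bg² ∫ Ĝ_bg χ E dV′. On a uniform cell-centered
voxel grid the operator is a discrete convolution applied via zero-padded
FFTs (O(N log N) per application); the self-voxel uses the classical
equivolume-sphere correction

  ∫_V₀ Ĝ dV = [ (2/3k²)((1+jka)e^{−jka} − 1) − 1/(3k²) ] I ,  a = (3ΔV/4π)^{1/3},

whose −1/(3k²) term carries the static depolarization (the k→0 limit
reproduces E_in = E₀/(1+χ/3) for a dielectric sphere). The linear system
is solved by BiCGSTAB (LGMRES fallback) from the zero vector with a
relative-residual tolerance, so solutions are reproducible at fixed tol;
non-convergence raises with the residual history attached. H is recovered
from E by discrete curl (central differences, one-sided at faces) divided
by −jωμ.

A Born series would diverge at brain-like contrast (ε_r ≈ 49, σ ≈ 1.3 S/m),
which is why the full VIE is used; the first Born approximation is instead
implemented independently (direct summation, no FFT, no iteration) as a
*test oracle* at χ ~ 1e-3, where the two must and do agree within 1 %.
Zero-contrast phantoms recover the analytic incident field to solver
tolerance exactly.

Grid resolution: 2.5 mm is the production default (≈17 points per brain
wavelength at 1 GHz); the test suite mostly runs 5 mm for speed. The
high-contrast validation (interior decay of a 5 cm brain sphere lit by a
1 cm-offset dipole) is resolution-sensitive: after removing 1/r spreading,
the fitted interior e-folding length at 2.5 mm is within 15 % of the
2.91 cm attenuation length, while at 5 mm the discretization error at
~8.6 points per wavelength inflates the discrepancy to ~20 %. The bundled
test therefore runs this one check at 2.5 mm (solver tol 1e-3, ~1–2 min);
all other solver tests are seconds.

Numerical Green's tables store 3 unit-moment solves per transmitter
(3N_t field grids) in HDF5 and reconstruct the field of any moment
assignment by linearity (verified against direct solves within 2·tol).

## Array geometry

"Uniformly distributed" transmitters are made deterministic: a Fibonacci
lattice on spheres (its minimum pairwise angular separation beats the
median of random placements; a single element goes to the +z pole by
convention) and ring grids on cylinders (rings = the largest divisor of
the count ≤ √count; rings are azimuthally offset by half a step
alternately; prime counts > 4 are rejected with suggestions). The array
surface radius is phantom outer radius + standoff, default standoff 1 cm.
Each element carries an orthonormal (r̂, θ̂, φ̂) triad — (ρ̂, ẑ, φ̂) on
cylinders — used to report moment solutions in surface-adapted components;
θ is declination from +z in [0°, 180°], φ azimuth in (−180°, 180°].

## Focusing optimization

Stacking is per-point [Ex, Ey, Ez] in row-major grid order and
per-transmitter [mx, my, mz]; all vectors are columns. The normal
equations (G_EᴴG_E + αI)M = G_Eᴴ E_d are solved by Cholesky factorization
of the Hermitian positive-definite matrix (problem sizes stay at a few
hundred columns, so no iterative solver is needed); the normal-equation
residual is below 1e-10 relative on every solve, and α = 0 is allowed only
for numerically full-rank systems. An independent gradient-descent
minimizer of the objective confirms the closed form to 1e-8 relative on
random small systems.

The misfit is evaluated over the *entire tissue interior* on a uniform
grid (default 4 mm), with E_d ≈ 0 outside the hotspot — fringe fields must
be penalized for sidelobe suppression, not just hotspot mismatch. The
default regularization is the fixed-relative rule α = τ·s_max² with
τ = 1e-3; an L-curve (maximum curvature over a log-α grid) is available.
For the canonical 64-element brain-sphere scenario the solution is nearly
α-independent over τ ∈ [0, 1e-2]: the focal shape is set by the physics,
not the regularizer.

Desired-profile targets are a 3D Gaussian (amplitude
peak·exp(−‖r−c‖²/2σ_g²) along a fixed polarization; FWHM 2√(2 ln 2)σ_g)
or a uniform sphere. Steering re-solves with a shifted profile against the
cached system matrix.

## Metrics

All diagnostics use the field amplitude |E|, not intensity |E|² (an
intensity FWHM would be √2 narrower), and are invariant to global scale
and global phase. FWHM is measured on a line profile through the focus:
the local maximum nearest the focus, half-max crossings located by linear
interpolation, NaN sentinel if a crossing never occurs inside the grid.
Profiles are sampled either through an exact analytic evaluator (the
superposed dipole fields of a solution — the accurate path, used by the
pipeline in analytic mode) or by linear interpolation of stored grid
samples. Contrast at distance d is reported two ways, since "d cm away"
is direction-ambiguous: the shell mean over |‖r−focus‖ − d| ≤ half a cell,
and the mean of the two points ±d along the named cut. Neighbor phase
statistics (per-axis phase differences between nearest-neighbor elements,
wrapped to (−π, π]) exclude elements below 1 % of the maximum moment
magnitude — most elements of an optimized array are nearly dark and their
phase is meaningless.

## Phantoms

Voxelization classifies voxels by center point (no partial-volume mixing):
deterministic, and labeled volumes converge to analytic volumes as the
spacing shrinks (within 2–3 % at 2.5 mm for the bundled geometries). The
layered head is brain (3.2 cm radius) / skull (1 cm) / skin-like shell
(0.8 cm); the limb is bone (1 cm radius) / muscle (2 cm) / outer tissue
(2 cm) over a 20 cm length. The dielectric table has no "skin", "tissue"
or "bone" rows, so by default skin → Muscle, limb outer tissue → Fat
(standing in for skin plus adipose tissue) and bone → Skull; all three
mappings are explicit arguments and can be overridden.

## What the solver modes do and do not show

The `analytic` pipeline mode treats the whole space as the phantom's
innermost material: Green's functions are exact and assembly takes
seconds, but there is no air standoff and no tissue–air interface. Two
consequences matter when comparing against boundary-aware simulations of
a bounded tissue body:

* Near the phantom surface the unbounded mode contains the transmitters'
  unscreened near fields (each source is only ~1 cm away through lossy
  medium), so the optimizer sees — and partially trades the focal
  amplitude against — strong fringe fields there. In a bounded body the
  ε_r ≈ 49 : 1 interface suppresses the interior near-surface field, the
  effective aperture weighting is more uniform, and sidelobe contrast is
  higher.
* Off-center targets sit closer to part of the array with a shorter lossy
  path, so in the unbounded mode steered foci come out *stronger* than a
  central focus and their cuts ride a shoulder rising toward the near
  surface. In a bounded sphere, interface refraction/aberration penalizes
  off-axis focusing and steered foci come out weaker than center.

The central focal *width* is robust to all of this: 2.41 cm on the
diagonal cut for the 64-element brain scenario, independent of α, of the
misfit region, and of replacing the optimizer by pure phase conjugation
(time reversal) — and matching the 2.43 cm of an ideal lossless
full-aperture z-polarized plane-wave focus at λ ≈ 4.3 cm. It is the
diffraction limit of the configuration. Peak-to-sidelobe quantities and
steering asymmetries, by contrast, are boundary-sensitive and should be
computed with the VIE mode when they matter; the VIE route costs 3
full-grid solves per transmitter, which is why the fast acceptance
pipeline uses the analytic mode and reports its boundary-free numbers
as such.

The synthetic scenarios emulate idealized tissue (piecewise-homogeneous,
isotropic, dispersion-free at a single frequency, point-dipole antennas
with no feed or matching network). Passing tests therefore demonstrate
the correctness of the propagation/optimization machinery under those
assumptions — not the clinical attainability of the hotspots; anatomical
realism, antenna engineering, SAR/thermal dose and neural response are
out of scope.

## Determinism

The production path has no randomness: placement lattices, voxelization,
kernel construction and the Krylov iteration (zero start vector, no
restarts) are all deterministic, so repeated runs produce byte-identical
solution vectors. Monte-Carlo comparisons and randomized property tests
carry fixed seeds or derandomized hypothesis profiles.
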