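# mwfocus

Three-dimensional microwave focusing inside lossy biological tissue.

`mwfocus` is a planning/simulation toolkit for synthesizing a localized,
sub-centimeter electric-field "hotspot" deep inside tissue (brain, limb)
using an array of small loop antennas modeled as point magnetic dipoles.
It is aimed at computational bioelectromagnetics work on non-invasive
neural stimulation and hyperthermia-style treatment planning: given a
tissue phantom, an array layout, an operating frequency and a desired field
profile, it computes the transmitter-to-field Green's functions
(analytically in homogeneous media, numerically for heterogeneous voxel
phantoms) and solves for the complex dipole moments that best realize the
prescribed hotspot — including electronic steering of the focus and
quantitative focusing metrics.

## The model

Each transmitter *n* is an infinitesimal magnetic dipole at **r***ₙ* with
complex moment **m**ₙ (A·m², phasors, `e^{+jωt}` convention). Fields map
linearly through dyadic Green's functions; the total magnetic field is

  **H**(**r**) = Σₙ **Ĝ**(**r**, **r**ₙ) **m**ₙ

and likewise for **E** through the electric dyadic. Stacking the electric
field at *N_d* interior grid points and the *N_t* moments gives the linear
system **E**ₘₒ𝒹 = **G**_E **M** with **G**_E of size (3*N_d* × 3*N_t*). The
moments are chosen by Tikhonov-regularized least squares,

  ΔE(**M**) = ‖**G**_E **M** − **E**_d‖² + α‖**M**‖² ,
  **M**ₒₚₜ = (**G**_Eᴴ **G**_E + αI)⁻¹ **G**_Eᴴ **E**_d ,

where **E**_d is the desired profile (e.g. a z-polarized 3D Gaussian of
standard deviation σ_g = 1 cm and peak 0.01 V/m) and α stabilizes the
inversion (`choose_alpha` implements a fixed-relative rule
α = τ·s_max(**G**_E)² and an L-curve scan). Steering the hotspot is a
re-solve with a shifted **E**_d reusing the same **G**_E.

Wave propagation in tissue is governed by the complex permittivity
ε_c = ε₀ε_r − jσ/ω. The package ships a dielectric table (Brain, Skull,
Muscle, Blood, Fat at 100 MHz / 1 GHz / 10 GHz, log–log interpolated in
between) and exposes the derived quantities: in-medium wavelength
λ = 1/(f√(με)), the good-conductor skin depth δ = 1/√(πμσf), and the exact
lossy-dielectric decay length 1/α with
α = ω√(με/2)·√(√(1+(σ/ωε)²) − 1).

For heterogeneous phantoms (layered head sphere, layered limb cylinder)
the Green's functions have no closed form; `mwfocus.forward_solver`
computes them with an FFT-accelerated volume-integral-equation (VIE)
scattering solver over a voxel grid, verified against the analytic fields
(zero contrast) and a first-Born oracle (weak contrast).

## Worked example

Config (`example.yaml`) — the canonical scenario: a homogeneous 5 cm
brain-material sphere, 64 dipoles on a 6 cm sphere (1 cm standoff), 1 GHz,
z-polarized 1 cm Gaussian hotspot at the center:

```yaml
phantom: {kind: homogeneous-sphere, radius: 0.05, material: Brain}
frequency: 1.0e9
array: {surface: sphere, count: 64, standoff: 0.01}
target: {profile: gaussian, center: [0, 0, 0], sigma: 0.01, peak: 0.01,
         polarization: [0, 0, 1]}
solver: {mode: analytic}
grid_spacing: 0.004
alpha: {strategy: fixed-relative, tau: 1.0e-3}
```

```
$ mwfocus focus example.yaml
peak |E| = 0.0007452 V/m at [0. 0. 0.]
FWHM (diagonal) = 2.410 cm
contrast (shell_2cm) = 2.581
contrast (diagonal_2cm) = 3.200
```

Reading the output: the realized focus lands exactly on the requested
center; its full width at half maximum along the (x̂+ŷ)/√2 diagonal is
2.41 cm — essentially the diffraction limit for a z-polarized full-aperture
focus at λ_brain ≈ 4.3 cm, and close to the 2.36 cm FWHM of the requested
σ = 1 cm Gaussian. The peak amplitude is ~7.5 % of the requested 0.01 V/m:
with the misfit evaluated over the whole interior, the optimizer trades
absolute level against fringe-field suppression, and by linearity all
moments can simply be rescaled to reach any desired absolute peak. The two
contrast figures are the peak-to-surroundings ratio 2 cm away (spherical
shell mean, and the two points on the diagonal cut).

Material properties for any tabulated tissue:

```
$ mwfocus props --material Brain --points 3 --out props.csv
frequency_hz,eps_r,sigma_s_per_m,skin_depth_conductor_m,skin_depth_general_m,wavelength_m
1e+08,89.8,0.79,0.0566248,0.0762977,0.316361
1e+09,48.9,1.31,0.0139054,0.0291071,0.0428713
1e+10,34.6,9.78,0.00160935,0.00328869,0.00509662
```

Other subcommands: `mwfocus steer` (multi-target sweep sharing one system
matrix), `mwfocus gf` (build/persist a numerical Green's table to HDF5),
`mwfocus metrics` (re-analyze an exported field). Fields export to legacy
ASCII VTK, solutions/manifests to JSON, metric tables to CSV.

The same pipeline is available as a library:

```python
from mwfocus import RunConfig, run_focus
cfg = RunConfig.from_yaml("example.yaml")
solution, field, report, manifest = run_focus(cfg)
print(report.fwhm_by_cut["diagonal"])   # 0.02410 (m)
```

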