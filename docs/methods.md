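# Methods

This note records the physical models behind `sonochamber`, the parameter
choices that matter, the numerical conventions, and what the package does
*not* claim.

## Scope and model chain

The package models a microliter-scale sonoporation chamber as a chain of
three weakly coupled problems:

1. a **free-field piston source** that sets the incident pressure and the
   focal geometry;
2. a **plane-layered stack** (bath | slide | sample gap | coverslip |
   backing) that filters that pressure on the way to the cells;
3. a **linearized microbubble** response at the delivered pressure.

The coupling is one-way: the focal pressure calibrated in step 1 scales the
unit-amplitude plane-wave solution of step 2, whose sample-plane peak feeds
step 3. This focal-zone plane-wave approximation is good when the stack sits
near the focus and the beam's angular spectrum is narrow compared with the
spacing of the critical angles; it ignores beam spread across the 1.2 mm
slide and any reverberation between transducer and slide.

## Materials

Each medium carries density, longitudinal speed, shear speed (0 for
fluids), and a power-law attenuation `α(f) = α₀ (f/f_ref)^n` tabulated in
dB/cm at `f_ref` = 1 MHz (1 dB/cm = 11.5129 Np/m). Defaults shipped in
`data/materials.csv`:

| material | ρ (kg/m³) | c_long (m/s) | c_shear (m/s) | α₀ (dB/cm @1 MHz) | n |
|---|---|---|---|---|---|
| water | 1000 | 1480 | 0 | 0.0022 | 2 |
| glass (borosilicate) | 2500 | 5600 | 3400 | 0.2 | 1 |
| polystyrene | 1050 | 2350 | 1120 | 0.35 | 1 |
| adiprene (polyurethane) | 870 | 1680 | 0 | 1.2 | 1 |
| polyethylene | 950 | 1950 | 540 | 1.0 | 1 |
| air | 1.204 | 343 | 0 | 1.6 | 2 |

Choices worth flagging:

* **Glass attenuation** is pinned at 0.2 dB/cm so that even a hypothetical
  10 mm glass path at 1 MHz loses ≤ 5% of the acoustic power
  (`1 − e^{−2αd}` = 4.50%). The literature on slide glass spans roughly
  0.05–0.5 dB/cm at 1 MHz; any value ≤ 0.22 dB/cm satisfies the same bound.
  Under this coefficient the actual 1.2 mm slide loses only 0.55% — i.e.
  attenuation is a minor effect next to interference and reflection, which
  is the design-relevant conclusion.
* **Adiprene** is fluid-modelled (soft polyurethane rubbers carry almost no
  shear at MHz) and pinned to ρ = 870 kg/m³, c = 1680 m/s, inside the range
  quoted for castable polyurethanes. This pair has impedance slightly below
  and speed above water, the configuration in which a fluid–fluid interface
  exhibits *both* a critical angle (61.8°) and an intromission angle
  (16.3°) — the canonical demonstration pair.
* Glass ships with internally consistent elastic moduli (K = 39.87 GPa,
  G = 28.9 GPa, E = 69.83 GPa): a record's bulk/shear moduli must reproduce
  its stored speeds to 0.1%, and `speeds_from_moduli` exposes the
  bulk-vs-bar distinction (extended solid vs thin slide) explicitly.
* Shear attenuation reuses the longitudinal dB/cm law; it only affects the
  oblique solid branches and no headline number is sensitive to it.

## Layered solvers

Conventions: time dependence `exp(+iωt)`, propagation along +z, complex
wavenumber `k = ω/c − iα(f)`, unit incident pressure, down-going amplitudes
referenced at their layer's top and up-going at the bottom (all stored
exponentials bounded). First and last layers are half-spaces; the last
carries no returning wave.

* `solve_normal` multiplies 2×2 pressure/velocity layer matrices
  (`cos kd`, `iZ sin kd`; `Z = ρω/k`) and back-substitutes the per-layer
  amplitudes. Solids are fluid-modelled here: at normal incidence mode
  conversion vanishes.
* `solve_oblique` assembles one global linear system over all partial-wave
  amplitudes: fluids carry a longitudinal pair, solids additionally a
  vertically polarized shear pair, with the lateral wavenumber
  `kx = k₁ sinθ` shared by every layer (Snell). Interface conditions:
  fluid–fluid `u_z, σ_zz`; solid–solid welded `u_x, u_z, σ_zz, σ_xz`;
  fluid–solid slip with `σ_xz = 0`. Rows are max-abs equilibrated; a
  condition number above 10¹³ triggers a 10⁻⁶-degree angle nudge with a
  warning (isolated layer-resonance poles, not physical regimes). Power
  fractions use the axial flux `½ρω³ Re(k_z)|φ|²` per branch, which is
  identically zero for evanescent branches; lossless stacks conserve
  `T + R = 1` to ~10⁻¹⁵ at every angle tested, including beyond both
  critical angles.
* `brute_force_five_layer` writes the eight boundary-condition equations
  of the five-layer fluid stack directly and solves them; it shares no
  code path with the transfer matrices and exists to cross-check them
  (agreement to 10⁻⁹ demanded over 1000 seeded random stacks).

Degenerate inputs: zero-thickness interior layers are elided (limit
consistency); an interior layer identical to its neighbours leaves the
lossless coefficients unchanged; reciprocity (reversed stack, equal lossless
power transmission) is tested.

The chamber-relevant result: at the 26.5° design angle — beyond both
water→glass critical angles (15.3°, 25.8°) — the sample still receives
0.56× the incident amplitude because the 1.2 mm slide is thin compared with
the evanescent decay lengths (1/|k_z| ≈ 0.7 mm longitudinal, 2.4 mm shear),
so both branches tunnel.

### Gap interference

`sample_amplitude_vs_gap` rebuilds the stack per gap L and reports the peak
|p| inside the sample layer (sampled on 101 z-points by default; the
sampling, not the solver, limits accuracy near 10⁻⁵ relative). In the
lossless normal-incidence case the pattern is exactly λ/2-periodic in L.
Because the air backing reflects near-totally regardless of wall material,
wall-material sensitivity must be judged over the interference pattern as a
whole: across a full λ/2 period the high-finesse glass cavity spans
amplitude ratios 0.22–17 (excursion ≈ 17) while polystyrene walls span
1.2–2.1 (≈ 0.85). Over the narrow 10–20 µm operating range (0.04 rad of
phase) both materials drift almost identically, so the package quotes the
operating-range excursion in the design report but performs the
material comparison over the full period. A fully homogeneous path (walls
*and* backing matched to the sample) is L-independent with ratio 1, the
degenerate check.

## Piston fields

On axis, the flat baffled piston uses the exact closed form; the focal
distance is located by a dense grid scan (1 µm default) plus bounded
refinement, landing within λ/4 of `a²/λ`. Off axis, the Rayleigh integral
over the piston face is evaluated with Gauss–Legendre (radial, default 48
nodes) × periodic trapezoid (azimuth, 64 nodes); the on-axis column
reproduces the closed form to ~10⁻¹⁴ and quadrature refinement is tested to
converge. Focused sources use the O'Neil spherical-cap expression on axis
(removable singularity at the curvature centre evaluated analytically as
`p₀kh`) and a thin-lens focusing phase over the disk for maps; the two
differ at the sub-percent level for the shallow caps considered.

The active element radius is nowhere printed for the hardware modelled, so
the default `a` = 9.43 mm is *inferred* from the nominal 6 cm focal
distance (`a²/λ = 60 mm` at 1 MHz in water); this inference is echoed in
every design report.

Focal metrics anchor on the **last** on-axis maximum above 90% of the
on-axis supremum — necessary because every near-field lobe of an ideal flat
piston reaches the same 2p₀ amplitude, and only the final lobe is the focal
spot. Length and width are −6 dB (half-pressure) extents, a recorded
convention since none is standard for this table; iso-areas are surfaces of
revolution of the `|p| = peak·(1−x)` contour component containing the peak
(the upper band edge `peak·(1+x)` never binds). Absolute iso-areas from a
bounded finite-element simulation (tube walls, reverberation) are *not*
reproduced by these free-field models and are not claimed; the claimed and
tested statements are the orderings — iso-areas strictly increasing with
band, and focused < flat for length, width, and every band — plus the focal
distance itself. With the small inferred aperture, weak focusing cannot
place the focused peak at exactly 60 mm (near-field structure dominates);
the default 62 mm curvature radius preserves every claimed ordering.

## Bubble response

The shelled-bubble resonance and its Minnaert limit are closed-form; the
radius inversion brackets with Brent's method over [10 nm, 100 µm]. Shell
defaults (γ = 1.07 perfluorocarbon-like gas, σ = 0.072 N/m, χ = 0.55 N/m)
are typical lipid-shell literature values, always overridable, and no
headline number depends on them; the report's default R₀ = 1.5 µm is a
typical contrast-agent mean radius. Note that for γ ≥ 1 the resonance
bracket is strictly positive, so the "no real resonance" error can only be
reached through the radius inversion running out of bracket. The MI uses
the kPa/√Hz convention, numerically identical to MPa/√MHz. Cavitation-regime
classification (stable vs inertial) is deliberately not implemented: the
regimes have no defensible single threshold here.

## Design pipeline

`evaluate_design` (1) solves the source amplitude so the free-field focal
peak equals the calibrated 500 kPa, (2) solves the five-layer stack at the
design angle, (3) reports the sample-plane peak, per-layer attenuation
(quoted along the layer normal), the standing-wave excursion over the
declared 10–20 µm gap range, and critical-angle verdicts, and (4) attaches
the bubble response and the ≥ 30 mL classical-bath comparison
(`ceil(πR²H)` with R and H as lower bounds). The 380 kPa transmitted-
pressure reference from the bounded finite-element characterization is
printed alongside the pipeline's own value with an explicit
model-difference note — the free-field + plane-wave chain is not expected
to and does not reproduce it (it yields ~280 kPa); the claimed property is
transmitted < free-field calibration. The 26.5° angle is treated as a
geometric design constant throughout: with the default constants it lies
just above the 25.8° shear critical angle, and the package deliberately
does not assert which named angle it "is".

## What the tests do and do not show

The synthetic stack generator draws lossless fluid media spanning three
orders of magnitude in impedance and thicknesses of 10 µm–10 mm,
deterministically per seed; it exercises the solvers' algebra (oracle
equivalence, energy conservation, reciprocity), not the realism of any
particular chamber. Passing tests therefore validate the wave algebra and
the pinned-constant pipeline, but say nothing about constants of a real
slide batch, transducer bandwidth, tube-wall reverberation, nonlinear
propagation, or bubble dynamics beyond the linear resonance — all out of
scope. Problem sizes in the shipped tests (1000 five-layer stacks, 1 µm
axial scans, ~100-point field maps and gap sweeps) were chosen as the
smallest that make the stated tolerances meaningful.
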