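# Methods

`acoustolev` models a bulk-acoustic-wave levitation chamber used to
concentrate 3D tissue spheroids on a single plane inside a hydrogel
before sectioning. This note documents the physical models, the
numerical choices, the synthetic-data generator, and the limits of
what the test-suite demonstrates.

## Chamber acoustics

The chamber is a fluid box of height *h* = 1.1 mm driven from below by
a 3×3 array of 2×2 mm² PZT units (pitch 2.4 mm) embedded in epoxy and
excited sinusoidally (default 60 V at 660 kHz). The fluid is the
PEGDA–gelatine precursor, acoustically water-like (>80 % water), so
the default medium is water at 25 °C (ρ = 1000 kg m⁻³, c = 1480 m s⁻¹).
The precursor and the cast gel grid are treated as one continuous
fluid: their impedance contrast is negligible, so the grid is not
represented geometrically.

The steady state obeys the Helmholtz equation ∇²p + k²p = 0 with
k = ω/c under the package-wide e^{−iωt} convention (velocity
v = ∇p/(iωρ)). Boundary conditions:

- **bottom** (z = 0): driven Neumann, ∂p/∂z = ρω²D(x, y), where D is
  the piecewise-constant displacement map of the array. Model A drives
  every unit at 1.15 nm V⁻¹ and the epoxy at 0.6 nm V⁻¹; model B grades
  the units by position (center 1.7, edge 1.2, corner 1.0 nm V⁻¹) to
  mimic the measured edge effect of a real array.
- **lid and side walls**: Robin impedance conditions ∂p/∂n = iωρp/Z
  with Z_top = 13 MPa s m⁻¹ (glass) and Z_side = 17 MPa s m⁻¹
  (aluminium). Walls are therefore strongly but not perfectly
  reflecting (|R| ≈ 0.8 at the lid).
- **mirror planes** (x = 0, y = 0): homogeneous Neumann; the default
  solve covers one quarter of the chamber and exploits the mirror
  symmetry of the stock drive maps.

The unprinted dimensions default to: chamber 10 × 10 mm laterally
(comfortably larger than the 7.2 mm array footprint) and a 2.4 mm
pitch (2 mm unit + 0.4 mm kerf); both are configurable.

### Discretization

Second-order central finite differences on a regular grid with
ghost-point closure of all boundaries; the complex sparse system is
factorised with SuperLU (minimum-degree ordering). The domain is a box,
so no FEM machinery is needed. Default resolution is
(dx, dy, dz) = (100, 100, 50) μm ≈ (λ/22, λ/22, λ/45): about 6×10⁴
quarter-domain unknowns, solving in tens of seconds on one CPU. The
solver refuses grids coarser than λ/10 laterally or λ/15 vertically.
A convergence study (`convergence_study`) confirms second-order
behaviour of the node height and <5 % drift of max |p| at the default
resolution.

Pressure nodes are located as interior minima of |p| along vertical
lines, refined with three-point parabolic interpolation; ties break
toward the smallest z. A finite-impedance field never reaches |p| = 0,
so "node" always means a local minimum.

### The 1D column oracle

`column.solve_column` solves the same physics analytically for a
laterally uniform piston: p(z) = A e^{ikz} + B e^{−ikz} with the
bottom/lid conditions above. The impedance-condition sign was
validated against the three limits with known answers (matched lid →
pure travelling wave of amplitude ρcωD; rigid lid → antinode at the
lid, node at h − λ/4; pressure-release lid → p = 0 at the surface).
The 3D solver reproduces the column solution to <1 % L2 when run with
a uniform map and sound-hard lateral walls; this is the main
cross-validation of the 3D code.

### Fidelity to the reference FEM values

With the stated drive (69 nm unit displacement), height, frequency and
impedances, both the closed-form column and the converged 3D solve
give max |p| ≈ 3.1–3.3 MPa and a central node at 514–539 μm: the
chamber sits close to its half-wave resonance (λ/2 = 1.12 mm vs
h = 1.10 mm) and the glass lid reflects ~80 % of the incident
amplitude. The reference FEM of the physical device reports a lower
peak (1.4 MPa) and node (450 μm); that model's exact lateral geometry,
any damping, and its mesh are not published, and our box model is
insensitive to the plausible ranges of the unknowns we probed (lateral
size 7.4–14 mm, grid refinement 200→30 μm). We deliberately report
the values our stated model produces rather than re-tuning unknown
geometry to match. Notably, the experimentally measured levitation
heights (510 ± 50 and 475–500 μm) bracket our predicted node.

## Radiation force

For a compressible sphere with radius a ≪ λ the time-averaged force is
F = −∇U with the standard Gor'kov potential

U = V [ f₁⟨p²⟩/(2ρc²) − (3/4) f₂ ρ⟨v²⟩ ],
f₁ = 1 − κ_p/κ_m, f₂ = 2(ρ_p − ρ_m)/(2ρ_p + ρ_m),

⟨·⟩ = |·|²/2 for complex amplitudes. The implementation is validated
to <1 % against the planar standing-wave closed form
F_z = 4πΦka³E_ac sin(2kz), Φ = f₁/3 + f₂/2, and obeys F ∝ V,
F ∝ (drive voltage)², and discrete curl(F) = 0.

The reference spheroid is 150 μm diameter, ρ_p = 1099 kg m⁻³, with a
tissue-like default compressibility κ_p = 4.0×10⁻¹⁰ Pa⁻¹ (the exact
measured value for fixed spheroids is not available; force magnitudes
therefore carry order-of-magnitude confidence, and indeed the model
yields ~1 μN peak vertical force against a ~20 nN weight). The
long-wavelength assumption is enforced softly: a > λ/10 warns.

**Per-unit force comparison.** `unit_force_comparison` quantifies how
drive inhomogeneity maps to trapping strength: for each unit class
(center/edge/corner) it takes the maximum |F_z| along the vertical
line through the unit center within ±λ/8 of that unit's node — i.e.
the peak of the unit's own standing-wave force profile, the quantity
per-unit force figures report. Alternatives (e.g. maximising over the
whole unit footprint) mix in the lateral trap structure and the
influence of the nearby absorbing side walls; the center-line profile
isolates the unit's drive. In model B this yields center/edge ≈ 1.6
and center/corner ≈ 2.3. In model A the ratios are not exactly 1
(≈1.3–1.5): the corner and edge units of a finite 10 mm chamber sit
close to the absorbing aluminium walls, an effect a larger (or
lossless-walled) chamber removes.

## Levitation dynamics

Spheroids move overdamped: the momentum relaxation time
2a²ρ_p/(9μ) ≈ 1.4 ms (a = 75 μm, μ = 1 mPa s) is far below the
transport timescale, so dx/dt = F_net/(6πμa) with
F_net = F_rad + (ρ_m − ρ_p)Vg ẑ. Viscosity defaults to 1 mPa s
(the precursor's low-viscosity window) and affects kinetics only —
terminal positions are viscosity-independent, which is tested. The
integrator is explicit with displacement-limited steps (≤ quarter of a
grid cell) and stops on sub-10-nm steps; the floor is handled by
clipping, so a resting particle can still be lifted. Equilibrium
heights come from bracketed root-finding on F_z(z) + buoyant weight
(bisection to 0.1 μm), choosing the highest descending zero — the
stable balance just below the pressure node. Because the acoustic
force (~μN) dwarfs the net weight (~1.7 nN), the equilibrium sits
within a micrometre of the node and is effectively independent of
spheroid size, which is the platform's central alignment property.

## Synthetic measurements

`synth` replaces the wet-lab cross-section measurements. Diameters are
truncated-Gaussian (±3σ; the study populations are 140 ± 10,
340 ± 40 and 140 ± 15 μm). Sedimented heights model the three
artifacts seen in passive wells — rough cast floor (half-normal offset,
SD 60 μm), stacking (probability 0.15 adds a random neighbour's
diameter), wall adhesion (probability 0.03 resamples the height
uniformly over the well) — plus 5 μm measurement noise. These weights
were calibrated once, analytically by moment matching to the reported
sedimented fits (150 ± 105 μm for the 140 μm population, 235 ± 95 μm
for the 340 μm one), then frozen. Levitated heights are node height +
per-block Gaussian offset (SD 30 μm, emulating frame-height
inhomogeneity between hydrogel blocks) + per-spheroid jitter chosen so
the pooled SD matches the reported 50/80/55 μm; block counts equal the
study's block numbers (4/3/3). Heights are independent of diameter by
construction. All generators are bit-reproducible given a seed.

What the generator does *not* emulate: spatially correlated floor
topography, spheroid–spheroid exclusion on the node plane, optical
measurement bias, or any dependence of levitation error on spheroid
properties. Passing statistics tests therefore demonstrates the
analysis stage is correct, not that real data will match these
parametric shapes.

## Alignment statistics

Heights are fitted per group by Gaussian MLE (sample mean, n−1 SD) on
the raw values — binning-free and asymptotically equivalent to the
frequency-curve fits used in practice — with a one-sample KS distance
as goodness. The "thickness containing 70 %" of a population is the
central 70 % interval of the fitted Gaussian, 2·z₀.₈₅·σ ≈ 2.073σ
(σ = 105 μm → 217.6 μm, reported as 220 at the 10 μm reporting
granularity; an alternative "mean + 2SD" reading reproduces neither
reported thickness and was set aside). Slab coverage is
2Φ(t/2σ) − 1 for the σ-centered slab, with an empirical sliding-window
variant for raw samples; width↔coverage are exact inverses and tested
as such. Group comparisons use the two-sided two-sample KS test
(asymptotic Kolmogorov distribution with effective size n₁n₂/(n₁+n₂);
exact enumeration below combined n = 25). The null rejection rate at
α = 0.05 is verified to be calibrated over 1000 seeded replicate
pairs. Circularity is 4πA/P².

## Pipeline and reproducibility

`acoustolev run-experiment` chains solve → force → trajectories →
synthetic measurement → statistics, writing plain CSV/VTK/JSON plus a
manifest (config SHA-256, seed, output paths). One global seed expands
to per-stage seeds as (seed·100003 + stage) mod 2³¹, so stages re-run
independently yet reproducibly. Solver stages are deterministic;
generator/statistics stages are bit-reproducible.

Problem sizes used by the test-suite and the acceptance script: the
production grid (100, 100, 50) μm for the model A/B solves; coarser
grids (150–200 μm lateral) for dynamics and convergence exercises;
n = 1000 replicates for KS calibration; preset-sized populations
(n = 45–285) for the statistics stage.

## Known limitations

- Lossless fluid by default; thermoviscous damping, boundary layers
  and acoustic streaming are out of scope, as are elastic waves in the
  frame and transient fields.
- Impedance walls are local (plane-wave) approximations of the glass
  and aluminium boundaries; the real lid is a finite plate.
- The Gor'kov model ignores secondary (inter-particle) forces and
  viscous corrections; spheroids are treated as homogeneous spheres.
- The absolute pressure scale inherits the uncertainty of the
  measured displacement map and unpublished chamber geometry (see
  "Fidelity" above); force *ratios* and node *heights* are the robust
  outputs.
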