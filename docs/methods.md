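# Methods

This note documents the models implemented in `tcfus`, the numerical
choices behind them, the synthetic phantoms that stand in for anatomical
data, and the limits of what the validation suite demonstrates.

## Acoustic model

Two scalar pressure equations are integrated in the time domain on
rectilinear (optionally nonuniform) voxel grids:

* **Linear (LAPWE)**: ρ∇·(1/ρ∇p) − (1/c²)p_tt − (ã/c²)p_t = 0. The
  density-variation term ρ∇·(1/ρ∇p) carries the physics of reflection and
  transmission at tissue interfaces; without it a voxelized impedance step
  would transmit incorrectly. The damping coefficient
  ã = 2a√(a²c⁴/4π²f² + c²) is chosen so that the damped dispersion relation
  k² = ω²/c² + iωã/c² has Im k exactly equal to the attenuation a (Np/m) at
  the working frequency — the code contains a closed-form test of this
  identity. ã is evaluated once per run at the drive frequency, so runs are
  narrowband by construction.
* **Nonlinear (Westervelt–Lighthill)**: adds (δ/c⁴)p_ttt with the sound
  diffusivity δ = 2αc³/4π²f², and the quadratic term (β/ρc⁴)(p²)_tt with
  β = 1 + B/2A. The nonlinear coefficient is the standard Westervelt
  normalization: with it, the measured plane-wave second-harmonic growth
  matches the Fubini perturbation series (B_n = 2p₀ J_n(nσ)/nσ) to a few
  percent in the pre-shock region, which is the package's calibration-free
  check of the nonlinear term. (A printed variant of this equation with a
  β/2ρc⁴ coefficient produces exactly half that growth rate and is
  inconsistent with the Fubini solution.)

### Discretization

Collocated grid, second order in space and time. The spatial operator is
evaluated in flux form: face fluxes F = (1/ρ)_face ∂p/∂ξ with the
arithmetic mean of neighboring 1/ρ (harmonic-mean density), which preserves
continuity of normal velocity across material jumps — this is what the
interface R/T validation exercises directly. The leapfrog update treats the
ã damping semi-implicitly (centered p_t), which is unconditionally harmless
at the CFL-limited dt.

For the Westervelt terms, p_ttt uses a four-level backward difference that
is linear-implicit in the new level, and (p²)_tt a second-order backward
difference over four stored levels. Both carry O((ωdt)²) amplitude errors
with larger constants than the linear part, so nonlinear runs default to a
reduced Courant number (≈0.4 of the limit) in the tests. Sources are
injected after the update's implicit division; the injection is rescaled by
(1+ãdt/2)/(1−δ/(c²dt)+ãdt/2) so that both solver variants realize the same
effective in-equation source strength (verified by the δ-vs-ã equivalence
test, which agrees to ≪1 %).

The time step honors the anisotropic stability bound c·dt·√(Σᵢ1/Δᵢ²) ≤ 1
with a default safety factor 0.95, then is rounded down so an integer
number of steps spans one drive period (phasor projection needs whole
periods). Grids graded faster than 1.2 per cell trigger a warning because
the three-point nonuniform stencil degrades to first order locally.

### Boundaries

Convolutional PML (stretched-coordinate, recursive-convolution memory
variables on every spatial derivative), polynomial grading of order 3,
theoretical normal-incidence reflection 10⁻⁴, 16 layers by default. The
measured normal-incidence reflection of the default stack is ≈0.1 %;
`pml_layers=0` degenerates to a reflecting (pressure-release) wall. Air
voxels (ρ < 10 kg/m³) are treated as p = 0 pressure-release boundaries by
default — with a ~1000× density contrast the physically relevant effect is
near-total reflection, and freezing the voxels avoids resolving 343 m/s
waves; a `full` mode keeps air as a propagating material.

### Sources, receivers, phasors

Sources are additive ("soft"): they do not scatter returning waves, which
the time-reversal recordings require. A one-voxel sheet receiving
Δp = B·cos ωt per step radiates plane waves of amplitude B·Δξ/(2ωc·cosθ·dt²);
the inverse of this factor makes requested amplitudes ≈ emitted pressure.
Because the relation is exact only in the continuum limit, quantitative
comparisons (the piston validation) calibrate the actually emitted
amplitude with a cheap 1D run at the same Δz and dt, and feed that into the
reference — the comparison then carries no free scale.

Steady state is declared after 60 drive periods (configurable; the 60 vs 90
period check in the validation suite shows < 0.1 % residual change), and
phasors are extracted by single-frequency DFT projection over the final two
periods. Receivers record raw time series at voxel centers; for array
elements, captures can alternatively be averaged over the element's voxel
patch (see below).

## Transducer model

An idealized 1024-element, 30 cm hemispherical array (1 cm² flat elements
tangent to the sphere, geometric focus at the center, 230/650 kHz). Element
placement uses a boundary-offset Fibonacci spiral — the clinical grouping
is proprietary — giving a minimum center spacing of 10.87 mm at the real
packing density (72 % of the hemisphere); that exceeds the square-tile
equivalent side √A = 10 mm but no lattice can reach the equal-area-circle
diameter (11.28 mm) at this density. Elements are voxelized as tangent-
plane slabs of one-voxel L1 thickness (the thinnest hole-free tiling at any
orientation); contested voxels go to the nearest element, so element voxel
sets are disjoint.

Drive levels: p_element = √(P_total·Z_water/(N·A_element)) with
Z_water = 1.4823 MRayl; 1000 W into 1024 × 1 cm² gives 120.31 kPa.

## Aberration correction

All four strategies produce per-element (amplitude, phase) steering
vectors; the drive phase is the negative of the propagation phase delay
(cos(ωt + φ) convention), so adding any global constant changes nothing.

* **DPC** φᵢ = 2πf·dᵢ/c_water — pure water-path delays.
* **RTPC** φᵢ = 2πf·[(dᵢ−bᵢ)/c_water + bᵢ/c_bone], with bᵢ the bone path of
  the straight element→target segment from midpoint-rule voxel traversal
  (accurate to about one voxel diagonal; no refraction, by construction).
* **SPC** φᵢ = −arg(p_captured,ᵢ) from an inverse run (point source at the
  target, 16-layer PML, duration ≥ transit time plus a settle margin);
  amplitudes uniform at p_element.
* **SPAC** as SPC with amplitudes f·|p_captured,ᵢ|,
  f = √(N·p²_element/Σp²_captured), which makes Σaᵢ² = N·p²_element exactly
  (same input power as uniform driving).

Captures default to averaging the complex phasor over each element's voxel
patch rather than sampling the face-center voxel. The patch average is the
exact reciprocal counterpart of driving the whole face in the forward run:
with it, conjugating the captured phases provably maximizes the focal
pressure over per-element phases (so SPC dominates any geometric phase
rule up to solver noise), and Cauchy–Schwarz gives SPAC ≥ SPC at equal
power. Center-voxel sampling remains available; it is noticeably less
robust because a single voxel can sit near a speckle null whose phase does
not represent the face. Elements whose capture falls below 10⁻⁶ of the
maximum (no line of sight) are deactivated with a warning.

## Thermal model

Pennes bioheat equation with explicit conservative finite differences:
harmonic-mean face conductivities (energy is conserved to round-off on
insulated domains), a stability-bounded dt covering both the diffusion
limit and the perfusion relaxation rate, and three interface conditions:
Dirichlet (region pinned, e.g. a 16 °C water bolus), Neumann (fixed flux),
convective (h·(T_outside−T)+F, e.g. air at 25 °C with h = 6 W/m²K; bolus
h = 70 W/m²K). The acoustic heat source is entered as
ρS = a·p²/(ρc) W/m³ — twice the attenuation times the plane-wave intensity;
the `acoustic_heat_source` function returns S = a·p²/(ρ²c) in W/kg so that
the ρS term of the equation carries the correct volumetric rate. Perfusion
ω is stored in the mass-normalized unit m³ kg⁻¹ s⁻¹ implied by the sink
term ρ_b c_b ρω(T−T_b); the customary ml·min⁻¹·kg⁻¹ figures convert via
×10⁻⁶/60. Optional vascular shutdown scales ω linearly to zero between 50
and 51 °C. The treatment protocol runs 30 min of source-free equilibration
(equilibrium is typically reached after ~10 min) followed by 20 s of
sonication, returning both temperature fields; ablation summaries should be
read as both absolute temperature and rise above the 37 °C baseline, since
a "50 °C threshold" is ambiguous between the two conventions.

Solver validation: perfusion-only steady state ΔT = S/(ρ_b c_b ω) (<0.3 %),
1D step response against the erf heat kernel (<0.1 %), convective-end
equilibration, and h→0 reduction to Neumann.

## Phantoms (what they emulate, and what they do not)

No anatomical data ships with the package; all inputs are generated:

* **Interface slabs** — thin (single-voxel-thick) x–z domains with a
  grid-aligned planar interface, a Tukey-tapered sheet source (taper
  suppresses rim diffraction), and oblique incidence realized as a phase
  ramp rather than a rotated grid (no staircase on the interface). Domains
  extend ≥8 wavelengths each side at λ/15 sampling. R and T are measured by
  a difference method: a homogeneous reference run (sharing the interface
  run's dt — dt is set by c_max, which differs between the two volumes)
  provides the incident phasor; total−incident on the source side gives the
  reflected phasor; all phasors are phase-referred to the interface plane
  and signed by relative phase (>90° offset ⇒ negative), reproducing the
  signed analytic coefficients to ±0.01–0.02.
* **Pistons** — circular r = 10 mm, rectangular 20×20 mm, planar ring
  7.5/10 mm faces on a source plane in a 40×40×90 mm water tank
  (c = 1500 m/s, ρ = 1000 kg/m³) at 500 kHz, lossless or α = 5.756 Np/m.
  Faces are rendered as sub-voxel area-coverage masks (8×8 supersampling):
  a boolean mask's staircase area bias (up to +2.4 % for the ring annulus
  at λ/10) would otherwise enter the radiated amplitude directly. The
  protocol grid is isotropic λ/12; the desk-scale validation grid is λ/10
  transverse × λ/15 axial, because the remaining dominant error is axial
  phase dispersion and axial refinement buys second-order accuracy at
  linear cost. The independent reference is the Rayleigh–Sommerfeld
  integral (closed form on axis for the lossless circular piston; complex
  wavenumber k+iα when lossy), with the source amplitude calibrated by the
  1D run described above. Measured NSD: 1.8–3.1 % over the six cases
  (worst: lossy circular).
* **Skull shells** — three-region volumes (water / bone shell / brain
  interior with the packaged tissue properties) whose outer surface is a
  sphere and whose local thickness is t·(1+ε·g(n̂)) with g a seeded smooth
  random function of direction built from a few cosine modes; the mode
  frequency cap controls smoothness. The focusing study uses a 16 mm-radius
  96-element array at 500 kHz around an 8 mm shell of nominal thickness
  2.5 mm (≈0.8 bone wavelengths) with ±50 % first-order-mode thickness
  variation — the regime of smooth, large-scale thickness error that
  dominates real skulls at these frequencies and that a straight-ray
  correction can actually model. With fine-scale (higher-mode) perturbation
  the ordering of DPC vs RTPC becomes realization noise: refraction and
  scattering, which the straight ray ignores, then dominate — consistent
  with ray-traced corrections helping only on average in anatomical
  studies. Passing tests on these phantoms demonstrate the solver and
  steering machinery, not anatomical fidelity: real skulls add porous
  internal structure, shear conversion (not modeled — pressure-only
  equations), and CT-derived property gradients.

## Focal metrics

Fields are box-filtered (3 voxels), local maxima located, and the maximum
nearest the intended target selected (the global maximum may be a skull
hot-spot). The field is thresholded at 50 % of that peak; the 26-connected
component containing it yields D (target→centroid distance), per-axis
bounding extents (FWHM at the default threshold), shape factor
F = max/min extent, and volume as voxel count × voxel volume. Filter width,
connectivity and threshold are configurable; translation equivariance and
the Gaussian FWHM identity (2.355σ) are tested.

## Problem sizes

Validation runs are sized for a single CPU core: interface slabs ≈10⁵
voxels (seconds each), pistons ≈8×10⁶ voxels × 1300 steps (≈2 min each),
the focusing study ≈4×10⁶ voxels across five runs (≈4 min), all in float32
(float64 changes the reported NSDs by ≪0.1 points). The paper-scale
protocol values (λ/12 isotropic grids, 40×40×90 mm, 60 periods; 1 ms
inverse propagation at 230 kHz on ~8×10⁷ voxel head models) remain the
defaults of the corresponding setup functions where they are desk-feasible,
and are documented here where they are not.

## Known limitations

* Pressure-only propagation: no shear waves, so skull-interior mode
  conversion and related secondary hot-spots are out of reach.
* Narrowband attenuation (ã fixed at the drive frequency); broadband pulses
  would see mistuned damping.
* Straight-ray RTPC ignores refraction by design.
* The bioheat solver uses voxel-aligned interfaces (no conformal
  correction), so curved-boundary fluxes carry a staircase error.
* Homogeneous per-tissue properties; per-voxel CT-derived bone maps are not
  supported.
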