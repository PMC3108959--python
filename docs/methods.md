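# Methods

## Model and assumptions

The tumor and any surrounding normal tissue are treated as rigid, isotropic
porous media at steady state.  Interstitial fluid velocity follows Darcy's
law `u = -K ∇p`; mass conservation with distributed exchange gives

    -∇·(K ∇p) = Φ_B - Φ_L,

with the Starling filtration source `Φ_B = Lp(S/V)(p_e - p)`,
`p_e = p_v - σ(π_v - π_i)`, and the lymphatic sink `Φ_L = L_L (p - p_L)`.
Assumptions inherited from this class of models:

* transport equilibrates much faster than the tumor grows, so all
  physiological parameters are time-independent;
* vasculature is treated as a volume-averaged source — tumor radii (mm–cm)
  are much larger than intercapillary distances (tens of µm), so microscopic
  structure is averaged out;
* exchange coefficients are pressure-independent (the laws are affine in
  `p`, making the steady problem a single linear elliptic equation);
* solid tumors have no functional lymphatics (`L_L = 0`), hence their
  steady-state pressure equals the effective pressure `p_e`;
* a necrotic core has no functioning vessels: both exchange terms vanish
  there and the pressure obeys Laplace's equation.  The core retains the
  viable-tumor hydraulic conductivity; only the sources are switched off.

The controlling dimensionless group is `α = R·√((Lp·S/V + L_L)/K)`, the
ratio of interstitial to vascular flow resistance.  `1/λ = R/α` is the
width of the rim boundary layer over which the pressure falls from `p_e`
to the surrounding value.

## Parameters (units: cm, s, mmHg)

The shipped `baseline.yaml` is the standard mammary-carcinoma set used
throughout this literature:

| parameter | normal | tumor | meaning |
|---|---|---|---|
| K | 8.53e-9 | 4.13e-8 | interstitial hydraulic conductivity, cm²/(mmHg·s) |
| Lp | 3.6e-8 | 2.8e-7 | microvascular wall conductivity, cm/(mmHg·s) |
| S/V | 70 | 200 | vascular exchange area density, cm⁻¹ |
| p_v | 15.6 | 15.6 | vascular pressure, mmHg |
| σ | 0.91 | 0.82 | osmotic reflection coefficient |
| π_v | 20 | 20 | plasma osmotic pressure, mmHg |
| π_i | 10 | 15 | interstitial osmotic pressure, mmHg |
| L_L | 1.042e-6 | 0 | lymphatic filtration coefficient, (mmHg·s)⁻¹ |
| p_L | 0 | 0 | lymphatic hydrostatic pressure, mmHg |

Derived: tumor `p_e = 11.5 mmHg`; `λ = 36.8 cm⁻¹`, so `α = 36.8` for a 1 cm
tumor.  The lymphatic coefficient of normal tissue is not part of the
classical seven-row table; the shipped value is a representative literature
figure for normal-tissue lymphatic drainage and only influences the
embedded-tumor demonstration profiles.  Tissue properties vary widely
between organs — the configuration loader exists precisely so the table can
be replaced per application.  The lymphatic coefficient is stored as the
single product `L_L = Lp,L·(S/V)_L` because only the product ever enters
the equations.

Velocities are reported in both cm/s and µm/s (rim velocities are
naturally ~0.1 µm/s: for the 1 cm baseline tumor the model gives
0.17 µm/s).

## Closed forms (`analytic`)

Dimensionless pressure is defined as `P = (p - p_surr)/(p_e - p_surr)`.

* Uniform isolated sphere: `P = 1 - sinh(αr̄)/(r̄ sinh α)`; removable
  singularities at `r̄ = 0` are evaluated by series expansions, not by small
  offsets, so the symmetry condition holds exactly at the center.
* Necrotic core `r̄ < r̄_n`: constant core pressure joined to a shell
  solution written in the shifted-exponential basis
  `P = 1 + (F e^{α(r̄-1)} + G e^{-α(r̄-r̄_n)})/r̄`.  The usual sinh/cosh basis
  is numerically rank-deficient beyond `α ≈ 35` (sinh and cosh agree to
  machine precision), which the baseline tumor exceeds; the shifted basis
  stays well-conditioned for all `α`.  Constants are fixed by `P(1) = 0`
  and zero flux into the sourceless core.
* Embedded tumor: `p = p_e,t + A sinh(λ_t r)/r` inside, and in the normal
  shell `p = p_ss,n + (B e^{λ_n(r-R_out)} + C e^{-λ_n(r-R)})/r` (shifted
  exponentials again, for conditioning), with pressure and Darcy-flux
  continuity at `R` and a Dirichlet far-field value at the finite outer
  radius `R_out` — no infinite-domain assumption.  The 3×3 interface system
  is column-equilibrated before solving; a condition number above 1e14
  after equilibration is reported as degenerate.  An exchange-free shell
  (`λ_n = 0`) is handled exactly with the Laplace solution `B + C/r`.

The closed forms were verified by symbolic substitution into the governing
equation (residual identically zero) and against independent node-centered
finite-difference solves at 10⁴–2×10⁴ nodes (see `tests/helpers_oracles.py`).

## Radial finite-volume scheme (`fvm_radial`)

Cell-centered conservative discretisation on `[0, R_out]`: the flux through
each interior face is `-K_f A Δp/Δr` with `A = 4πr_f²` and `K_f` the
distance-weighted harmonic mean — the choice that preserves flux continuity
exactly across piecewise-constant conductivity interfaces.  Grids are
near-uniform with faces snapped onto the region radii `R_n` and `R`, so
region boundaries are conservative interfaces.  The affine source is kept
implicit in the matrix (no outer iteration is needed for a linear law).

Boundary conditions: the center face has zero area, which enforces the
symmetry condition automatically; the outer face applies the Dirichlet
surrounding/far-field pressure through a quadratic (three-point) one-sided
flux closure.  The half-cell two-point closure was found to dominate the
global error (first-order flux error concentrated at the rim, where the
profile is steepest); the quadratic closure restores uniform second-order
behaviour while keeping the system tridiagonal and the telescoping
conservation identity exact.  It falls back to the two-point form if the
outermost two cells differ in conductivity.

Solvers: direct banded factorisation (default) or relaxed Gauss–Seidel
sweeps with relaxation factor 0.75 by default (under-relaxation, mirroring
the historical scheme; over-relaxation `1 < ω < 2` is also accepted).
Iteration stops when the residual norm has fallen six orders of magnitude
(tolerance 1e-6, configurable); non-convergence raises with the residual
history attached.  Every solve reports the conservation gap — the relative
imbalance between the volume-integrated net source and the boundary
outflux — which is a roundoff-level identity (≲1e-13) for direct solves.

Observed convergence order against the closed form is 1.98–2.00 over
N = 100–800; at N = 1000 the maximum dimensionless error is ≤2e-5 for
α up to 33.

## Voxel scheme (`fvm3d`)

A structured cubic-voxel grid replaces unstructured tetrahedral meshing: it
has the identical conservation structure and physics while remaining
desk-scale implementable and testable; this is a deliberate simplification.
The 7-point stencil uses harmonic-mean face conductivities; Dirichlet
conditions hold on exterior-labelled voxels (eliminated unknowns) and on
the outer box faces via half-cell ghosts.  Sources are affine per voxel by
region and vanish in necrotic and exterior voxels.

The steady Darcy problem with affine sources is a single symmetric
positive-definite linear system with no pressure–velocity coupling loop, so
no SIMPLE-style outer iteration exists here: the elliptic system is solved
directly.  Methods: Jacobi-preconditioned conjugate gradients (default),
sparse LU for small grids, and matrix-splitting SOR sweeps (relaxation
0.75) for parity with the radial solver.  SOR-type sweeps converge far too
slowly for production voxel counts and are intended for small-grid
verification runs.

Accuracy against the closed form is measured on a voxelized sphere
surrounded by an exchange-free conducting shell out to twice the tumor
radius (this keeps the Dirichlet surface on the smooth box boundary; a
staircased Dirichlet sphere would add a first-order geometric error of
order half a voxel in the effective radius).  The tumor radius for these
checks is chosen to give `α = 5` (≈0.136 cm at baseline), which resolves
the rim layer at 64 voxels per axis; shell-averaged relative errors are
1.2% / 0.54% / 0.15% at 32 / 64 / 96 voxels per axis.

## Critical radii (`analysis`)

"Reaches effective pressure" is operationalised as `P(0) ≥ 1 - ε` with
ε = 0.01 by default; ε is a configuration knob and all reports state it.
The 1% rule reproduces the qualitative classification of the four simulated
radii (only 0.1 cm is sub-critical at baseline).  The critical tumor radius
solves `α/sinh α = ε` on the strictly monotone closed form (bracketing root
find, relative precision better than 1e-6); the critical necrotic radius
brackets the non-increasing map `R_n → P(0)` against the threshold
`(1-ε)·P(0; R_n=0)`, with a dense-scan fallback plus warning if
monotonicity is ever violated numerically.  Sweeps default to the analytic
path; the numerical path is available and cross-checked to ≤1e-3.

For the baseline tumor at ε = 0.01: critical tumor radius 0.198 cm;
critical necrotic radius 0.853 cm for a 1 cm tumor.

## Degenerate inputs, tie-breaks, tolerances

* Dead tissue (no vascular or lymphatic exchange anywhere) has no defined
  steady-state pressure; requesting it raises.
* A fully necrotic tumor with zero surrounding pressure yields identically
  zero pressure in all three paths (the discrete systems become pure
  Laplace problems with zero data).
* Cell/voxel region assignment is by center position with half-open
  intervals; a face exactly on a region radius belongs to the boundary of
  both regions and carries the harmonic-mean conductivity.
* Default embedded-domain extent is `R_out = 3R` when unspecified; doubling
  it changes the baseline center pressure by far less than 0.1% because the
  normal-tissue decay length `1/λ_n ≈ 0.05 cm` is tiny compared to `R`.
* The 3-D conservation identity is exact only up to the linear-solver
  residual; conservation-critical runs should use the direct method or a
  tolerance of 1e-10 or tighter.

## What the synthetic geometry does and does not emulate

The voxelized-sphere generator is deterministic and reproduces ideal
spherical geometry with sharp region boundaries.  It does not emulate real
tumors' irregular margins, heterogeneous vascular density inside the viable
rim, anisotropic conductivity, or partial-volume effects at tissue
interfaces — so passing tests demonstrate correctness of the transport
solver and its conservation structure, not anatomical realism.  Arbitrary
masks can be supplied through the labelled-mask file format.

## Known limitations

* No solute/drug concentration transport: pressure, velocity and the
  filtration-rate profile `Φ_B(r)` are the delivery surrogates computed.
* No tumor growth dynamics or poroelastic deformation (rigid matrix).
* Isotropic scalar conductivity per region; no tensor (DTI-derived)
  anisotropy.
* Structured voxels only in 3-D; no tetrahedral/unstructured meshes and no
  image segmentation.
* Problem sizes used in the shipped tests (≤1000 radial cells, ≤96³ voxels)
  are chosen by the convergence studies above; they are not tied to any
  particular historical mesh count.
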