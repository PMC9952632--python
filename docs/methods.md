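# Methods

`archflow` studies how endovascular reconstruction of the aortic arch
reshapes the blood flow and the wall-shear environment, using four idealized
stages of one arch: a normal control, a preoperative lumen carrying a
saccular arch aneurysm, and two postoperative lumens (1 week and 6 months
after a modular inner branched stent-graft excludes the sac and occludes the
left subclavian artery).  This note records the model, the defaults, and the
numerical choices, in enough detail to judge what the passing tests do and do
not demonstrate.

## Flow model

Blood is treated as an incompressible Newtonian fluid (density
rho = 1060 kg/m³, dynamic viscosity mu = 3.5 mPa·s) in laminar pulsatile
flow with rigid walls.  The cardiac cycle has period T = 1 s.  Boundary
conditions:

* **Inlet** (ascending aorta): a prescribed cross-section *mean* velocity
  v(t) built from three cosine pieces, continuous at 0.3 s and 0.6 s,
  ranging from 0.295 m/s at end-diastole to 1.06 m/s at peak systole
  (t = 0.15 s).  The spatial profile is a blunt plug by default (rim nodes
  are no-slip; the interior is scaled so the flux is exactly v(t)·A), with a
  parabolic option.  Whether the physiological signal is a mean or a peak
  velocity is ambiguous; it is treated as a mean.
* **Outlets** (all supra-aortic branches and the descending aorta): one
  shared pressure waveform p(t), 90 mmHg in diastole, 140 mmHg at the
  systolic peak (t = 0.25 s), converted to Pa (×133.322) before use.  Branch
  flow split is therefore purely geometry/resistance driven.
* **Walls**: no-slip, enforced strongly (wall-node velocities are exactly
  zero in every snapshot).

The diastolic piece of p(t) admits more than one algebraic reading; the
implemented `periodic_reanchor` policy,

    p(t) = (p(0.35) − 90)·cos(0.7692·pi·(t − 0.35) + pi − 1.5) + p(0.35),

is chosen because 0.7692·pi·0.65 ≈ pi/2 returns the signal to ≈90 mmHg at
t = T, i.e. it restores periodicity (wrap mismatch 0.08 mmHg).  The price is
a 2.3 mmHg jump at t = 0.35 s (2.6% of diastolic), which
`waveform_diagnostics` reports rather than hides.  The policy is a named,
swappable argument.  Inlet-waveform angular coefficients are the exact
rationals 20·pi/3 and 10·pi/3 — the printed 4-digit decimals would leave
~2e−10 junction jumps where the intent is plainly a whole/half cosine period.

## Parametric geometry

No imaging data exists for these lumens, so each case is a parametric solid
of revolution-like construction: a planar centerline (ascending segment,
semicircular torus arc, descending segment) swept with a polar disc
template.  Adult-aortic presets (all overridable):

| quantity | value |
|---|---|
| lumen radius | 12.5 mm |
| ascending / descending length | 60 / 120 mm |
| arch curvature radius | 32 (normal, preop), 25 (1 week), 29 mm (6 months) |
| branch radii IA / LCCA / LSA | 6 / 4 / 4 mm |
| IA bifurcation | 20 mm common trunk, then RSA + RCCA (4 mm, ±20°) |
| aneurysm sac | 20 mm bulge, 10 mm neck half-width, ±70° azimuth |
| flow extensions | 5 × local diameter at the inlet and every outlet |
| wall layers | 6 geometric layers, ratio 1.2, on the trunk wall |

Branches are grown by extruding rectangular patches of trunk-wall triangles
along the local outward direction, so the junction is conformal and
watertight by construction; a patch covers ≈ sqrt(pi)·r per side so its area
matches pi r².  At the coarse tier this quantizes the ostium to the wall
grid, which is why perfusion fractions are qualitative, not clinical,
numbers.  The sac is a smooth (cos²-windowed in arc length and azimuth)
radial bulge of the outer curvature; postoperative lumens simply omit it,
and their IA/LCCA ostia sit strictly more proximal than preoperatively.
The region under the sac is axially refined 3× because the steep neck would
otherwise fold a few sheared wall-layer prisms.

Prisms between consecutive cross-sections are split into tetrahedra with the
min-vertex diagonal rule, which makes neighboring prisms agree on shared
quad diagonals; boundary facets are recovered by face counting, making
watertightness (closure of the outward area vectors to ~1e−16) an invariant
rather than a repair.  Meshing is pure arithmetic: identical specs give
bitwise-identical meshes.

**What the generator does not emulate:** patient-specific cross-section
shape and tapering, arch torsion out of the plane, the stent-graft's actual
wireframe and wall compliance, residual sac lumen (assumed none at both
postoperative stages), and absolute vessel dimensions (the source imagery
carries no scale).  Passing the cross-case ordering tests therefore shows
that the *modeled morphological differences* reproduce the reported
hemodynamic orderings — not that any absolute area or flow value matches a
patient.

## Discretization

Equal-order linear (P1) simplex elements in 2D (verification) and 3D
(production), with an incremental pressure-correction (projection) scheme:

1. tentative momentum: implicit viscous operator, Adams–Bashforth-2
   convection, previous pressure gradient; strong Dirichlet at inlet/walls;
2. pressure Poisson for the increment, with the outlet waveform value
   imposed as a Dirichlet datum (pressures are thereby anchored to the
   outlet signal at every step — the reported pressure is not floating);
3. lumped-mass velocity correction and re-imposition of the Dirichlet data.

Both sparse operators are constant in time and factorized once (SuperLU);
each step is two triangular solves plus vectorized assembly of the
nonlinear terms.  The fixed step is 1 ms for production runs (the 2 ms
`SolverConfig` default leaves ~1.3% cycle-max flux imbalance from the
splitting error; 1 ms gives ~0.4%, inside the 1% conservation contract).
Two cycles are simulated and the first is discarded as transient; 100
snapshots of the final cycle are retained.

Peak-systolic Reynolds number in the arch is several thousand, far beyond
what a ~50k-cell mesh can resolve with a plain Galerkin convection term, so
production runs add a grid-Peclet-limiting artificial viscosity
nu_a = c·h·U_ref per cell (c = 0.25, U_ref = 1.06 m/s, h the isotropic cell
size), folded into the constant implicit operator.  This is first-order
upwinding in effect: it caps the effective cell Peclet number at ~4 and
laminarizes the large-scale field.  Consequences to keep in mind: absolute
WSS levels in the arch are smoothed, and the risk-area fractions are larger
than patient-scale studies report; the cross-case *differences* are the
meaningful output.  The convection-free or smooth verification problems
(Poiseuille, oscillatory channel) run with c = 0 and carry the quantitative
burden of validating the discretization.

The steady solver is the same scheme marched in pseudo-time with constant
boundary data.  The dominant transient is the fundamental viscous mode,
whose decay time is mesh-independent, so the march applies Aitken
extrapolation over 40-step windows to collapse it; stationarity is declared
when the per-step relative velocity change drops below 1e−8.  (A monolithic
stabilized P1-P1 saddle-point solver was tried first and rejected: it
developed axis-column pressure oscillations on the 3D swept tubes.)

Known conservation behavior: because the outlet nodes carry Dirichlet
pressure data, the discrete continuity residual is not tested there, and
steady surface-flux imbalance is ~1e−4 at test resolution (O(h²)); the
pulsatile cycle-max imbalance is 0.4% on all four cases.

## Wall shear and indices

The WSS vector is the tangential part of mu (grad u + grad uᵀ)·n on each
wall facet, reconstructed from the single adjacent cell — exact for linear
fields (verified on plane Couette to 1e−10) and a thin-secant estimate on
the graded wall layers (Poiseuille: 0.5% coarse, 2.3% refined against the
4 mu Q/(pi R³) closed form).  Facets with degenerate adjacent cells are
excluded and counted.

Indices per facet over the final cycle, with T the period:

* TAWSS = (1/T)∫|tau| dt, tau_mean = |(1/T)∫tau dt|,
* OSI = 0.5·(1 − tau_mean/TAWSS), zero-TAWSS facets flagged undefined,
* RRT = 1/(TAWSS·(1 − 2·OSI)), singular facets capped at 1e6 Pa⁻¹ and
  flagged.

Time integrals use the composite trapezoid rule with periodic wrap; on
uniform grids this is exact for the vector mean of trigonometric signals and
second-order (not spectral) for |tau| wherever the traction crosses zero,
which sets the ~1e−5 accuracy seen in the oversampled-oracle suite at 1024
samples.  Risk regions use strict inequalities at TAWSS < 0.4 Pa,
OSI > 0.25, RRT > 5 Pa⁻¹ — a mutually consistent triple, since
1/(0.4·(1 − 0.5)) = 5 exactly.  Area statistics are facet-area sums over
the wall with flow-extension surfaces excluded (they are numerical
scaffolding), reported in cm² and as wall fractions, with a per-anatomical-
region breakdown.

## Perfusion and morphometry

Per-outlet perfusion is the cycle average of the outward surface flux
(vertex-mean facet quadrature, exact for P1), reported in m³/s and mL/min
plus the fraction of mean inlet flow; occluded outlets report exactly zero
with a note.  The trunk centerline comes from the parametric definition (no
skeletonization — it is exact and deterministic); curvature is estimated by
circumscribed circles of sliding point triples with a 5-sample boxcar on the
curvature, which is exact on circles, rigid-motion invariant, and recovers a
500-sample helix to well under 2%.  The minimum curvature radius over the
trunk reproduces each case's arch radius, giving the 1-week < 6-month ≤
normal ordering by construction of the presets.

## Resolution tiers and runtimes

`coarse` (5 mm target edge, ~45–57k tets per case) is the working tier:
every case solves in ~2 minutes on one CPU and the four-case comparison in
~10 minutes, which is the problem size used throughout the tests and the
acceptance script.  `medium` (3 mm) and `fine` (1.8 mm, approaching
patient-study element counts) exist for convergence studies and are not run
routinely.

## Limitations

Beyond the generator gaps listed above: no fluid–structure interaction, no
turbulence model (deliberately — pulsatility suppresses sustained
turbulence, and the artificial viscosity dissipates what the mesh cannot
carry), Newtonian rheology, one shared outlet pressure (no per-branch
impedances), and a 2D-planar centerline (no arch torsion, hence no helical
flow component).  Absolute risk-area and perfusion values at the coarse tier
are resolution- and stabilization-dependent; only their cross-case orderings
are treated as results.
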