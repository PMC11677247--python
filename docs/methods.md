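# Methods

## Scope and model

`osseowave` studies, at desk scale, the mechanical conditions for
osseointegration of a cylindrical titanium implant in a layered
mandibular-segment block under two loading modes: extracorporeal shock wave
therapy (ESWT) pulses delivered by a copper applicator plate, and
displacement-controlled physiological (occlusal) loading.  Per-element
hydrostatic (mean) stress, shear strain and pore-fluid pressure are
classified by mechanobiological threshold rules into tissue-differentiation
fates, and summarized as volume fractions of the peri-implant healing zone.

The solid is a bonded particle model: spheres of diameter `d` on an FCC
lattice (nearest-neighbour distance `d`, coordination 12), each carrying a
translation, a finite rotation, a pore pressure and an element stress
tensor.  Tissues are isotropic linear poroelastic (Biot); the metals
(Ti-6Al-4V implant, Cu applicator) are elastoplastic with a von Mises yield
stress and no pore space.  No bond breakage, contact detection or gravity:
the loads of interest stay far below tissue strength, the applicator is
bonded to the tissue face, and gravity is orders of magnitude below the
applied stresses.

## Pair mechanics

Pair kinematics are total-Lagrangian.  The normal strain is
`eps_n = (r - r0)/r0`; the shear strain vector is the relative tangential
displacement of the two material points that initially coincided at the
contact, convected with the element rotations, divided by `r0`.  Rigid-body
motion therefore produces exactly zero strain (verified to 1e-10).

The pair response is a many-body closure.  Each side contributes

    sigma_n(i) = 2 G_i eps_n + (1 - 2 G_i / (3 K_i)) * sigma_eff_i ,
    tau(i)     = 2 G_i gamma ,

and the two sides combine in series (harmonic mixing), which handles
dissimilar-material pairs.  `sigma_eff_i` is the element's effective mean
stress, evaluated as `K_i tr(eps_i)` from the current strain
homogenization.  In the uniform affine limit the closure reproduces
isotropic linear elasticity *exactly* (this is also the fixed point
`sigma_mean = 3 K eps` of the equivalent stress-feedback form of the same
closure; the instantaneous form is used because a one-step-lagged stress
feedback acts as a delayed restoring force and pumps the stiffest modes of
an undamped explicit integration).

The transmitted normal stress subtracts the pair pore stress
`mean(alpha_i P_i, alpha_j P_j)` so that the homogenized element stress is
the *total* stress of Biot theory.  Forces act over a contact area whose
reference value `A = V_el/(2 d)` makes the homogenization exactly
consistent (`q A Z/3 = V_el` with lever `q = r/2` and coordination
`Z = 12`).

### Surface treatment

Free surfaces are the main discretization hazard of a bonded lattice:
boundary elements miss bonds and both under-report their stress and
under-transmit tractions.  Two corrections are built in:

* **Geometry-corrected estimators.** Mean stress and volumetric strain
  (rate) are estimated through the inverse pair-geometry tensor
  `Geo_i = sum_j r0^2 n (x) n`, using the identity
  `tr(Geo^-1 sym(L Geo)) = tr L`, which is exact for uniform/affine fields
  on *any* neighbour set.  The undrained pore-pressure response is
  therefore exact even on surface elements.
* **Directional area weights.** Each element's bond areas are scaled by a
  fitted symmetric weight tensor `S` satisfying
  `sum_j r^2 (n.S.n) n(x)n = 4 d^2 I` (interior solution `S = I`), so the
  transmitted traction at a free surface is restored direction by
  direction.  Pair weights are the mean of the two sides, clipped to
  [0.5, 3].

With these, a homogeneous block recovers the input Young's modulus and
Poisson's ratio to well under 1% (measured on the core representative
volume), and the P-wave first-arrival speed is within ~3% of
`sqrt((K + 4G/3)/rho)`.

## Pore fluid

Each porous element carries one pressure `P` (positive in compression).
The undrained storage update `dP = -alpha M d(eps_vol)` is applied inside
the force evaluation from the current strain increment (again to avoid a
delayed-feedback instability); Darcy exchange
`T_ij = (k_harm/eta) A/(L V)` runs on the step clock with automatic
sub-cycling when the explicit diffusion limit `0.5/max(M sum T)` is
exceeded.  Metal elements are impermeable (`T = 0` across their pairs,
`P = 0`).  All outer surfaces are sealed by default; a drained-surface mask
is available.  The two-point-flux stencil reproduces the continuum
Laplacian exactly on the interior FCC lattice; verification against the
Terzaghi series (on the interior column of an oedometer model built from a
soft synthetic material, starting from the settled undrained Skempton
state) gives RMS error ~3.5% of the initial pressure.

## Integration

Velocity-Verlet (kick-drift-kick) for translations; explicit angular
velocity and accumulated-rotation update with sphere inertia.  Timestep
`dt = C d / max(cp)` with `C = 0.2`.  Quasi-static runs use non-viscous
local (Cundall-type) damping applied to both forces and torques — it
vanishes identically at equilibrium, so it does not bias statics; shock
wave runs are undamped.  Plasticity is a radial return of the element
deviator to the yield surface, applied to the pair shear forces through a
(slightly lagged) per-element scale factor; the default scenarios stay far
below the metal yield stresses.

## Geometry and materials

The scaled benchmark block is 6 x 6 x 8 mm: a 0.4 mm gingival layer (the
tissue table has no gingiva row; it is mapped to the fibrous-tissue
properties), a 0.6 mm cortical layer, cancellous bone below, and a
cylindrical implant (radius 2 mm, length 6 mm from the top surface) inside
a peri-implant shell of outer radius 2.5 mm — a 0.5 mm healing gap whose
material follows the osseointegration phase: primary matrix (phase 1),
granulation tissue plus a 0.25 mm fibrous interface at the implant
(phase 2), woven bone (phase 3, interface configurable).  The lowest
element layer is fixed.  The 0.3 mm Cu applicator plate continues the
lattice beyond the +X face (bonded, strain-free at start) and is scaled to
half the block face (3 x 3 mm) when the full 7 x 7 mm plate does not fit;
its rigid prescribed velocity follows the pulse protocol.  Simplified
teeth (dentin cylinders with a PDL sleeve) are available but off by
default — the benchmark block is too small to host them.

Material assignment is anti-aliased: each element's volume cell is
supersampled (3^3 points) against the continuum geometry and its
properties are blended from the partial volumes — Reuss (series) averages
for K and G across the thin horizontal tissue layers and the implant tip
cap, volume averages for density, Biot coefficient, permeability and the
storage compliance `1/M`.  The metal *side wall*, where both Voigt and
Reuss misrepresent a 100-GPa/sub-GPa interface, stays sharp: straddling
elements snap to metal or tissue by per-lattice-plane equal-area
dithering, which matches the true metal cross-section to half a cell.
Region labels (used for boundary conditions and zone statistics) remain
discrete.

Several tabulated soft tissues (fibrous/primary matrix, PDL, woven bone)
have Biot coefficient `alpha = 1 - K/Ks` slightly below their porosity;
the micro-homogeneity inequality `alpha >= theta` is therefore not
enforced — only a positive storage modulus is.

## Loading protocols

*ESWT*: the plate velocity rises as a half-sine over 0.01 us to the peak
`V`, holds 0.1 us, ramps down, and repeats every 1 us for 5 pulses.  `V`
comes from the plane-wave balance `V = sqrt(EFD/(Z tau_eff))` with
`Z = rho cp` of copper and `tau_eff` defaulting to the pulse period; the
delivered-energy estimator `Z int v^2 dt` carries the documented shape
correction `tau_eff/(tau_hold + t_rise)`.  The studied intensity range is
0.01-0.5 mJ/mm^2.

*Physiological*: the top element plane moves down at 0.1 m/s until the
reaction force reaches the target (100 N rest, 200 N mastication).  At
desk scale the instantaneous crossing is dominated by inertia, so the
driver measures the *sustained* resistance: on each crossing the set is
held, the transient is relaxed under strong local damping, and the held
displacement is refined by secant iteration until the settled force is
within 0.5% of the target.  The secant stiffness is the settled force over
the held displacement.

## Mechanobiological classification

Mean stress is tension-positive; rules in decision order: |sigma| < 3 kPa
quiescent; compression beyond 2 MPa overload; tension above 0.15 MPa
fibrogenic; shear strain above 5% gates fibrogenic (tension) or
chondrogenic (compression); low shear gates osteogenic up to the
compressive ceiling (default 0.15 MPa, configurable to the 0.2 MPa reading
used in the study's applied analysis), with stronger compression
chondrogenic.  Boundaries are closed on the osteogenic side.  Pore
pressure between 20 kPa and 2 MPa suffices for cell transport, with an
optimal band a factor 2 around 68 kPa.  The distortional-strain band
(0.05-1.1%, optimum 0.5%) is reported as an auxiliary flag, not a fate.
The classifier consumes the total mean stress (the mapped field quantity);
an effective-stress switch exists.  Zone statistics follow the stated
procedure: per-sample label counts over the shell (+ fibrous interface)
divided by the zone size, averaged over the sampling window, with
fractions under 5% reported as "<5%" (that reading of the 5%-mean
convention; a trimmed-mean alternative would change only the reporting).

## Problem sizes and what desk scale can and cannot show

Default runs use d = 500 um (~3400 elements; ~11600 at 333 um), chosen so
the whole verification and analysis suite runs in minutes on one core.
Two desk-scale limits are documented rather than hidden:

* **Discretization convergence.** The three-level stiffness study
  (500/400/333 um) converges to ~2% for a homogeneous block and the
  layered geometry, but the full benchmark shows a ~10% spread driven by
  the stiff implant column: the punch-like load transfer at the apex and
  the one-element-wide soft shell are O(d) features at these diameters.
  Matching the full-scale 4% convergence claim would need d <~ 200 um,
  i.e. the resolution of the original cluster-scale study.
* **Shock wave shear bound.** During the pulse train the peri-implant
  shear ratchets with the applicator's net advance (~0.08 um per pulse):
  0.026% after the first pulse — inside the reported 0.05% bound — but
  ~0.1% by the fifth, because the cumulative indentation of the bonded
  plate concentrates at its edge 0.5 mm from the shell.  At full scale the
  same advance is negligible relative to the domain.

The synthetic geometry reproduces the *structure* of the study model
(layers, healing shell, applicator), not the anatomical mandible, teeth or
implant thread; absolute stiffnesses and fraction values are therefore
scaled analogues, while the threshold logic, poroelastic physics and
protocol machinery are full-fidelity and verified against closed-form
oracles.
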