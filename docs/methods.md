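# Methods

`gyrusim` couples a 2D tissue-mechanics model of a cortical gyrus to an
idealized MR imaging chain in order to predict the spurious fMRI signal
changes caused by the micrometre-scale tissue displacements that
accompany vasodilation.  This note documents the model, its assumptions,
the numerical choices, and what the synthetic test fixture does and does
not represent.

## Synthetic gyrus geometry

The study geometry is a labeled 8.5 mm x 15.3 mm coronal patch: a single
folded cortical band (one crown, two flanks) of 2.5 mm thickness around
a Gaussian-bump centerline, embedded with white matter below and CSF
above.  The band is split radially into the six neocortical layers with
default thickness fractions (L1..L6) = (0.10, 0.10, 0.25, 0.15, 0.20,
0.20) of the cortical thickness — canonical neocortical proportions,
configurable because results depend on them — and tangentially into 12
segments of equal mid-surface arc length.

All interfaces are constructed as graphs y(x): the GM/WM interface is an
analytic Gaussian bump (default amplitude 4.0 mm, wavelength 7.2 mm)
plus a small seeded long-wavelength irregularity emulating a hand-traced
boundary, and the remaining interfaces are normal offsets re-expressed
as graphs.  Configurations whose concave curvature radius falls below
the cortical thickness are rejected (the offset construction would
self-intersect).  This construction cannot represent a deep finger-like
gyrus with near-vertical flanks; the default is the deepest moderate
fold the construction supports.  Consequences worth keeping in mind:

* the fold's crown curvature radius (~0.8-1 mm) is tight relative to the
  cortical thickness, so the unfolding-based baseline stress is strong
  (|sigma_tt|/mu up to ~3);
* the cortical band terminates at the fixed lateral domain boundaries,
  which suppresses long-range lateral shifts; crown displacements are
  therefore smaller than on a free-standing deep gyrus for the same
  activation (about an order of magnitude below the headline values of
  the study the model emulates, with all orderings preserved);
* the pial displacement field peaks over the activated flank segment and
  decays toward the crown and the far flanks, rather than peaking
  exactly at the crown.

Meshing is a structured conforming triangulation: columns follow the
tangential segmentation, rows the layer interfaces, so every region and
segment boundary is a mesh line and every element carries exactly one
label.  The cell size is calibrated internally so the mesh-wide mean
edge length tracks the requested target (default reference meshes: 206
and 143 um); an optional `surround_coarsening` refines the cortex
relative to WM/CSF at fixed average size.

## Constitutive model and solver

Tissue is isotropic, nearly incompressible neo-Hookean:

    W(F) = mu/2 [tr(F F^T) J^(-2/3) - 3] + kappa/2 (J - 1)^2,  J = det F,
    sigma = (1/J) dW/dF F^T,

with GM mu = 1400 Pa, WM mu = 1900 Pa (rho = 1040 kg/m^3 is carried but
unused: quasi-static, no inertia).  The 2D idealization is plane strain
(F_33 = 1; through-plane extent constant).  The default volumetric
penalty is kappa = 1e4 mu: the literature spans kappa/mu from ~1e3 to
~1e6, and the displacement results are insensitive to kappa in this
whole range (verified in the parameter-grid tests up to 5 GPa), so a
moderate default keeps the equations well-scaled; bulk moduli in the
GPa range are available via `MaterialField.from_regions(kappa="table")`
or explicit values.

Discretization: 6-node quadratic triangles on the P1 mesh, 3-point Gauss
quadrature, total-Lagrangian Newton with backtracking line search.  Two
numerical choices matter for near-incompressibility:

* **Mean dilatation.** The volumetric energy acts on the element-averaged
  Jacobian.  Pointwise penalty integration at kappa/mu >= 1e4 makes the
  Newton landscape effectively non-descendable from cold starts (the
  geometric part of the Hessian turns indefinite); the mean-dilatation
  form removes both that fragility and volumetric locking.  Pointwise
  |J - 1| inside elements is then only bounded through the element
  averages: after converged small-strain solves it stays below 0.01, but
  inside the strongly bent elements of the unfolding solve it can reach
  ~0.1 at coarse resolution.
* **Augmented Lagrangian.** Inner Newton solves use an effective bulk
  modulus of 100 mu (robust, fast), and an Uzawa multiplier update per
  load level drives the volumetric pressure to the true-kappa penalty
  solution (contraction ~1e-2 per augmentation; terminated at a
  multiplier change of 1e-6 of the mean shear modulus, i.e. ~1 mPa —
  far below the ~100 Pa activation loads).

The consistent tangent is assembled from central finite differences of
the first Piola stress per quadrature point for the isochoric and
initial-stress terms (keeping the linearization independent of the
stress routine it checks) and exactly for the volumetric term (the 2D
cofactor is linear in F).  Load is applied incrementally (Dirichlet
values, growth stretches and initial stress scale with the load factor)
with adaptive step bisection on non-convergence; the converged solution
is path-independent, so the increment count is purely a robustness
device (verified: 2 vs 8 increments agree to 1e-7 um).  Convergence:
residual 2-norm below 1e-8 of a cancellation-free internal-force scale,
floored by a unit-strain force scale so stress-free solutions terminate.

Growth (tissue swelling) uses the multiplicative split F = F_e F_g with
F_g = diag(g, g, 1) and the energy evaluated on F_e weighted by det F_g.
A requested volume change of p means an in-plane area factor (1 + p),
g = sqrt(1 + p).

## Baseline stress from unfolding

The folded cortex is assumed to carry residual stress; it is estimated
by numerically unfolding the cortical band: both the pial and the GM/WM
boundary are driven onto two parallel horizontal lines (y prescribed in
20 continuation steps, x free, one lateral pin; target separation = mean
cortical thickness) and the Cauchy stresses of the flattened state are
mapped element-by-element back onto the folded reference mesh.  The
prescribed boundary increments are extended into the band interior
(linear blend across the depth) as the initial guess of each step, which
prevents boundary-element inversion; steps bisect adaptively.

The mapped-back field is not self-equilibrated: applied as-is it relaxes
the folded mesh by hundreds of micrometres, and scenario responses
evaluated around such a drifted state acquire large spurious couplings
(the volume mechanism became ~80% prestress-dependent in our
experiments).  The default therefore re-equilibrates the field by three
fixed-point passes — solve the baseline under the current field, replace
the field by the total stress of the relaxed state — which contracts
the drift by roughly an order of magnitude per pass (recorded in
`FlatteningResult.drift_log`); `equilibrate=0` restores the raw
behavior, and `map_stress_back` always returns the raw mapped field.

A residual ~10% coupling between the baseline field and the volume
response remains: it enters through the geometric stiffness and scales
with sigma0/mu, which is O(1) on this tightly curved fold.  The
normalized stress map (sigma_tt / mu_GM, the Fig-2-style output) shows
the expected bending pattern: opposite signs across the thickness at the
crown, sign tracking the local curvature.

## Activation scenarios

An "activated" set of layer segments (default: the L1 flank segment two
tangential positions below the crown segment) undergoes

* **stiffness**: mu -> (1 + c) mu on the activated elements, and the
  initial stress they carry scales by the same factor.  The scaling is
  the load: a purely additive initial stress field that is in
  equilibrium gives exactly zero response to a stiffness change (u = 0
  remains a solution for any mu), whereas the stress carried by a
  stiffened elastic network at fixed baseline strain grows with its
  modulus, creating a local stress surplus c * sigma0.  This convention
  reproduces the reference patterns quantitatively: response linear in
  c, proportional to the global stress scale, and inversely proportional
  to the baseline stiffness across the parameter grid (factor ~5 over
  the literature mu range, matching the reference grid's spread).
* **volume**: growth g = sqrt(1 + p) on the activated elements
  (baseline stress off by default for this scenario; on in the combined
  and additivity protocols).
* **combined**: both simultaneously.

Every scenario is reported as the difference between the activated and
the baseline solve under identical conditions, so a zero change yields
exactly zero displacement and any residual drift cancels.  The headline
observable is d_tot = sqrt(u^2 + v^2) in micrometres at the crown probe
(50 um inside the pial apex, evaluated with quadratic shape functions so
the probe is mesh-independent).

The default segment placement skips the crown-straddling segment: a
source centered on the apex pushes the crown in opposite directions
under the two mechanisms, which does not correspond to the lateral
left-to-right shift of the modeled configuration.  Flank segments give
parallel responses (direction cosine ~ +1.0).

## MR imaging chain

Tissue property maps (PD as % of CSF, T1, T2* at 7 T, per layer) are
rasterized from the labeled geometry at 20 um over an 8 mm field of view
centered on the crown (integer voxel counts at 0.25/0.5/1.0 mm; the FOV
stays inside the simulated domain so displacement fields need no
extrapolation).  The activated geometry displaces the region interfaces
with the FEM displacement field.  Signal equations:

    PD/BOLD:  S = PD exp(-TE / T2*)
    VASO:     S = PD |1 - 2 exp(-TI / T1)| exp(-TE / T2*)

with TE = 5 ms (PD/VASO), TE = 33 ms = T2* of GM (BOLD), and
TI = ln(2) T1b = 1456 ms nulling blood at T1b = 2100 ms (full
relaxation, no blood compartment inside tissue voxels).  Acquisition is
a symmetric central k-space crop of the 2D FFT (DC at the fftshift
center) followed by inverse transform and magnitude, normalized so a
uniform raster is reproduced exactly; voxel = raster spacing is the
identity.  No noise, B0/B1 inhomogeneity or relaxation during readout is
modeled: the effect under study is a partial-volume/displacement effect,
and Gibbs ringing emerges naturally from the truncation.

Signal-change maps are S_active - S_rest and the relative change masked
where the rest signal falls below 2% of its maximum (VASO-nulled tissue
creates singularities in the relative map; for the same reason the
~1/V resolution-scaling check is meaningful for PD and BOLD but not for
the VASO relative map).

## What the tests show — and do not show

The synthetic fixture reproduces the reference study's *structure*:
linear sweeps (R^2 > 0.99), volume slope > stiffness slope, additive
mechanisms at the percent level, kappa-insensitivity, 1/mu grid scaling,
layer-3 maximum and outer-layer dominance of the normalized response,
monotone growth with activated extent, bending-sign baseline stress,
contrast ordering VASO > BOLD > PD and ~1/V artifact scaling.  Absolute
crown displacements are geometry-bound: the moderate wall-to-wall fold
yields ~0.4/5.3/5.9 um (stiffness/volume/combined at 10%) versus
41/70/111 um on the deep traced gyrus it stands in for — its cortical
band is clamped at the lateral domain walls and its fold depth is capped
by the offset-construction guard, both of which suppress the long-range
lateral shift that dominates on a free-standing deep gyrus.  Passing
tests therefore validate the method and its trends, not subject-specific
magnitudes.  Additivity holds to ~4% of the combined response (0.24 um;
the residual is the genuine second-order coupling of the two mechanisms
through the shared segment — a volume change imposed kinematically
instead of via growth would remove it), and crown displacements agree
between the 206/143 um reference meshes to ~4 nm (~1% of the small
stiffness response) — the percentage is limited by the smallness of the
synthetic response, not by the solver (tolerances sit orders of
magnitude below it).

## Problem sizes

Default study: ~9k triangles (quadratic, ~36k dof) at the 206 um
reference mesh, ~18k at 143 um; unfolding in 20 steps plus 3
re-equilibration passes; scenario solves in 2 increments (path
independence verified).  The full reference pipeline (both meshes, three
scenarios, MR chain) runs in minutes on one CPU.
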