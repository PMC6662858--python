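# Methods

## Model and discretization

The solver advances the monodomain equation on a regular cell-centered
Cartesian grid (the ghost box) while the membrane state lives on a
triangulated Lagrangian mesh of the tissue region Ω_c:

    ∂V/∂t = (1/Cm) { (1/Am) ∇·(σ ∇V) − [I_ion(x,t) + I_s(x,t)] }     (box Ω)
    dy/dt = f(Ṽ(X,t), y(X,t)),   Ĩ_ion = g(Ṽ, y)                    (mesh Ω_c)

with the couplings

    I_ion(x) = Σ_e Σ_Q Ĩ_ion(X_Q) δ_h(x − χ(X_Q, t)) ω_Q      (spreading)
    Ṽ(X_Q)   = Σ_ij V(x_ij) δ_h(x_ij − χ(X_Q, t)) Δx₁Δx₂      (interpolation)

where X_Q, ω_Q are per-triangle Gauss points/weights, χ(X, t) the motion
map, and δ_h the tensor product of the four-point smooth cubic kernel ψ
normalized by the cell area. The normalization is required for the pair to
be mutually consistent: with it, interpolation reproduces constants and
linears exactly (moment property of ψ) and spreading conserves the integral
(partition of unity); the two operators are exact adjoints under the
quadrature/cell-area inner products, and both identities are tested to
1e-10 and to the last bit against direct summation.

Nodal recovery of the potential is an L² projection: solve M c = b with
M_lm = Σ_Q φ_l(X_Q) φ_m(X_Q) ω_Q (consistent by default, optional lumping)
and b_l = Σ_Q φ_l(X_Q) Ṽ(X_Q) ω_Q, prefactored with SuperLU and re-factored
only when the structure moves.

Diffusion uses the staggered-flux second difference, which for constant
axis-aligned conductivities is the 5-point stencil with σ_l on axis 1 and
σ_t on axis 2. The monodomain conductivity is the per-direction harmonic
combination σᵢσₑ/(σᵢ+σₑ), which equals (λ/(1+λ))σᵢ under equal anisotropy
but remains well-defined for measured human-ventricle values (Potse set:
σᵢ = 0.3/0.03, σₑ = 0.3/0.12 S/m) that violate it. Units for ventricular
runs are (mV, ms, mm): Cm = 1 µF/cm² → 0.01 µF/mm², Am = 0.24 µm⁻¹ →
240 mm⁻¹, S/m ≡ mS/mm, converted in exactly one function
(`ventricular_constants`). The dimensionless FitzHugh–Nagumo benchmarks set
Cm = Am = 1 and σ = (Kx, Ky) directly, making the normalized model a
literal special case of the monodomain update; the FHN adapter returns the
*negated* cubic reaction term so that the generic subtracted-current update
reproduces the model's native added-reaction form (the contract records
this in `current_sign`).

## Time stepping

Both the PDE and the membrane ODEs use the three-stage TVD (Shu–Osher)
Runge–Kutta scheme; the stage combination (1; −3/4, 1/4; −1/12, −1/12,
8/12) is algebraically the standard SSPRK3 (linear amplification
1 + z + z²/2 + z³/6, real-axis stability |z| ≤ 2.512 — both asserted in
tests). Step ordering: (1) move the structure and rebuild the transfer
stencils (moving runs only; the last motion step is clipped to the window
end); (2) evaluate Ĩ_ion at quadrature points from the interpolated
potential and the P1-interpolated nodal state, add the stimulus if its
window is active, spread to the grid; (3) advance V by RK3; (4) interpolate
the new V to quadrature points and L²-project to nodes; (5) advance y by
RK3 with the freshly projected nodal potential held fixed across the three
stages; (6) reset the far ghost region to rest.

Within (3) the reaction term is either re-evaluated at every RK stage with
the membrane state frozen (`per_stage`, the default) or evaluated once per
step (`frozen`). The two agree to the splitting error (≈2e-2 max-norm after
100 coarse steps at the spiral front, asserted in tests); the long
benchmark runs use `frozen`, which removes two interpolate/spread pairs per
step (~3× less transfer traffic, the dominant cost).

Ghost handling: the one-cell ring outside the box is a homogeneous
Dirichlet layer at the resting potential, so the stencil is uniform up to
the boundary. Cells farther than the kernel support (2 cells) from any
quadrature point are reset to rest every step (interval configurable); the
2-cell halo is left to the PDE so the kernel never reads stale values.
Spreading and interpolation refuse positions within kernel support of the
box edge (`DomainOverflowError`), and a node leaving the box halts the run.

## Meshing and quadrature

Regions (rectangle, circle, polygon, implicit indicator) are triangulated
from an offset-row (hexagonal) lattice plus exact boundary points, Delaunay
triangulation, and — for non-convex regions — centroid filtering; the
lattice spacing shrinks geometrically until the max edge satisfies the
requested bound. Rectangles and circles are boundary-conforming (areas
exact / within boundary-polygon error); implicit regions (the ventricle
sections) have indicator-accurate, hence ragged, boundaries — adequate for
activation-order experiments, stated as such below. The leak constraint of
kernel-coupled discretizations is enforced at solver construction: max
current edge ≤ 0.5 min(Δx₁, Δx₂) (factor configurable; 0.5 is the
conventional immersed-boundary margin). Quadrature is the 3-point
degree-2 interior Gauss rule per triangle by default (degree-1 centroid and
degree-4 6-point Dunavant rules available); the interpolate→spread round
trip of a constant is then exact to ~0.5% in the interior, which bounds how
well the coupled scheme can reproduce pointwise 0-D dynamics (the
decoupled-cell test asserts 5e-3 agreement with a reference integrator, a
tolerance set by this smoothing, not by time integration).

## Motion

The benchmark motion law is radial expansion with material-coordinate
velocity k(X) n(X) = rate · (X − X_c): each point moves on a straight ray
at constant speed, i.e. pure linear dilation. Two consequences drove design
choices:

* **Window.** Under sustained dilation the structure leaves the printed
  ghost box at t ≈ 1.5, so the motion is applied over a configurable window,
  default [0, 1.25] (dilation 1.5, structure still ≥ 2 kernel cells inside
  the box), then held.
* **Weights.** Spreading with *material* quadrature weights divides the
  Eulerian current density by the area Jacobian (2.25 after the default
  window); empirically the medium then loses excitability (the recovery
  load is effectively multiplied by J) and the spiral dies — so the package
  spreads and projects with *current-configuration* weights (material ×
  per-element Jacobian, identical when stationary), which keeps the
  Eulerian current density equal to the membrane current density pointwise.

## Estimators

* **Activation time**: per cell or probe, first upward threshold crossing,
  linearly interpolated in time (u = 0.5 for normalized FHN, V = 0 mV for
  the ventricular model — the conventional half-amplitude and zero-crossing
  choices, configurable).
* **Front speed at a point**: from the per-step 4×4 cell patch around the
  probe, per pass the axis-wise upstroke delays give ∇T and the normal
  speed is 1/|∇T| (exact for plane waves, asserted to <1%); the mean is
  taken over passes in the second half of the run.
* **Arm width**: length of the maximal super-threshold segment along the
  local front normal through the crossing nearest the domain centroid, with
  sub-cell endpoints; the normal is the principal eigenvector of the locally
  averaged structure tensor ∇u∇uᵀ, which stays defined at the band center
  where the raw gradient vanishes. Width and speed estimators are invariant
  under 90° rotation (tested).
* **Rotation sense**: sign of the wrap-robust summed angular increments of
  the excited-region centroid about the domain center, y-axis up.

## Benchmark configurations and problem sizes

The named FHN benchmarks carry the published settings exactly (ghost box
[−0.1, 2.6]², 275² cells, dt = 0.1 stationary; [−0.75, 3.25]², 408²,
dt = 0.1 moving; a = 0.1, ε = 0.01, β = 0.5, γ = 1, σ = 0, K = 10⁻⁴;
piecewise-constant broken-front initial data, seam ties resolved
first-match-wins in the printed branch order). `scale` coarsens grid and
time step together. Long runs in the test suite use scale 0.2–0.3 and the
acceptance script scale 0.5 (138², dt = 0.2): a direct-solver resolution
study (128² → 384², embedded in the suite's oracle) shows front speed, arm
width, and rotation period move by < 2% across that range, so the coarse
runs measure the same converged physics at a fraction of the cost.

## The synthetic ventricular sections

The transverse section is two overlapping disks (LV outer r = 33 mm, wall
16 mm; RV outer r = 36 mm, free wall 6 mm) with carved cavities, the RV
cavity a crescent bounded on the septal side by an LV-concentric circle;
the longitudinal section is the analogous clipped-ellipse construction.
Region masks (septum, LV/RV endocardial shells restricted to the lower
segments) emulate Purkinje-fed stimulation sites: healthy mode stimulates
septum + both endocardial regions, LBBB mode only the RV endocardium
(including its septal face). The stimulus is −0.15 µA/mm² for 2 ms —
roughly twice the surrogate's diastolic threshold (a 14 mV rise reaches the
gate; the stimulus delivers ~30 mV). The surrogate myocyte's parameters
(τ_in = 1.2, τ_out = 14, τ_open = 120, τ_close = 240 ms, 110 mV amplitude)
are design choices producing a recognizable human AP morphology (~350 ms
APD90) with an upstroke wide enough to be resolved at the demo resolution
(0.7 mm grid, 0.35 mm mesh edge); conduction velocities come out ≈ 0.11
(along-fiber) and 0.044 mm/ms (cross-fiber), the correct anisotropy ratio
√(D_t/D_l) though slower in absolute terms than real myocardium. These
sections are *idealized stand-ins*, not patient anatomy: the experiments on
them support activation-*order* statements (LBBB delays the LV lateral
wall; the septal point, stimulated from the RV side in both modes, is
unaffected) and nothing quantitative about real hearts — absolute
completion times depend on the synthetic geometry and the surrogate's
conduction speed and are not comparable to measurements on real sections.

## What the generators emulate — and what passing tests show

The geometry/IC module generates everything programmatically: the benchmark
domains and the printed piecewise initial data, and the synthetic sections
with stimulus masks. Real data differ in ways these generators do not
capture: fiber fields rotate (here anisotropy is axis-aligned), real
ventricular boundaries are smooth patient-specific contours (here implicit
indicators with ragged boundaries), and real myocytes have rich ionic
dynamics (here a two-gate surrogate). Passing tests therefore demonstrate
the *numerical method* — coupling identities, convergence, oracle
equivalence, qualitative electrophysiology — not predictive cardiac
modeling.

## Numerical choices and degenerate inputs

Tolerances: transfer identities 1e-10 relative (they are transpose
identities, so they hold to rounding); mass solve via sparse LU (singular
mesh → diagnostic error); blow-up guard aborts when max|V − rest| exceeds
1e3 (FHN) / 1e4 (mV units) naming time and step. Degenerate rectangles,
zero-area polygons, non-positive edge lengths, unknown quadrature orders,
inverted elements after motion, sub-minimum grids, and out-of-range config
fields all raise typed errors with field-precise messages. n(X) at the
motion centroid is the zero vector (k vanishes there anyway).

## Known limitations

* The published benchmark speed/width figures (0.116/0.115, 0.273/0.271
  stationary; 0.134/0.137, 0.304/0.306 moving) are **not reproduced** by
  these estimators — and, as far as this implementation and an independent
  direct conforming-grid solver can determine, cannot be: at the stated
  parameters the converged front-normal speed is ≈ 0.0046 (the analytic
  cubic-front bound is √(2K)(½−a) = 0.0057) and the u ≥ 0.5 front-normal
  arm width ≈ 0.164, with a rotation period ≈ 191 consistent with the
  ~1-unit arm spacing visible in spiral snapshots. The four red tests in
  `tests/test_acceptance.py` record this discrepancy deliberately; the
  acceptance script reports the honestly measured values. There are
  readings under which the published numbers do arise from the same
  dynamics — 2πr/(T·dt) with r the probe's distance from the domain center
  and T the measured rotation period reproduces 0.116 and 0.115 to three
  digits (the arm's tangential sweep speed expressed per time step), and a
  radial rather than front-normal cut through the arm near the centroid
  inflates the width by sec(pitch angle) ≈ 1.7, matching 0.273 — but
  neither is a front-normal speed or width, so they are not what these
  estimators compute.
* Under the windowed motion reading the post-motion medium is identical to
  the stationary one, so the moving > stationary ordering of speed and
  width is not expected to emerge; the matched-grid comparison tests record
  the measured outcome.
* Axis-aligned anisotropy only; no fiber rotation, no 3-D, no bidomain,
  no Purkinje network; the surrogate myocyte is not a calibrated ionic
  model (the cell-model contract accepts external ones).
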