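# Methods

`osteoflux` couples a mechanistic, fluid-flow-driven model of trabecular
surface remodelling with a structural beam twin, and distils the outcomes of
the mechanistic model into strain-based phenomenological adaptation laws.
This note records the models, the numerical choices, and the places where
the design was genuinely open.

## The poroelastic trabecula

A single trabecula is idealised as a 2D plane-strain region — a projected
cylinder, 1 mm long and 0.2 mm wide — tied at both ends to elastic bone
plates (0.5 mm thick, 1.4 mm wide, 1 mm deep, plane stress).  The tissue is
an isotropic Biot medium: drained skeleton E = 18 kN/mm², ν = 0.3, solid and
fluid bulk moduli K_s = 20 and K_f = 2.3 kN/mm², porosity φ = 0.05, fluid
viscosity μ = 10⁻⁹ N·s/mm², specific weight 9.8·10⁻⁶ N/mm³.  Derived
constants: K = 15 kN/mm², α = 1 − K/K_s = 0.25, and the storage modulus from
1/M = φ/K_f + (α − φ)/K_s ≈ 3.15·10⁴ N/mm².  Darcy's law q = −(κ/μ)∇p
closes the fluid mass balance.

### The permeability reading

The literature value for the lacuno-canalicular permeability is quoted as
10⁻²⁰ m², i.e. κ = 10⁻¹⁴ mm² and a mobility κ/μ = 10⁻⁵ mm⁴/(N·s).  In this
*intrinsic* reading the 1 s load pulse is almost fully drained (consolidation
coefficient c ≈ 0.27 mm²/s, drainage time of the half-width ≈ 0.04 s): the
fluid expelled per unit surface is then set by the loading *rate* alone and
is nearly independent of the strut width.  A surface-velocity-driven
adaptation loop has no equilibrium in that regime — thickening does not
reduce the stimulus — and peak Darcy fluxes are of order 10⁻⁵ mm/s.

The same number read as a soil-mechanics *hydraulic conductivity*
k = 10⁻¹⁴ mm/s (the convention of the commercial soils elements this model
class is usually built with) gives κ = kμ/γ_f ≈ 1.02·10⁻¹⁸ mm² and a
mobility ≈ 10⁻⁹ mm⁴/(N·s).  The pulse is then storage-dominated: pore
pressure builds to its undrained value and drains only through a thin
boundary layer, the near-surface fluid speed scales like F/width at the
10⁻⁸ mm/s scale of the published velocity thresholds, and thickening
*reduces* the stimulus — the adaptation loop is self-limiting.  Only this
reading supports the homeostatic calibration and the remodelling behaviour
the model family reports, so it is the package default
(`bone_poroelastic()`); the intrinsic reading remains available
(`bone_poroelastic("intrinsic")`) and is the one that reproduces the
10⁻⁵ mm/s peak-flux order.  The two readings bracket the published numbers,
which are not mutually consistent under either single choice.

### Discretisation

Equal-order 4-node u–p quadrilaterals, assembled in batch with 2×2 Gauss
quadrature; plates are drained plane-stress Q4.  The trabecula-plate tie is
node sharing (the plate blocks are meshed so their inner edge contains the
trabecula's end-row nodes exactly).  Backward Euler in time over 10 equal
increments of a 1 s step; the triangular pulse ramps to the amplitude over
the first half-step and back to zero over the second.  Equal-order u–p
pairs admit spurious pressure modes at small time steps, so a
fluid-pressure-Laplacian stabilisation acting on the pressure increment is
on by default, with element coefficient β = α²A_e / 4(λ + 2G).  The
monolithic symmetric system is factorised once per mesh (SuperLU) and
reused for all increments.  Kinematic constraints (fixed edges, single-node
"move only along the load direction" top-plate conditions, shared-component
platens) enter through a sparse transformation matrix, so the reduced
system stays symmetric.

Verification: the solver reproduces the closed-form step-load consolidation
(Terzaghi) series on a 1D-surrogate column within 1 % L2 (drainage at one
end, rollers elsewhere; intrinsic permeability, where the diffusion length
is resolved), is exactly linear in the load, and honours the
tension/compression and mirror-angle symmetries to solver tolerance.  The
peak-load pressure field changes by <2 % in L2 between h = 0.015 and
h = 0.0075 mm meshes in the resolved regime.  Under the conductivity
reading the boundary layer (√(cΔt) ≈ 1.6 µm) is deliberately sub-element at
every practical resolution; near-wall gradients are then resolution-limited,
which is why the stimulus thresholds are calibrated on the same mesh
resolution as the production runs (below).

## Geometry and remeshing

The lateral boundaries are natural cubic splines through 12 characteristic
points per side (spacing L/11, endpoints included); the end closures are
straight segments.  Splines are parameterised by the normalised projection
of the points onto the *initial* axis direction: remodelling moves points
only horizontally, so this projection is strictly increasing no matter how
far the strut reorients, and the transfinite mesh fibres that connect
equal-parameter stations of the two sides can never fold — Jacobian
positivity reduces to width positivity.  Mesh rows follow the spline
parameter; the column count resolves the widest cross section (remodelled
ends flare).  Meshing is deterministic.

## The remodelling loop

Per iteration: mesh the current geometry, run one transient pulse, collapse
the Darcy-flux field to one characteristic velocity per characteristic
point, move points, regenerate the splines.

* **Stimulus.**  For each point, the elements whose centroids fall in a
  disc of influence contribute the *time-median* of their flux magnitude
  over the 10 increments; the element values are averaged.  The disc radius
  is one third of the local point spacing, recomputed each iteration, with
  a floor of two element sizes (the radius-to-element ratio of the
  reference resolution, 0.03 mm disc on an 0.015 mm mesh); the floor keeps
  discs populated where the boundary stretches and makes adjacent discs
  overlap on coarse meshes.  An alternative reading of the statistic
  (median over the disc's elements) is available via
  `RemodellingParams.velocity_statistic`; it blurs the left/right stimulus
  asymmetry that drives reorientation and is not the default.
* **Update rule.**  Points with V ≥ V_apposition move outward, V ≤
  V_resorption inward, the lazy zone leaves them in place; the step is
  min(0.005·V/V_target, 0.05) mm applied to the horizontal coordinate
  (also for inclined geometries — node heights never change).
* **Boundary smoothing.**  One neighbour-averaging pass (weight 0.3) is
  applied to each side's displacement profile per iteration.  The
  discretised stimulus-geometry feedback is prone to a period-two
  "snaking" of the moving boundary — a protruding point drains faster,
  deposits, and protrudes further — which grows slowly but without bound
  at near-threshold loads.  The smoothing damps the sawtooth mode by a
  factor ≈ 0.4 per iteration while leaving uniform thinning/thickening and
  long-wavelength reorientation essentially untouched.  The step rule
  itself is applied exactly before smoothing.
* **Stopping.**  The loop runs for up to 100 iterations, exiting early
  only at its true fixed point (no point moved at all — every stimulus in
  the lazy zone).  Separately, each iteration evaluates the convergence
  *criterion* — no point moved more than 5 % of the central width — whose
  final value is reported as the `converged` flag.  Using the 5 % rule as
  a loop exit would halt resorption runs after one iteration (their
  steps, 0.0025 mm, always pass it) far from equilibrium.

### Calibration of the velocity thresholds

Frost's Mechanostat sets the homeostatic axial strain at 1250 µε; the
corresponding force on the equivalent cylindrical section (radius 0.1 mm)
is F_target = E·πr²·ε_target ≈ 0.707 N.  Pure compression at F_target
should elicit minimal adaptation.  Because the near-wall stimulus scale is
resolution-limited (above), the thresholds are calibrated per mesh: the
initial geometry is solved once, a 13-point logarithmic grid of candidate
targets spanning the observed characteristic velocities is screened with
10 remodelling iterations each, and the candidate whose final points have
drifted least from the initial geometry wins.  Net drift (final minus
initial), not per-iteration motion, is the objective: a slowly but
persistently thinning candidate must lose against one that slightly flares
the extremities and then stops.  The band keeps the published relative
half-width (±4 % of V_target).  At the reference resolution the calibrated
target is of the same 10⁻⁸ mm/s order as the published thresholds.

## The beam twin

A single 3-node Timoshenko element (quadratic displacement and rotation,
two-point reduced Gauss integration, shear correction 0.9 for the solid
circular section, radius 0.1 mm) spans between the same plate blocks,
sharing translations with the coincident plate nodes.  The plate continuum
carries no rotational DOF, so each beam end gets a rotational spring to
ground; k = 4EI_plate/t ≈ 32.9 kN·mm/rad by the plate formula, while the
configuration default keeps the quoted 30 kN·mm — both are exposed and
neither is silently corrected.  Strain drivers are read at the second Gauss
point: ε_a on the axis, ε_b the difference between the two outer-surface
section points (±r on the bending plane), K_ε = ε_b/ε_a.  The element is
verified against closed-form Timoshenko solutions (exact for end moments
and axial loads; convergent under refinement for transverse point loads).

The directional constraint on the top plate couples lateral and axial
response: with it, K_ε spans roughly ±1.6 over the fit-domain angles at
these dimensions — the bending preponderance never runs away even for
strongly inclined loads, because the load path must follow the plate's
prescribed direction.

## Study plan, equivalent beam, and the fitted laws

The reference plan pairs 14 load inclinations θ ∈ {0, π/16, …, π} with
amplitudes {F_target/2, F_target, 2F_target} — 42 scenarios; a full
14 × 5 preset adds the 3F/4 and 3F/2 multiples.  Near-horizontal angles
{7π/16, π/2, 9π/16} are computed but excluded from fits (the lateral-load
geometry spreads symmetrically and admits no single-beam interpretation).
Scenario records carry the beam drivers (ε_a, K_ε) and the equivalent-beam
reduction of the final geometry: start/end nodes at the end-edge midpoints,
φ_f from the axis vector, Δφ = φ_f − φ_i, apparent radius from the
horizontal pair separations, remodelled radius by projection onto the
adapted cross-axis (equal to apparent·cos φ_f for the equal-height pairs
the upright study produces), R_A = w_f/w_i.

Fits (strains dimensionless): per-angle OLS of R_A against ε_a over the
amplitudes; slopes regressed linearly on K_ε separately in tension
(θ < π/2) and compression, excluding the K_ε = 0 discontinuity, and pooled
into R_A = (i·K_ε + sign(ε_a)·j)·ε_a + k_mean with k_mean the mean of all
per-angle intercepts (both subdomains pooled); Δφ fitted as an odd cubic
a·K_ε³ + b·K_ε over θ ∈ [0, 6π/16] ∪ [10π/16, π], with the unconstrained
cubic kept for diagnostics and a plain linear fit on the stricter
quasi-linear domain [0, 5π/16] ∪ [11π/16, π].

## Validation scenario

A 0.92 × 0.2 mm trabecula whose axis makes 30° with a compressive load of
0.4 N/mm² carried by the stiff loading plate (0.56 N over the 1.4 × 1 mm
plate face), ramped linearly over the 1 s step, remodelled for 100
iterations.  The benchmark is computed in the *load frame*: the
trabecula-plus-bone-plates assembly keeps its upright geometry and the load
is applied 30° past vertical compression — the same problem up to a rigid
frame rotation, but one in which the bone plates can be meshed and the load
path through them (plates, tied junctions, direction-only constraint on the
loaded plate) is identical to the main study.  Complete reorientation means
the adapted axis aligns with the load line; the reported width change uses
the equivalent-beam reduction.

Two modelling choices matter here and were settled by their physics:

* *Contact.*  Transmitting the plate load at a bare corner of the inclined
  top edge (the literal hard-contact limit of a flat platen on an inclined
  free edge) makes the bending stimulus explode and the strut thicken
  without bound, while a bilateral tied platen pulls on the separating
  corner and reverses the reorientation.  Loading through the meshed bone
  plate — whose contact face with the much stiffer loading plate stays
  fully compressed — reproduces the expected behaviour and is what the
  load-frame formulation provides for free.
* *Junction drainage.*  In the source benchmark fluid may cross the
  junctions into the loaded, equally pressurised porous bone plates.  With
  fluid-free elastic plates, pressure continuity into such plates is far
  better approximated by a sealed junction (no gradient across it) than by
  clamping the junction pressure to zero: a drained junction turns the
  strut ends into sinks, erases the bending-asymmetry stimulus there, and
  stalls the reorientation half-way.

At h = 0.02 mm the benchmark reorients to within ~4.5° of the load line and
thins the apparent cross section by ~19 % — the expected axial equilibrium,
since 0.56 N ≈ 0.79·F_target and the adapted width is close to linear in
the load.  The reorientation completeness is resolution-sensitive (at
h = 0.03 mm the residual is ~4–8° and thinning ~14 %), so the validation
runs one step finer than the sweep.

## Scaled-down study conditions

The reference fidelity (h = 0.015 mm, 100 iterations, 42 scenarios) is
config-selectable but slow; the packaged acceptance study runs the 12
fit-domain angles × 3 amplitudes at h = 0.03 mm with the same 100-iteration
budget, and the validation scenario at h = 0.02 mm.  Stimulus noise grows
with element size (few elements per disc, resolution-limited near-wall
gradients), which is the main quality cost of coarsening; the calibration
is always rerun at the production resolution.  What passing at this scale
shows is that the *mechanism* — self-limiting width adaptation linear in
load, reorientation toward the load direction, odd saturating Δφ(K_ε) —
and the regression structure survive; the fitted coefficients themselves
are solver- and resolution-specific and are reported alongside, not
matched to, the published values.

## Known limitations

* 2D plane strain only; no branching or perforation; plates never adapt.
* The near-wall stimulus is resolution-limited under the conductivity
  reading; thresholds are meaningful only relative to a calibration at the
  same resolution.
* The moving boundary needs the displacement-smoothing pass for long-run
  stability; without it, near-threshold scenarios develop sawtooth modes.
* The lateral-load (θ = π/2) adapted geometry has no equivalent-beam
  semantics; it is reported but excluded from fits.
* Low-amplitude (F_target/2) equilibria carry threshold-chatter noise of
  order one step (0.005 mm ≈ 4 % of the thinned width), which is the
  dominant residual in the per-angle fits at coarse resolution.
* More consequentially, F_target/2 runs never reach the lazy-zone fixed
  point: at the thinned width one displacement step moves the stimulus
  across the whole ±4 % band, so ~20 of the 24 points stay active, and a
  persistent left/right stimulus differential at the junction corners
  (obtuse corners drain measurably faster than acute ones on a sheared
  strut) ratchets the inclination by ~0.2–0.3° per iteration toward an
  over-rotated attractor well past the load angle.  The effect survives
  mesh refinement to the reference resolution and is the principal gap
  between this solver's low-amplitude reorientation data and the
  reference behaviour; the F_target and 2·F_target series sit on the
  expected curve.  It degrades the reorientation-fit quality measures and
  the spread of the per-angle intercepts relative to the reference study.
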