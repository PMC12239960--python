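# Methods

`magjanus` simulates hard-magnetic Janus microrobots: hydrogel spheres
(diameter σ ≈ 0.5–1 mm) carrying a dense, permanently magnetised
NdFeB-composite spherical cap. Chains of such robots self-assemble through
dipole–dipole attraction, locomote on surfaces under programmed uniform
magnetic fields, and fragment or re-form when the field program changes.
This note records the model, its parameters, the numerical choices, and —
explicitly — what the model does and does not reproduce.

## Particle model

Each robot is a sphere with geometric centre **r**ᶜ and a body frame of two
orthonormal vectors: the symmetry axis **u** (pointing from the magnetic
cap toward the hydrogel pole) and the dipole direction **μ̂**, constrained
perpendicular to **u** (magnetisation of the cap is transverse to the
symmetry axis). The cap occupies a spherical cap of height *h*·σ
("sedimentation height" as a fraction of the diameter). Two derived
quantities place the magnetic physics at the cap rather than the centre:

* cap volume V_cap = (π/6) h²(3−2h) σ³,
* cap-centroid offset s = 3R(1−h)²/(3−2h), so the magnetic reference point
  is **r**ᵐ = **r**ᶜ − s **u**.

Loads:

* **Excluded volume** — WCA (purely repulsive truncated Lennard-Jones)
  between centres, cutoff 2^{1/6} σ, shifted so potential and force vanish
  continuously at the cutoff.
* **Dipole–dipole** — point dipoles of reduced magnitude m* at the
  magnetic points; forces act at **r**ᵐ, so the torque about the centre
  includes the lever arm (**r**ᵐ−**r**ᶜ)×**F**.
* **External field** — energy −**μ**·**B** (torque **μ**×**B**, no net
  force; all fields are spatially uniform).
* **Gravity/buoyancy** — split into the buoyancy-corrected hydrogel load
  (ρ_gel−ρ_w)V_sphere·g at the centre and the excess cap load
  (ρ_NdFeB−ρ_gel)V_cap·g at the cap centroid; the second term rights a free
  robot cap-down.
* **Walls** — planar rectangles with closest-feature contacts; a WCA-form
  repulsion in the centre-to-surface distance with effective σ_wall = R,
  plus Coulomb stick/slip friction (λ_s = 0.5, λ_d = 0.4) applied only to
  particles that are part of a chain (centre distance to a neighbour below
  1.1 σ); isolated robots roll rather than slide and get no friction.
  Friction resists the tangential applied force (stick inside the static
  cone, kinetic λ_d·N otherwise) and the yaw torque about the contact
  normal with effective contact radius R.

Dynamics are overdamped and athermal: γ **ṙ**ᶜ = ΣF and γ_r **ω** = ΣT,
with no inertia and no stochastic term. Randomness enters only through
seeded initial placements.

## Units and parameters

Reduced units: σ (one diameter), ε = 4.0694×10⁻¹⁰ J, τ = 1/60 s. For the
reference robot (σ = 600 μm, h = 0.33, ρ = 1.0/1.12/7.6 g/ml, dipole
moment μ = 1.08×10⁻⁶ A·m²):

| quantity | reduced | physical |
|---|---|---|
| translational damping γ | 0.3 | 5.65×10⁻⁶ kg/s |
| rotational damping γ_r | 0.1 (γ/3) | — |
| dipole magnitude m* | 1.152 | 1.08×10⁻⁶ A·m² |
| net buoyant weight | 2.90 ε/σ | 1.97 μN |
| field unit | 1 | 0.434 mT |
| timestep Δt | 10⁻³ τ | 16.7 μs |

The default cap fraction 0.33 makes the robot mass 0.313 mg and the net
buoyant weight 1.97 μN, the design point of the reference robot. For other
diameters, ε is rescaled with the particle volume: the reduced dipole
magnitude is then size-invariant and the physical drag coefficient scales
linearly with size, as for Stokes drag. The dipole moment scales with the
cap volume (fixed cap magnetisation), anchored at the measured moment of
the reference robot. The measured remanent moment 0.87×10⁻⁶ A·m², the
fabricated diameters 325/575/1082 μm, the coercivity and the tilt-threshold
field are available as presets (`geometry.MEASURED`); they are experimental
inputs, not simulator outputs.

## Short-range regularisation of the dipole interaction

The point-dipole pair interaction evaluated at cap centroids is singular:
when two caps face each other the magnetic points can approach to
(1−2s) σ ≈ 0.42 σ while the centre–centre WCA is still finite, and the
1/r³ energy then has no minimum — pairs collapse onto the singularity.
Physically the point approximation is meaningless below the cap's own
size. The dipole kernel therefore saturates below r_min = 0.8 σ: the 1/r
powers are evaluated at r_min while directions follow the true separation.
0.8 σ (= 480 μm for the reference robot) is the contact-scale magnetic gap
used in the analytic force budget, so all contact-scale physics is
untouched; the choice also makes head-to-tail chains, not cap-facing
pairs, the bonded ground state. Conservation-law and gradient tests apply
outside the saturated region.

## Integration

Explicit Euler with orientation updates by the exponential map (Rodrigues
rotation of **u** and **μ̂** about the angular-velocity axis), with
re-orthonormalisation of the body frame each step. At the nominal
Δt = 10⁻³ τ, stiff contacts (WCA + saturated-dipole bonds, wall contacts
under load) are beyond the explicit-stability limit and produce bounded
oscillations which stick/slip friction rectifies into spurious creep.
Each nominal step is therefore advanced by adaptive sub-steps capped at
0.005 σ displacement and 0.02 rad rotation per sub-step; in smooth regimes
this is exactly one plain Euler step. A step requiring more than 2000
sub-steps aborts with a diagnostic; the count of extra sub-steps is
reported per run. Halving the nominal timestep moves the endpoint of a
two-robot assembly run by < 10⁻³ σ.

## Field programs

All programs return the field in mT as a function of time in seconds:
static; rotating (in a coordinate plane, either sense); oscillating
(sinusoidal sweep between angular bounds, optionally with the whole plane
tilted or pitched); conical precession; piecewise schedules (holding the
last segment beyond the end). Presets carry the published gait parameters:
walking 4 mT/1 Hz rotating in the vertical plane; crawling 6 mT/3 Hz
sweeping −2π/3…π/3; swinging 6 mT/2 Hz sweeping ±π with the plane tilted
−30°; lateral 6 mT/3 Hz, ±π/3 with 6° pitch; assembly by horizontal
oscillation (8 mT/60 Hz) or conical precession (6 mT/32 Hz, 80° half-angle,
the half-angle chosen so the near-horizontal rotating component drives the
observed synchronised spinning); disassembly by switching the rotating
field to 20 Hz. The oscillation waveform is sinusoidal by default
(triangular available); the published angular amplitudes only bound the
sweep.

## Scenario initial states

A straight head-to-tail chain annealed for 60 τ under the horizontal
oscillating assembly field adopts a staggered (zigzag) configuration with
magnetic gaps at the contact scale; this state carries the chain's bending
stiffness and is the initial state of every chain scenario on terrain.
The vertical-plane gaits (walking, crawling) instead start from the
straight head-to-tail chain in the gait plane: the deterministic dynamics
preserves that mirror symmetry exactly, and the planar branch is the
straight-ahead two-step tumble seen experimentally (one body length
advanced per field period). The planar branch is unstable to out-of-plane
perturbation; the perturbed system settles into a slower leapfrog gait
(~0.9 σ per period instead of ~2 σ for the half-millimetre dimer at
10 Hz, i.e. ~4.5 mm/s instead of ~10 mm/s). Both branches are exact model
behaviour; the scenario defaults select the planar protocol and expose
`init="zigzag"` for the other.

## What the model reproduces

* The analytic force hierarchy: peak dipolar force ≈ 26 μN at the contact
  scale, an order of magnitude above the 1.97 μN net buoyant weight,
  itself far above the ~0.1 μN drag at 20 mm/s.
* Self-righting of a single robot (cap down within 1° in ≪ 100 τ).
* Dimerisation under a precessing field at intermediate cap fractions,
  with tighter binding at larger caps, and no dimerisation at h = 0.05
  within the 600 τ window (the scaled dipole is then too weak to bring the
  pair together).
* Assembly of eight robots into a single zigzag chain (efficiency 1.0)
  through transient dimers and trimers under the oscillating field.
* Walking and crawling speeds linear in the actuation frequency and
  increasing with chain length; the half-millimetre dimer at 10 Hz walks
  at ~10 mm/s (one body length per period).
* A swinging speed–frequency curve with an interior maximum (step-out).
  The in-model step-out is at ~10² Hz rather than a few hertz: the model
  has linear single-body drag only, no fluid inertia or hydrodynamic
  coupling, so orientations follow far faster than in the experiment.
* Fragmentation of an assembled 8-chain within tens of milliseconds of
  switching the rotating field to 20 Hz, with fast-rolling debris, and
  reassembly to efficiency 1.0 by the gather (conical) and chain
  (oscillating) programs inside a walled chamber.
* A chain under a static vertical field tilts up monotonically with field
  strength, with essentially no response at 0.5 mT — the qualitative
  torque-balance behind the measured sub-millitesla actuation threshold.
* Climbing of shallow inclines (~10°) by a walking chain, with ascent
  speed decreasing as the slope steepens.

## Known limitations

* **Chains open at slow vertical field crossings.** When a slow rotating
  field passes vertical, grounded side-by-side dipoles repel, and the
  interior particles of a chain feel cancelling vertical dipole forces, so
  rigid tumbling of long chains does not nucleate; chains transiently open
  and re-close each half period. Consequently steep-slope climbing
  (> ~10°) and stair ascent do not occur: the walker's swing lands short
  of a riser and the step edge's excluded-volume zone blocks the follow-up
  swing. The stairs and merge-to-climb scenarios ship with the published
  geometry and their tests document this as a model limitation.
* **Heavy-cap dimerisation failure is not reproduced.** The reported
  failure to dimerise at h ≈ 0.95 has no counterpart in this load split:
  the righting torque scale G_m·s ∝ h²(1−h)² vanishes as h → 1, so
  nothing prevents flipping; large-cap pairs bind strongly instead.
* **No noise, no flows.** Reassembly of scattered fragments relies on
  confinement and the gather program; a plain slow rotating field cannot
  bring distant fragments together (time-averaged lateral interactions are
  repulsive and the dynamics is deterministic).
* **No hydrodynamic interactions** beyond linear single-body drag; no
  rolling resistance for single robots (friction off entirely, as
  specified); no substrate compliance or wet adhesion.
* The cumulative cargo-release statistic, 100·(A₀−A_t)/A₀ on
  fluorescence-area series, is implemented as an analysis utility; the
  degradation experiments themselves are outside the simulator's scope.

## Problem sizes

Shipped scenarios use 2–8 particles, 60–600 τ (1–10 s of physical time) at
Δt = 10⁻³ τ, and run in seconds on one CPU core; the dimerisation sweep
uses the full published 600 τ observation window per cap fraction.
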