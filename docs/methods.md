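# Methods

`splenosim` models the capture and retention of sickle red blood cells
(RBCs) by splenic red-pulp macrophages under near-wall shear flow. This note
describes the models, their parameters, the reduced desk-scale mode used by
the shipped assays, and the calibration and numerical choices behind them.

## Physical picture

In the red pulp, slow Couette-like flow (~150 μm/s) carries RBCs past
macrophages adhered to the vessel wall. Receptor–ligand bonds between the
RBC membrane and the macrophage surface form and break stochastically;
whether a cell is retained depends on the balance between hydrodynamic drag
and the collective bond strength. Deoxygenation (hypoxia) stiffens sickle
RBCs (HbS polymerisation), distorts their shape toward the crescent form,
and strengthens adhesion — all three effects raise retention.

## Cell surfaces

RBC surfaces are closed triangulated meshes generated from a spherical
Fibonacci point set (convex-hull connectivity; a 500-vertex mesh always has
996 triangles and 1494 edges) mapped through an analytic shape function:

* **biconcave** — the Evans–Fung discocyte profile
  z(ρ) = ±(D₀/4)·√(1−ρ²)(C₀+C₁ρ²+C₂ρ⁴), D₀ = 7.82 μm,
  C₀ = 0.207161, C₁ = 2.002558, C₂ = −1.122762;
* **elongated** — a flattened triaxial ellipsoid (oval form);
* **granular** — a quasi-sphere with smooth seeded corrugation that stores
  the membrane's excess area;
* **sickle** — a tapered prolate body bent about its minor axis (crescent).

After mapping, a two-parameter Newton iteration rescales the *discrete* mesh
so that total area and enclosed volume hit the targets
S = 132.87 μm², V = 92.46 μm³ to ~1e−9 relative (for the granular form the
free parameters are global scale and corrugation amplitude, which keeps the
body round). Macrophages are rigid spherical caps (default apex height
h_M = 11 μm on an 8–11 μm radius) closed by a base disc on the wall.

## Membrane elasticity (3D)

The standard cellular-level model: wormlike-chain springs with a power-law
repulsive core (m = 2) on edges, dihedral-angle bending energy
k_b(1 − cos(θ − θ₀)), local and global area penalties, and a global volume
penalty. The stress-free reference is the as-generated mesh (per-edge rest
lengths, per-edge reference dihedrals, per-triangle reference areas), so the
reference configuration carries exactly zero force. The macroscopic shear
modulus maps to spring parameters through the hexagonal-network relation
(solved for the persistence length; the POW coefficient follows from force
balance at the rest length, per edge so every edge is individually
equilibrated); the flat-patch virtual-shear check reproduces the target
modulus within ~5%. Bending: k_b = 2E_b/√3.

Moduli: E_s0 = 4.792 μN/m and E_b0 = 2.9e−19 J for normal cells; sickle
cells are 5× stiffer under normoxia and 50× under hypoxia (both moduli).
Membrane viscosity is not modelled; dissipation comes entirely from the
solvent coupling. Forces are the exact analytic gradient of the energy
(validated against central finite differences to <1e−4 relative).

## Stochastic adhesion

The Hammer–Apte / Bell–Dembo bond model. Within the formation cutoff
d_on an unbonded membrane vertex binds to the nearest point of the
macrophage surface with probability P_on = 1 − exp(−k_on Δt),
k_on = k_on⁰ exp(−σ_on(l−l₀)²/2k_BT); a live bond breaks with
P_off = 1 − exp(−k_off Δt), k_off = k_off⁰ exp(−σ_off(l−l₀)²/2k_BT), and
ruptures deterministically once stretched to d_off (as printed, the
dissociation test is gated on l < d_off, which would make over-stretched
bonds unbreakable; the deterministic rupture closes that gap). Bonds are
Hookean springs (stiffness K_s, rest length l₀ = 0.3 μm,
d_on = d_off = 0.75 μm, σ_on = 0.51, σ_off = 0.17 μN/m); anchors are frozen
at formation (the macrophage is rigid); at most one bond per vertex.

Presets (μN/m, s⁻¹):

| preset   | K_s | k_on⁰  | k_off⁰ |
|----------|-----|--------|--------|
| normal   | 2.7 | 5.42e4 | 2.71   |
| normoxia | 2.9 | 5.42e4 | 2.71   |
| hypoxia  | 6.7 | 8.14e4 | 0.54   |

Adhesive sites sit on every second contour vertex (~1.2 μm apart,
comparable to d_on) — the resolution-dependent site density the one-bond-
per-vertex rule implies; a grazing contact engages only a few sites, which
keeps capture a genuine arrest race rather than a foregone conclusion.

The sickle rows are the published calibrated sets. No normal-RBC adhesion
strength is published; the `normal` K_s is obtained by the same
detachment-velocity fitting used for the sickle presets (fit to the
~500 μm/s release threshold of normal cells) with the normoxia kinetics.

RBC–RBC aggregation uses a Morse potential between vertices of distinct
cells, U = D_e[e^{−2β(r−r₀)} − 2e^{−β(r−r₀)}] with defaults
D_e = 15 k_BT per vertex pair, β = 3.84 μm⁻¹, r₀ = 0.4 μm, cutoff 1.6 μm
(adopted from the RBC rouleaux-modelling literature; strong enough that a
doublet survives 150 μm/s shear). With aggregation disabled the attractive
tail is removed and only the repulsive core remains as intercellular
excluded volume. The paired aggregation assay uses 10 cells over a 6 s
window; the clustering gain saturates once every cell is caught, so the
window is chosen short enough that the no-aggregation arm stays well below
ceiling.

## Solvent

Two coupling routes:

* **Explicit DPD** — soft conservative force a(1−r/r_c), pair-antisymmetric
  dissipative and random forces obeying fluctuation–dissipation
  (σ² = 2γk_BT), bounce-back walls dressed with frozen moving wall-particle
  layers, periodic in the flow direction. The number density, a and γ are
  not published for this system; defaults (density 4/r_c², a = 0.08 pN,
  γ = 4e−3 pN·s/μm, weight exponent 0.25, r_c = 1 μm, Δt = 2.5e−5 s) follow
  conventional DPD-water practice with the friction raised until the
  channel Reynolds number is small enough for laminar microflow, and hold
  the kinetic temperature within ~1% and a self-sustained linear Couette
  profile within 2%.
* **Ambient reduced coupling** — the desk-scale mode. The solvent is
  integrated out: each vertex feels Stokes drag toward the analytic Couette
  profile, a thermal force satisfying fluctuation–dissipation, gravity
  (settling at 4 μm/s, the observed RBC sedimentation scale), and a
  deformability-induced wall lift
  u_lift = γ̇ Λ (E_s0/E_s)/z², Λ = 1200 μm³.
  The lift term is the standard near-wall migration of deformable particles
  in shear: soft (normal/oxygenated) cells drift away from the wall, the
  50×-stiffened hypoxic cells barely at all, so stiff cells settle into the
  macrophage capture zone while soft ones ride above it. This mechanism —
  deformability-controlled margination — is what makes oxygenation control
  retention in the reduced model. An optional potential-flow deflection of
  the profile around each cap is available but off by default.

## Desk-scale calibration

The reduced model has two free hydrodynamic constants that cannot be taken
from the parameter tables: the whole-cell drag ζ_cell and the lift scale Λ.
They are fixed once, by the same observations the original calibration
used, and never varied per assay:

1. ζ_cell = 7.2e−3 pN·s/μm so that the fully specified sickle-normoxia
   preset detaches at ≈1000 μm/s in the velocity-ramp assay;
2. the normal-cell K_s = 2.7 μN/m so that normal cells detach at ≈500 μm/s
   (the published fitting procedure for the unpublished parameter);
3. Λ = 1200 μm³ so that the per-macrophage retention at 150 μm/s and 2%
   hematocrit reproduces the observed ≈2.7 (hypoxia) and ≈0.75 (normoxia)
   cells per macrophage.

With these fixed, the hypoxia detachment bound (>2500 μm/s), the
hypoxia/normoxia retention ratio (≈4), the flyby contact threshold
(≈500 μm/s) and the velocity dependence of retention are predictions of the
model, not fitted.

Suspension morphology follows oxygenation: normoxic suspensions use the
biconcave (oxygenated) form, hypoxic suspensions the crescent — HbS
polymerisation, which drives both the stiffening and the shape change, is
hypoxia-dependent. The single-cell detachment assays use the morphology of
the cell actually probed (biconcave for normal cells, crescent for sickle
cells in both oxygenation states).

## Reduced 2D dynamics

Cells are closed polygons (32 vertices): the (x, z) cross-sections of the
four morphologies, all normalised to the discocyte cross-section area
(≈13.4 μm²). Membrane terms: harmonic edge springs (k = 0.25·E_s),
turning-angle bending (k = 0.5·E_b/ℓ₀), global enclosed-area and perimeter
penalties (the 2D analogues of volume and area constraints). The 2D mapping
prefactors are model constants chosen for numerical robustness; the 2D mode
preserves the *ordering* of stiffnesses across oxygenation states, which is
what the assays rely on, not the absolute moduli.

Integration: symplectic Euler (force → kick → drift) with per-vertex mass
m = ζ_v·τ, τ = 1 ms, Δt = 2e−5 s — the state (x, v) is Markov, which makes
restart from a snapshot bitwise exact. Walls reflect; the flow direction is
periodic with unwrapped coordinates (minimum image applied to macrophage,
bond, and intercellular distances). All randomness comes from named Philox
streams keyed by (master seed, stream id, chunk index); runs are bitwise
reproducible and restartable at chunk boundaries. Reported times are
multiplied by the configurable `time_scaling` factor (an accelerated-clock
relabelling); dynamics are invariant to it.

Degenerate inputs: coincident vertices are guarded (no NaNs from zero-length
edges); a NaN position aborts the run with a timestep diagnostic; requesting
an unreachable hematocrit raises an error naming the achievable value.

## Assays

Desk-scale problem sizes (the package's own choices): detachment ramps hold
each 100 μm/s level for 0.25 s up to 2600 μm/s; retention runs 6 cells past
2 macrophages for 12 s; the aggregation pair runs 10 cells past 1 macrophage
for 6 s; the velocity panel 6 cells for 6 s per level; the shape panel
6 cells for 10 s; the flyby a single 300 μm approach. All suspensions use
Δt = 2e−5 s and 32-vertex contours.


* **Detachment**: one cell seated just above the cap apex, equilibrated at
  10 μm/s for 0.8 s, then the wall velocity ramps in 100 μm/s holds of
  0.25 s up to 2600 μm/s. Detachment = zero bonds sustained for 0.1 s while
  the centroid drifts >8 μm downstream; never-detaching cells are
  right-censored (reported as > max velocity).
* **Retention**: 6 cells, 2 macrophages, Hct set by channel length at fixed
  cell count (the experimental protocol), 12 s window, 5 seeds. Retained =
  ≥1 bond held ≥0.05 s and windowed centroid speed <10% of the bulk
  velocity. Plateau = count unchanged over the trailing 20% of the run.
* **Aggregation**: paired runs (same seeds) differing only in the Morse
  attraction; captures within 0.6 s of a neighbour's capture are classified
  as cluster filtration, isolated ones as transitive.
* **Hct sweep** {1.5, 2.8, 3.6, 5.0}% via channel-length scaling.
* **Velocity panel** 100–500 μm/s and a step-wise 1000→100 μm/s schedule;
  plus the single-cell flyby: a crescent released 300 μm upstream, 1.8 μm
  above the apex; contact = surface gap < d_on during the pass.
* **Shape panel**: the four morphologies and an equal mix under hypoxia.
* **Calibration**: the critical velocity rises monotonically and nearly
  linearly with K_s, so the fit evaluates a coarse K_s grid on an extended
  ramp (to 6000 μm/s, where even the hypoxia preset releases) and inverts a
  linear regression — robust to the ramp's 100–200 μm/s stochastic scatter;
  plus one-at-a-time sensitivity ranking of (K_s, k_on⁰, k_off⁰). The K_s
  sensitivity dominates by almost an order of magnitude; the mutual order
  of the two rate sensitivities sits at the resolution limit of the
  desk-scale ramp.

## What the reduced mode does and does not show

The 2D ambient mode resolves the force balance at the adhesion patch, the
stochastic bond kinetics at the printed rates, and transport by drift,
settling, and deformability lift. It does not resolve 3D flow around the
cap (no lubrication or wake), tank-treading (2D contours tumble), membrane
viscosity, or hydrodynamic interactions between cells; absolute retained
counts at desk scale are therefore meaningful mainly as ratios and
orderings across matched conditions, which is how all comparisons are
framed. Passing desk-scale checks demonstrates internal consistency of the
model and calibration, not quantitative fidelity to any particular real
channel.

Known limitations: the retained-count plateau does not fall at 400–500
μm/s as it should — at those velocities the arrest load on a first bond
(≈2 pN) is still below the hypoxic single-bond capacity K_s(d_off−l₀) =
3.0 pN and an arrested cell swings into multi-bond face contact, so capture
succeeds at every velocity in the panel; the decline presumably requires
the 3D contact and lubrication physics the ambient mode does not resolve
(the flyby no-contact threshold, in contrast, is reproduced). The shape
panel discriminates morphologies only through 2D contact geometry and
tumbling reach, which resolves the extremes (crescent highest, elongated
lowest) more reliably than the middle of the ranking; the rest-length l₀ = 0.3 μm sits above the 0–0.2 μm literature
range quoted alongside it (the published model's own choice, kept as is);
the 3D fidelity mode couples membranes to the DPD solvent by pair forces
without face bounce-back, so impermeability is approximate at desk
resolutions.
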