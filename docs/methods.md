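# Methods

This note documents the model behind `rdx`, the numerical choices, the
synthetic benchmark systems the validation studies run on, and what the
passing tests do and do not demonstrate.

## Model

### Particles and units

Particles are spheres with a type, a stable integer id and a 3D Cartesian
position. A type carries three physical parameters: a *collision radius*
`r_coll` (nm) at which pair repulsion switches on, a *reaction radius*
`r_react` (nm) defining the encounter complex for bimolecular reactions,
and a microscopic diffusion constant `D` (nm²/µs). Internal units are
fixed to nm / µs / kJ·mol⁻¹ with `k_B = 0.0083144621` kJ·mol⁻¹·K⁻¹, so
1·10⁻¹⁰ m²/s = 100 nm²/µs and `k_B·T` at 293.15 K is 2.4374 kJ/mol.
Friction and mass never appear explicitly: they are absorbed into `D`
through the fluctuation–dissipation relation. Diffusion constants of the
benchmark species follow Stokes–Einstein at 20 °C in water
(η = 1.0·10⁻³ Pa·s): `D = k_B·T / (6π·η·r)`, giving 143.1 / 71.6 /
68.82 nm²/µs for radii 1.5 / 3.0 / 3.12 nm.

### Dynamics

Positions follow overdamped, memoryless, isotropic Brownian motion with
the Euler step

    x(t+Δt) = x(t) − Δt·D/(k_B·T)·∇U(x) + sqrt(2·D·Δt)·ξ,

ξ a vector of independent standard normals. Assumptions: overdamped limit,
no memory, no hydrodynamic coupling, spherical particles. For small enough
Δt the chain samples the Boltzmann distribution `exp(−U/k_B·T)` between
reaction events; this is the handle used for validation. The default
Δt = 1·10⁻⁴ µs (0.1 ns) is the largest step on the discretization plateau
for the benchmark potentials (see *Timestep selection*).

A Metropolis Monte Carlo kernel targets the same Boltzmann distribution
without time-discretization error: one attempted Gaussian displacement per
particle per sweep in a seeded random order, accepted with
`min(1, exp(−ΔU/k_B·T))`. The proposal SD defaults to `sqrt(2·D·δ)` with a
nominal δ = 1·10⁻⁴ µs. Any valid Metropolis kernel samples the same
stationary law; agreement of stationary observables (RDFs), not kernel
identity, is the contract. The MC path doubles as the relaxation scheme:
dense uniform random starts contain overlaps whose forces would
destabilize direct BD, so benchmark builders relax 3000 sweeps before
integration (builders refuse nothing — they simply relax by default;
`relax_first=False` gives the raw start).

Implementation notes: the MC kernel evaluates ΔU against a neighbor list
frozen at the start of each sweep with a safety margin of 8 proposal SDs
above the interaction cutoff; a pair drifting beyond that margin within
one sweep is a ≫5σ event. Potential sets containing terms other than box
walls and pair terms fall back to a generic (slower, exact) per-particle
sweep. Neighbor enumeration is k-d-tree based with a brute-force O(N²)
oracle in the test suite; lists are rebuilt every step.

### Potentials

All terms are piecewise-harmonic ("soft-core"): flat in the allowed
region, `k/2·x²` beyond it. Order-1 (geometry) terms act on single
particles — box walls, a planar disk membrane (off-plane penalty plus
radial escape penalty), a sphere surface (radius 0 = isotropic well), and
a cylinder wall. Order-2 terms act on pairs: repulsion
`U = k/2·(d−σ)²` for `d < σ` with contact distance `σ = r_coll,i +
r_coll,j` (the only symmetric combination of per-type radii), an
attraction well (repulsive core continued by a negative harmonic well that
reaches zero at `r_cut = σ + width`; the functional form is this package's
own definition, chosen for continuity at σ and at the cutoff), and
explicit harmonic bonds addressed by particle id (the minimal group
mechanism; config group templates expand to particles plus bonds). The
default force constant k = 10 kJ·mol⁻¹·nm⁻² balances spatial exclusion
against the partial overlap that lets reaction partners approach
(quantified by the apparent radius below). Exactly coincident pair members
receive a deterministic +x fallback direction rather than an exception.
Periodic boundaries are deliberately not implemented: the benchmark
geometry uses repulsive walls, and all analysis (RDF normalization, MSD)
assumes a bounded box.

### Reactions

Five rule kinds: conversion A→B, fusion A+B→C, fission C→A+B, birth
(a source particle emits a product at one summed reaction radius in a
uniform random direction) and decay. Each rule carries a microscopic rate
λ (µs⁻¹); within a step the rule fires with the Poisson probability
`p = 1 − exp(−λ·Δt)`. Fusion candidates are unordered educt pairs closer
than `R = r_react,A + r_react,B` (one draw per pair per step). Accepted
events execute in a seeded random order under the conflict rule that a
particle reacts at most once per step; randomized order avoids systematic
bias toward low particle ids. Fusion products are placed at the
volume-weighted educt position (the larger educt moves less); fission
products are placed on a uniformly random axis through the educt,
volume-weighted offsets summing to the configured separation (default:
summed product reaction radii), so fission placement is the exact inverse
of fusion placement. Ids are never reused, making the event log an
unambiguous genealogy. Reversible reactions do **not** satisfy detailed
balance exactly — a known limitation of this reaction scheme.

### Rate calibration

For bimolecular reactions the measurable macroscopic rate constant mixes
diffusional encounter formation with intrinsic reactivity. With mutual
diffusion `D = D_A + D_B` and reaction distance `R`:

    k_macro(λ) = 4π·D·R·[1 − sqrt(D/λ)/R·tanh(R·sqrt(λ/D))]   (3D only)

interpolating between the reaction-limited limit `λ·(4/3)π·R³` and the
Smoluchowski ceiling `4π·D·R`. The inversion (`invert_erban`) brackets the
root from the reaction-limited bound and solves in log-λ with Brent's
method to 10⁻¹² relative; a small-argument series for `1 − tanh(a)/a`
keeps both regimes stable. `k_macro ≥ 4π·D·R` is rejected: no finite
intrinsic rate beats diffusion. A units bridge converts nm³/µs ↔ M⁻¹s⁻¹
(factor 6.022·10⁵).

## Benchmark systems (synthetic data)

All validation inputs are generated programmatically; there are no
external datasets. The reference system is a binary mixture: species A
(1.5 nm) and B (3.0 nm) with equal collision and reaction radii, product C
at the equal-volume radius `(1.5³+3³)^(1/3) = 3.12` nm, in a cubic box
with soft walls. Equal particle numbers fill an occupied volume fraction
φ: `N_A = N_B = round(φ·V_box/(V_A+V_B))` (half-away-from-zero), which
regenerates the published setups {158, 1572, 3144, 4716, 6288, 7860}
particles for φ = 1…50% in the 100 nm box. Placement is uniform random
(overlaps expected), then MC-relaxed. A quasi-2D variant restrains
particles to a disk membrane; its MSD analysis uses the planar `4·D·τ`
convention.

What the generator emulates: excluded volume at cytosol-like densities
(φ ≈ 30%) and beyond, size asymmetry, confinement. What it does not:
polydispersity beyond two sizes, attractive biology-specific interactions,
hydrodynamics, real macromolecular shapes. Passing tests therefore
demonstrate correctness of the algorithmic machinery and its calibration
theory on soft-sphere crowding — not quantitative transferability to any
particular cellular system.

## Analysis

**RDF.** `g(r)` is a pair-distance histogram (default Δr = 0.05 nm)
normalized per bin by the expected ideal-gas count. Because the box is
wall-bounded, the per-bin reference is computed numerically: ≥10⁶ uniform
point pairs are sampled in the actual box with a fixed internal seed and
histogrammed with the same bins. This equals the analytic boundary-
correction factor in expectation, works for any box, and is testable via
the ideal-gas invariant (uniform input ⇒ g ≡ 1).

**Apparent radius.** The first local maximum of g(r) is located after
5-bin moving-average smoothing; the area under the raw g on [0, r_max] is
split at 50%, and `r_app` is half that pair distance. The outer quantiles
default to (0.5%, 97.5%) — bracketing the overlap region — and are
configurable, since both (0.5, 97.5) and (2.5, 97.5) conventions exist for
such intervals. With k = 10 the 50% benchmark gives r_app(A) ≈ 1.29 nm
versus the nominal 1.5 nm: the soft potential admits that much overlap.

**MSD and diffusion constants.** MSD(τ) averages over particles and
sliding origins. In crowded systems the MSD is triphasic: free diffusion
at the shortest lags (`D_micro`, fitted on lags 1–5 steps), a slower
intermediate linear phase (`D_eff`, what FRAP-type experiments see), and a
finite-size plateau near `L²/2`. Because the apparent slope decays
continuously in a bounded box, the `D_eff` window is chosen by an a-priori
caging-length rule: the lag range where the species' MSD lies in
[σ², 4σ²] with σ its same-type contact distance — past the transition
(the particle has displaced beyond its own contact shell), before box
confinement. One rule for all species and densities. A log-log-slope
window selector (`effective_window`) is also provided for systems with a
genuine plateau.

**Timestep selection.** BD RDFs at candidate timesteps are compared
against the discretization-free MC reference; the plateau is the largest
Δt whose RMS error stays within a factor (default 2) of the smallest-Δt
error or of the MC-vs-MC statistical floor. For the benchmark potentials
Δt = 1·10⁻⁴ µs sits at the floor (measured ratio ≈ 1.0).

**Kinetics reference.** The well-mixed A+B⇌C ODE is integrated with an
adaptive 4th/5th-order scheme at 10⁻¹⁰ relative tolerance — at least two
orders tighter than simulation noise, so the oracle never limits the
comparison. At desk-scale box edges the bulk law `kf·c_A·c_B` acquires a
real geometric bias: a particle near a wall has part of its reaction
sphere outside the accessible volume (≈ 9R/8L, ~20% at L = 25 nm,
R = 4.5 nm), and the soft walls slightly enlarge that volume. The
reference therefore scales kf by the exact encounter-probability factor of
the bounded soft-wall geometry, computed from the Boltzmann
single-particle density (`soft_wall_encounter_probability`); the factor
tends to 1 in the bulk limit (≈0.95 already at the full 100 nm box).
Verified directly: stationary A–B pair counts within R match the
geometric prediction.

## Validation studies and problem sizes

The packaged studies (`rdx.validation`) run the full pipeline at reduced
box edges at the published densities, sized for minutes on one core:

* **Crowding** (`crowding_study`): φ = 50% in a 50 nm box (982 particles;
  40 nm, 504 particles in the test suite), 3000 relaxation sweeps, 2·10⁴
  BD steps at Δt = 10⁻⁴ µs recorded every step. Yields
  D_eff/D_micro ≈ 69% (A) and ≈ 42% (B), with D_eff strictly decreasing
  over φ ∈ {10, 30, 50}%.
* **Apparent radius** (`apparent_radius_study`): same benchmark, 4000 MC
  sweeps sampled every 20; r_app(A) ≈ 1.29 nm.
* **Stationary consistency** (`bd_mc_rdf_study`): φ = 50% in a 30 nm box;
  BD-vs-MC RDF RMS error ≈ 1.0× the MC-vs-MC floor.
* **Kinetics** (`kinetics_ode_study`): φ = 30% in a 25 nm box, 10
  replicates, k_f = 60 nm³/µs (reaction-limited: mixing time ≈ 1 µs ≪
  reaction time ≈ 7 µs), k_b set for ~50% conversion; replicate-mean
  product counts track the ODE within 3 SE at all checkpoints. The
  repulsion-on/off comparison (`crowding_kinetics_comparison`) uses faster
  rates so equilibration fits the budget; the direction of the crowding
  effect is rate-independent.

## Numerical choices and degenerate inputs

* Erban inversion: Brent in log-λ, relative tolerance 10⁻¹²; λ = 0 maps
  to k = 0 by limit.
* ODE: RK45, rtol 10⁻¹⁰.
* Coincident particles: deterministic +x repulsion axis, no exception.
* Reaction detection reuses the pre-move neighbor list with a margin of
  8 noise SDs over the fusion distance; forces see a superset pair list
  (terms vanish beyond range), so both stages share one list per step.
* Divergence guard: any non-finite coordinate or |x| > 10⁶ nm aborts with
  a hint to reduce Δt.
* Trajectories record float32 positions in memory (sub-10⁻⁵ nm relative
  error at box scale); all statistics accumulate in float64.
* Statistical tests estimate variances about known well centers (second
  moments), avoiding the downward bias of sample-mean subtraction under
  autocorrelation, and derive SEs from independent particles or block
  means.

## Known limitations

* No periodic boundaries, no hydrodynamic coupling, no inertial dynamics.
* Detailed balance is not enforced for reversible reactions; equilibria
  of fast reversible systems deviate accordingly.
* The rate bridge holds in 3D only; quasi-2D membrane systems get correct
  diffusion but no 2D rate-calibration theory.
* Group support is minimal (templates → particles + harmonic bonds); no
  rigid bodies, no moving geometry potentials (e.g. a diffusing spherical
  vesicle).
* Microscopic rates assume the full overlap volume is reactive; strong
  repulsion shrinks the accessible overlap and thus lowers realized
  macroscopic rates — visible in the crowded-kinetics study, and a regime
  where the calibration theory itself stops being exact.
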