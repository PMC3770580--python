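"""Programmatic construction of the benchmark systems.

The reference benchmark is a binary mixture of two spherical species in a
cubic container with repulsive walls (no periodic boundaries):

* species A: radius 1.5 nm, species B: radius 3.0 nm (typical sizes of
  abundant cytosolic macromolecules); collision and reaction radii equal;
* the association product C has the equal-volume radius
  (1.5^3 + 3^3)^(1/3) = 3.12 nm;
* diffusion constants from Stokes-Einstein at 20 degC in water
  (D_A = 143.1, D_B = 71.6, D_C = 68.8 nm^2/us);
* occupied volume fractions from 1% to 50% emulate macromolecular
  crowding (cytosol is around 30%);
* soft harmonic repulsion with k = 10 kJ/mol/nm^2 between all pairs and
  against the walls.

Initial placements are uniform random (overlaps included) and then relaxed
with the Metropolis sampler by default, because the overlap forces of a
raw dense start destabilize direct Brownian dynamics; ``relax_first=False``
skips the relaxation deliberately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    DEFAULT_TEMPERATURE,
    ParticleTypeSpec,
    SystemState,
    TypeRegistry,
    WATER_VISCOSITY,
    equal_volume_radius,
    make_rng,
    stokes_einstein_D,
)
from .potentials import BoxWall, DiskMembrane, PairRepulsion, PotentialSet
from .dynamics import relax

__all__ = [
    "BenchmarkSpec",
    "BenchmarkSystem",
    "benchmark_registry",
    "benchmark_particle_numbers",
    "build_benchmark_state",
    "build_membrane_disk_system",
]

#: Random-sphere packing bound for equal spheres in 3D.
_PACKING_BOUND = 0.74

#: Default number of relaxation sweeps before Brownian dynamics.
DEFAULT_RELAX_SWEEPS = 3000


def benchmark_registry(temperature: float = DEFAULT_TEMPERATURE,
                       viscosity: float = WATER_VISCOSITY) -> TypeRegistry:
    """The A/B/C type registry with Stokes-Einstein diffusion constants."""
    r_a, r_b = 1.5, 3.0
    r_c = equal_volume_radius(r_a, r_b)
    reg = TypeRegistry()
    for name, r in (("A", r_a), ("B", r_b), ("C", r_c)):
        reg.add(ParticleTypeSpec(
            name=name, collision_radius=r, reaction_radius=r,
            diffusion_constant=stokes_einstein_D(r, temperature, viscosity),
        ))
    return reg


def benchmark_particle_numbers(phi: float, box_edge: float = 100.0,
                               r_a: float = 1.5, r_b: float = 3.0) -> tuple[int, int]:
    """Equal A/B particle numbers filling a fraction ``phi`` of the box volume.

    N_A = N_B = round(phi * V_box / (V_A + V_B)) with sphere volumes
    V = (4/3) pi r^3; rounding is half-away-from-zero.
    """
    if not 0 < phi < _PACKING_BOUND:
        raise ValueError(
            f"occupied volume fraction must lie in (0, {_PACKING_BOUND}) "
            f"(sphere-packing bound), got {phi}"
        )
    v_box = box_edge**3
    v_pair = 4.0 / 3.0 * math.pi * (r_a**3 + r_b**3)
    n = int(math.floor(phi * v_box / v_pair + 0.5))
    return n, n


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one benchmark setup."""

    phi: float
    box_edge: float = 100.0
    force_constant: float = 10.0
    temperature: float = DEFAULT_TEMPERATURE
    relax_sweeps: int = DEFAULT_RELAX_SWEEPS
    include_repulsion: bool = True

    def __post_init__(self):
        if not 0 < self.phi <= 0.5:
            raise ValueError(f"supported occupied volume fractions are (0, 0.5], got {self.phi}")
        if self.box_edge <= 0:
            raise ValueError("box edge must be > 0")


@dataclass
class BenchmarkSystem:
    """A ready-to-run benchmark: state + potentials + the parameters that built it."""

    state: SystemState
    potentials: PotentialSet
    spec: BenchmarkSpec


def _benchmark_potentials(spec: BenchmarkSpec) -> PotentialSet:
    terms = [BoxWall(origin=(0.0, 0.0, 0.0),
                     extent=(spec.box_edge,) * 3,
                     force_constant=spec.force_constant)]
    if spec.include_repulsion:
        terms.append(PairRepulsion(force_constant=spec.force_constant))
    return PotentialSet(terms)


def build_benchmark_state(spec: BenchmarkSpec, seed, *, relax_first: bool = True
                          ) -> BenchmarkSystem:
    """Build (and by default MC-relax) a benchmark configuration.

    Particles are placed uniformly at random in the box — overlapping
    starts are expected at high density — and then relaxed for
    ``spec.relax_sweeps`` Metropolis sweeps. Identical seeds produce
    identical systems.
    """
    rng = make_rng(seed)
    registry = benchmark_registry(spec.temperature)
    n_a, n_b = benchmark_particle_numbers(spec.phi, spec.box_edge)
    state = SystemState.empty(registry, (0.0, 0.0, 0.0), (spec.box_edge,) * 3)
    state.add_particles("A", rng.uniform(0.0, spec.box_edge, size=(n_a, 3)))
    state.add_particles("B", rng.uniform(0.0, spec.box_edge, size=(n_b, 3)))
    potentials = _benchmark_potentials(spec)
    if relax_first and spec.relax_sweeps > 0 and spec.include_repulsion:
        state = relax(state, potentials, spec.relax_sweeps, rng,
                      temperature=spec.temperature)
    return BenchmarkSystem(state=state, potentials=potentials, spec=spec)


def build_membrane_disk_system(n: int, disk_radius: float, seed, *,
                               particle_radius: float = 1.5,
                               force_constant: float = 10.0,
                               temperature: float = DEFAULT_TEMPERATURE,
                               include_repulsion: bool = False
                               ) -> tuple[SystemState, PotentialSet]:
    """A quasi-2D membrane: particles restrained to a disk in the z = 0 plane.

    Coordinates stay three-dimensional; a disk-membrane potential penalizes
    off-plane excursions (harmonically, equilibrium variance k_B T / k) and
    in-plane escape beyond the disk radius. MSD analysis of such systems
    uses the planar 4 D tau convention (``fit_diffusion(..., ndim=2)``).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = make_rng(seed)
    reg = TypeRegistry([ParticleTypeSpec(
        name="M", collision_radius=particle_radius, reaction_radius=particle_radius,
        diffusion_constant=stokes_einstein_D(particle_radius, temperature),
    )])
    half = disk_radius + 10.0 * particle_radius
    state = SystemState.empty(reg, (-half, -half, -half), (half, half, half))
    rho = disk_radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    positions = np.stack([rho * np.cos(theta), rho * np.sin(theta), np.zeros(n)], axis=1)
    state.add_particles("M", positions)
    terms = [DiskMembrane(center=(0.0, 0.0, 0.0), radius=disk_radius,
                          force_constant=force_constant)]
    if include_repulsion:
        terms.append(PairRepulsion(force_constant=force_constant))
    return state, PotentialSet(terms)
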