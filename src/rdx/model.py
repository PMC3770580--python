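"""Domain types and the physical unit system.

Internal units are fixed throughout the package:

====================  ==========
quantity              unit
====================  ==========
length                nm
time                  us (microsecond)
energy                kJ/mol
temperature           K
diffusion constant    nm^2/us
force constant        kJ/mol/nm^2
rate (unimolecular)   1/us
rate (bimolecular)    nm^3/us
====================  ==========

With these conventions a diffusion constant of 1e-10 m^2/s equals
100 nm^2/us exactly, and the thermal energy k_B*T at 293.15 K is
2.4374 kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KB",
    "AVOGADRO",
    "DEFAULT_TEMPERATURE",
    "WATER_VISCOSITY",
    "thermal_energy",
    "stokes_einstein_D",
    "equal_volume_radius",
    "diffusion_to_si",
    "diffusion_from_si",
    "ParticleTypeSpec",
    "TypeRegistry",
    "Particle",
    "SystemState",
    "SimulationParameters",
    "make_rng",
]

#: Boltzmann constant (molar), kJ/mol/K.
KB = 0.0083144621
#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214129e23
#: Default simulation temperature (20 degC), K.
DEFAULT_TEMPERATURE = 293.15
#: Viscosity of water at 20 degC, Pa*s.
WATER_VISCOSITY = 1.0e-3

#: 1 m^2/s expressed in nm^2/us.
_M2_PER_S_TO_NM2_PER_US = 1.0e12


def thermal_energy(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol for a temperature in kelvin."""
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0 K, got {temperature}")
    return KB * temperature


def diffusion_to_si(d_nm2_us: float) -> float:
    """Convert a diffusion constant from nm^2/us to m^2/s."""
    return d_nm2_us / _M2_PER_S_TO_NM2_PER_US


def diffusion_from_si(d_m2_s: float) -> float:
    """Convert a diffusion constant from m^2/s to nm^2/us."""
    return d_m2_s * _M2_PER_S_TO_NM2_PER_US


def stokes_einstein_D(
    radius: float,
    temperature: float = DEFAULT_TEMPERATURE,
    viscosity: float = WATER_VISCOSITY,
) -> float:
    """Stokes-Einstein diffusion constant of a sphere, in nm^2/us.

    Parameters
    ----------
    radius
        Hydrodynamic radius in nm.
    temperature
        Temperature in K.
    viscosity
        Dynamic viscosity in Pa*s.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0 nm, got {radius}")
    if viscosity <= 0:
        raise ValueError(f"viscosity must be > 0 Pa*s, got {viscosity}")
    kbt_joule = thermal_energy(temperature) * 1e3 / AVOGADRO  # J per molecule
    d_si = kbt_joule / (6.0 * np.pi * viscosity * radius * 1e-9)  # m^2/s
    return diffusion_from_si(d_si)


def equal_volume_radius(r_a: float, r_b: float) -> float:
    """Radius of the sphere whose volume is the sum of two sphere volumes.

    Used to size a fusion product so that volume is conserved:
    r_C = (r_A^3 + r_B^3)^(1/3).
    """
    if r_a < 0 or r_b < 0:
        raise ValueError("radii must be non-negative")
    if r_a == 0 and r_b == 0:
        raise ValueError("at least one radius must be positive")
    return float((r_a**3 + r_b**3) ** (1.0 / 3.0))


@dataclass(frozen=True)
class ParticleTypeSpec:
    """Per-type physical parameters.

    Attributes
    ----------
    name
        Unique type identifier.
    collision_radius
        Onset distance of pair repulsion, nm. The contact distance of a
        pair is the sum of the two collision radii.
    reaction_radius
        Per-particle encounter radius, nm; a bimolecular reaction may fire
        when the pair distance is below the summed reaction radii.
    diffusion_constant
        Microscopic diffusion constant D, nm^2/us.
    """

    name: str
    collision_radius: float
    reaction_radius: float
    diffusion_constant: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("type name must be non-empty")
        for attr in ("collision_radius", "reaction_radius", "diffusion_constant"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}.{attr} must be > 0, got {getattr(self, attr)}")


class TypeRegistry:
    """Ordered registry of particle types with array views of their parameters."""

    def __init__(self, specs: Iterable[ParticleTypeSpec] = ()) -> None:
        self._specs: list[ParticleTypeSpec] = []
        self._index: dict[str, int] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: ParticleTypeSpec) -> int:
        if spec.name in self._index:
            raise ValueError(f"duplicate particle type name {spec.name!r}")
        self._index[spec.name] = len(self._specs)
        self._specs.append(spec)
        return self._index[spec.name]

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self):
        return iter(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, key: int | str) -> ParticleTypeSpec:
        if isinstance(key, str):
            return self._specs[self.index(key)]
        return self._specs[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, TypeRegistry) and self._specs == other._specs

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown particle type {name!r}; known: {list(self._index)}") from None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    @property
    def collision_radii(self) -> np.ndarray:
        return np.array([s.collision_radius for s in self._specs])

    @property
    def reaction_radii(self) -> np.ndarray:
        return np.array([s.reaction_radius for s in self._specs])

    @property
    def diffusion_constants(self) -> np.ndarray:
        return np.array([s.diffusion_constant for s in self._specs])

    def mask(self, names: Sequence[str] | None) -> np.ndarray:
        """Boolean mask over type indices; ``None`` selects every type."""
        if names is None:
            return np.ones(len(self), dtype=bool)
        m = np.zeros(len(self), dtype=bool)
        for n in names:
            m[self.index(n)] = True
        return m


@dataclass(frozen=True)
class Particle:
    """A single particle: stable id, type name and position (nm)."""

    id: int
    type_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"particle {self.id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class SystemState:
    """Positions, identities and types of all particles plus the box clock.

    Particle data is stored in parallel arrays for efficiency; the
    :class:`Particle` view is materialized on demand. The simulation box is
    the axis-aligned cuboid between ``box_origin`` (lower corner) and
    ``box_extent`` (upper corner), both in nm. Coordinates are continuous
    3D Cartesian; there are no periodic images.
    """

    registry: TypeRegistry
    ids: np.ndarray
    type_indices: np.ndarray
    positions: np.ndarray
    box_origin: np.ndarray
    box_extent: np.ndarray
    time: float = 0.0
    step_index: int = 0
    next_free_id: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.type_indices = np.asarray(self.type_indices, dtype=np.int32)
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.box_origin = np.asarray(self.box_origin, dtype=float)
        self.box_extent = np.asarray(self.box_extent, dtype=float)
        if np.any(self.box_extent <= self.box_origin):
            raise ValueError("box_extent must exceed box_origin componentwise")
        if len({int(i) for i in self.ids}) != len(self.ids):
            raise ValueError("particle ids must be unique")
        if len(self.ids) and self.next_free_id <= int(self.ids.max()):
            self.next_free_id = int(self.ids.max()) + 1

    @classmethod
    def empty(cls, registry: TypeRegistry, box_origin, box_extent) -> "SystemState":
        return cls(
            registry=registry,
            ids=np.empty(0, dtype=np.int64),
            type_indices=np.empty(0, dtype=np.int32),
            positions=np.empty((0, 3)),
            box_origin=box_origin,
            box_extent=box_extent,
        )

    @property
    def n_particles(self) -> int:
        return len(self.ids)

    @property
    def box_lengths(self) -> np.ndarray:
        return self.box_extent - self.box_origin

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_lengths))

    def particles(self) -> list[Particle]:
        names = self.registry.names
        return [
            Particle(int(i), names[t], p)
            for i, t, p in zip(self.ids, self.type_indices, self.positions)
        ]

    def type_counts(self) -> dict[str, int]:
        counts = np.bincount(self.type_indices, minlength=len(self.registry))
        return dict(zip(self.registry.names, (int(c) for c in counts)))

    def type_mask(self, names: Sequence[str] | str | None) -> np.ndarray:
        """Per-particle boolean mask selecting the given type names."""
        if isinstance(names, str):
            names = [names]
        return self.registry.mask(names)[self.type_indices]

    def add_particles(self, type_name: str, positions: np.ndarray) -> np.ndarray:
        """Append particles of one type; returns the ids assigned (never reused)."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        new_ids = np.arange(self.next_free_id, self.next_free_id + n, dtype=np.int64)
        self.ids = np.concatenate([self.ids, new_ids])
        self.type_indices = np.concatenate(
            [self.type_indices, np.full(n, self.registry.index(type_name), dtype=np.int32)]
        )
        self.positions = np.concatenate([self.positions, positions])
        self.next_free_id += n
        return new_ids

    def copy(self) -> "SystemState":
        return replace(
            self,
            ids=self.ids.copy(),
            type_indices=self.type_indices.copy(),
            positions=self.positions.copy(),
            box_origin=self.box_origin.copy(),
            box_extent=self.box_extent.copy(),
        )


@dataclass(frozen=True)
class SimulationParameters:
    """Fixed-step integration parameters.

    Attributes
    ----------
    dt
        Integration time step, us. The default of 1e-4 us (0.1 ns) is the
        validated step for the soft benchmark potentials (k = 10); see the
        timestep-selection analysis.
    temperature
        Temperature in K.
    seed
        Seed for the single per-run random stream.
    n_steps
        Number of steps to integrate.
    output_stride
        Record observables every this many steps.
    """

    dt: float = 1e-4
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    n_steps: int = 0
    output_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.output_stride < 1:
            raise ValueError(f"output_stride must be >= 1, got {self.output_stride}")

    @property
    def kbt(self) -> float:
        return thermal_energy(self.temperature)


def make_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """One reproducible random stream per run (identical seed => identical draws)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
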