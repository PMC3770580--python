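"""Harmonic interaction potentials: energies and analytic gradients.

Two families of terms compose the total potential energy U of a
configuration:

* *order-1* (geometry) terms depend on a single particle's coordinates:
  box walls, a disk membrane, a sphere surface, a cylinder wall;
* *order-2* (pair) terms depend on a particle pair: soft-core repulsion,
  a short-ranged attraction well, and explicit harmonic bonds.

All terms are harmonic (piecewise-quadratic), so particles inside their
allowed region feel no force and excursions are penalized with k/2 * x^2.
Energies are in kJ/mol, gradients in kJ/mol/nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import SystemState, TypeRegistry
from .neighbors import NeighborList, build_neighbor_list

__all__ = [
    "BoxWall",
    "PairRepulsion",
    "PairAttraction",
    "SphereSurface",
    "DiskMembrane",
    "CylinderWall",
    "HarmonicBond",
    "PotentialSet",
    "CompiledPotentials",
    "box_wall_eval",
    "pair_repulsion_eval",
    "pair_attraction_eval",
    "surface_eval",
    "total_energy_and_gradient",
]

#: Default harmonic force constant for repulsion and wall terms, kJ/mol/nm^2.
DEFAULT_FORCE_CONSTANT = 10.0

# Deterministic fallback direction for exactly coincident pair members.
_FALLBACK_AXIS = np.array([1.0, 0.0, 0.0])


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass(frozen=True)
class BoxWall:
    """Cuboid container: flat inside, quadratic penalty beyond each face."""

    origin: tuple = (0.0, 0.0, 0.0)
    extent: tuple = (100.0, 100.0, 100.0)
    force_constant: float = DEFAULT_FORCE_CONSTANT
    types: Optional[tuple] = None  # None = all types

    def __post_init__(self):
        o, e = _as_vec3(self.origin), _as_vec3(self.extent)
        if np.any(e <= o):
            raise ValueError("box extent must exceed origin componentwise")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")


@dataclass(frozen=True)
class PairRepulsion:
    """Soft-core repulsion: U = k/2 (d - sigma)^2 for d < sigma, else 0.

    The contact distance sigma is the sum of the two collision radii of the
    pair, taken from the type registry at compile time.
    """

    force_constant: float = DEFAULT_FORCE_CONSTANT
    types_a: Optional[tuple] = None
    types_b: Optional[tuple] = None

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")


@dataclass(frozen=True)
class PairAttraction:
    """Short-ranged attraction well with a repulsive core.

    Piecewise harmonic in the pair distance d, continuous everywhere:

    * d < sigma:          k_rep/2 (d-sigma)^2 - k_att/2 (r_cut-sigma)^2
    * sigma <= d < r_cut: k_att/2 (d-sigma)^2 - k_att/2 (r_cut-sigma)^2
    * d >= r_cut:         0

    with r_cut = sigma + width. The well minimum (depth
    k_att/2 (r_cut-sigma)^2) sits at contact.
    """

    force_constant_repulsion: float = DEFAULT_FORCE_CONSTANT
    force_constant_attraction: float = 1.0
    width: float = 2.0  # r_cut - sigma, nm
    types_a: Optional[tuple] = None
    types_b: Optional[tuple] = None

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("attraction width must be > 0 (r_cut > sigma)")
        if self.force_constant_repulsion < 0 or self.force_constant_attraction < 0:
            raise ValueError("force constants must be >= 0")


@dataclass(frozen=True)
class SphereSurface:
    """Harmonic restraint to a sphere surface: U = k/2 (|x-c| - R)^2.

    With radius 0 this is an isotropic harmonic well centered at ``center``.
    """

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 0.0
    force_constant: float = DEFAULT_FORCE_CONSTANT
    types: Optional[tuple] = None

    def __post_init__(self):
        if self.radius < 0 or self.force_constant < 0:
            raise ValueError("radius and force constant must be >= 0")


@dataclass(frozen=True)
class DiskMembrane:
    """Planar disk (normal +z): off-plane penalty k/2 z'^2 everywhere plus a
    radial penalty k/2 (rho - R)^2 for in-plane distance rho > R."""

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 1.0
    force_constant: float = DEFAULT_FORCE_CONSTANT
    types: Optional[tuple] = None

    def __post_init__(self):
        if self.radius <= 0 or self.force_constant < 0:
            raise ValueError("disk radius must be > 0 and force constant >= 0")


@dataclass(frozen=True)
class CylinderWall:
    """Cylindrical container (axis +z): radial penalty k/2 (rho - R)^2 for rho > R."""

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 1.0
    force_constant: float = DEFAULT_FORCE_CONSTANT
    types: Optional[tuple] = None

    def __post_init__(self):
        if self.radius <= 0 or self.force_constant < 0:
            raise ValueError("cylinder radius must be > 0 and force constant >= 0")


@dataclass(frozen=True)
class HarmonicBond:
    """Harmonic bond between two explicit particles: U = k/2 (d - length)^2."""

    id_i: int
    id_j: int
    force_constant: float = DEFAULT_FORCE_CONSTANT
    length: float = 0.0

    def __post_init__(self):
        if self.id_i == self.id_j:
            raise ValueError("bond must connect two distinct particles")
        if self.length < 0 or self.force_constant < 0:
            raise ValueError("bond length and force constant must be >= 0")


_SURFACE_KINDS = (SphereSurface, DiskMembrane, CylinderWall)


# ---------------------------------------------------------------------------
# Single-point evaluation (reference API; the engine uses the vectorized path)
# ---------------------------------------------------------------------------

def box_wall_eval(x, origin, extent, force_constant: float):
    """Energy and gradient of the cuboid wall term at one position."""
    x, o, e = _as_vec3(x), _as_vec3(origin), _as_vec3(extent)
    if np.any(e <= o):
        raise ValueError("degenerate box: extent must exceed origin")
    below = np.minimum(x - o, 0.0)
    above = np.maximum(x - e, 0.0)
    excess = below + above
    energy = 0.5 * force_constant * float(np.dot(excess, excess))
    grad = force_constant * excess
    return energy, grad


def pair_repulsion_eval(xi, xj, sigma: float, force_constant: float):
    """Energy and the two gradients of the soft-core repulsion for one pair."""
    xi, xj = _as_vec3(xi), _as_vec3(xj)
    delta = xi - xj
    d = float(np.linalg.norm(delta))
    if d >= sigma:
        return 0.0, np.zeros(3), np.zeros(3)
    direction = delta / d if d > 0 else _FALLBACK_AXIS.copy()
    coeff = force_constant * (d - sigma)  # negative: pushes the pair apart
    energy = 0.5 * force_constant * (d - sigma) ** 2
    grad_i = coeff * direction
    return energy, grad_i, -grad_i


def pair_attraction_eval(xi, xj, sigma: float, r_cut: float, k_rep: float, k_att: float):
    """Energy and gradients of the attraction well for one pair."""
    if r_cut <= sigma:
        raise ValueError("r_cut must exceed sigma")
    xi, xj = _as_vec3(xi), _as_vec3(xj)
    delta = xi - xj
    d = float(np.linalg.norm(delta))
    well_depth = 0.5 * k_att * (r_cut - sigma) ** 2
    if d >= r_cut:
        return 0.0, np.zeros(3), np.zeros(3)
    direction = delta / d if d > 0 else _FALLBACK_AXIS.copy()
    if d < sigma:
        energy = 0.5 * k_rep * (d - sigma) ** 2 - well_depth
        coeff = k_rep * (d - sigma)
    else:
        energy = 0.5 * k_att * (d - sigma) ** 2 - well_depth
        coeff = k_att * (d - sigma)
    grad_i = coeff * direction
    return energy, grad_i, -grad_i


def surface_eval(x, term):
    """Energy and gradient of a sphere/disk/cylinder geometry term at one position."""
    x = _as_vec3(x)
    c = _as_vec3(term.center)
    k = term.force_constant
    if isinstance(term, SphereSurface):
        delta = x - c
        d = float(np.linalg.norm(delta))
        excess = d - term.radius
        direction = delta / d if d > 0 else _FALLBACK_AXIS.copy()
        return 0.5 * k * excess**2, k * excess * direction
    if isinstance(term, DiskMembrane):
        z = x[2] - c[2]
        rho_vec = x[:2] - c[:2]
        rho = float(np.linalg.norm(rho_vec))
        energy = 0.5 * k * z**2
        grad = np.array([0.0, 0.0, k * z])
        if rho > term.radius:
            excess = rho - term.radius
            energy += 0.5 * k * excess**2
            grad[:2] = k * excess * rho_vec / rho
        return energy, grad
    if isinstance(term, CylinderWall):
        rho_vec = x[:2] - c[:2]
        rho = float(np.linalg.norm(rho_vec))
        if rho <= term.radius:
            return 0.0, np.zeros(3)
        excess = rho - term.radius
        grad = np.zeros(3)
        grad[:2] = k * excess * rho_vec / rho
        return 0.5 * k * excess**2, grad
    raise TypeError(f"not a surface term: {term!r}")


# ---------------------------------------------------------------------------
# Compilation to arrays
# ---------------------------------------------------------------------------

PAIR_NONE, PAIR_REPULSION, PAIR_ATTRACTION = 0, 1, 2


@dataclass
class CompiledPotentials:
    """Array form of a :class:`PotentialSet` against one type registry.

    Pair terms become (T, T) matrices indexed by type; the per-pair contact
    distance sigma is the sum of the two collision radii. ``cutoff`` is the
    largest pair-interaction range (bond terms are evaluated by explicit id
    and do not enter the neighbor cutoff).
    """

    n_types: int
    pair_mode: np.ndarray  # (T, T) int8
    pair_sigma: np.ndarray  # (T, T)
    pair_k_rep: np.ndarray  # (T, T)
    pair_k_att: np.ndarray  # (T, T)
    pair_r_cut: np.ndarray  # (T, T)
    walls: list  # of BoxWall
    wall_masks: list  # of (T,) bool
    surfaces: list  # of surface terms
    surface_masks: list
    bonds: list  # of HarmonicBond
    cutoff: float

    @property
    def has_pair_terms(self) -> bool:
        return bool(np.any(self.pair_mode != PAIR_NONE))

    @property
    def mc_kernel_supported(self) -> bool:
        """True when the fast Metropolis kernel covers every term (walls + pair terms)."""
        return not self.surfaces and not self.bonds


class PotentialSet:
    """Ordered collection of potential terms composing the total energy U.

    When several pair terms cover the same type pair, the later term
    overrides the earlier one for that pair.
    """

    def __init__(self, terms: Sequence = ()) -> None:
        self.terms = list(terms)

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)

    def add(self, term) -> "PotentialSet":
        self.terms.append(term)
        return self

    def compile(self, registry: TypeRegistry) -> CompiledPotentials:
        t = len(registry)
        pair_mode = np.zeros((t, t), dtype=np.int8)
        pair_sigma = np.zeros((t, t))
        pair_k_rep = np.zeros((t, t))
        pair_k_att = np.zeros((t, t))
        pair_r_cut = np.zeros((t, t))
        r_coll = registry.collision_radii
        sigma_matrix = r_coll[:, None] + r_coll[None, :]

        walls, wall_masks = [], []
        surfaces, surface_masks = [], []
        bonds = []
        for term in self.terms:
            if isinstance(term, BoxWall):
                walls.append(term)
                wall_masks.append(registry.mask(term.types))
            elif isinstance(term, PairRepulsion):
                sel = np.outer(registry.mask(term.types_a), registry.mask(term.types_b))
                sel = sel | sel.T
                pair_mode[sel] = PAIR_REPULSION
                pair_sigma[sel] = sigma_matrix[sel]
                pair_k_rep[sel] = term.force_constant
                pair_r_cut[sel] = sigma_matrix[sel]
            elif isinstance(term, PairAttraction):
                sel = np.outer(registry.mask(term.types_a), registry.mask(term.types_b))
                sel = sel | sel.T
                pair_mode[sel] = PAIR_ATTRACTION
                pair_sigma[sel] = sigma_matrix[sel]
                pair_k_rep[sel] = term.force_constant_repulsion
                pair_k_att[sel] = term.force_constant_attraction
                pair_r_cut[sel] = sigma_matrix[sel] + term.width
            elif isinstance(term, _SURFACE_KINDS):
                surfaces.append(term)
                surface_masks.append(registry.mask(term.types))
            elif isinstance(term, HarmonicBond):
                bonds.append(term)
            else:
                raise TypeError(f"unknown potential term {term!r}")
        cutoff = float(pair_r_cut.max()) if t else 0.0
        return CompiledPotentials(
            n_types=t,
            pair_mode=pair_mode,
            pair_sigma=pair_sigma,
            pair_k_rep=pair_k_rep,
            pair_k_att=pair_k_att,
            pair_r_cut=pair_r_cut,
            walls=walls,
            wall_masks=wall_masks,
            surfaces=surfaces,
            surface_masks=surface_masks,
            bonds=bonds,
            cutoff=cutoff,
        )


# ---------------------------------------------------------------------------
# Vectorized evaluation
# ---------------------------------------------------------------------------

def order1_energy_gradient(positions: np.ndarray, type_indices: np.ndarray,
                           compiled: CompiledPotentials):
    """Sum of all order-1 (geometry) terms over all particles."""
    n = len(positions)
    energy = 0.0
    grad = np.zeros((n, 3))
    for term, mask in zip(compiled.walls, compiled.wall_masks):
        sel = mask[type_indices]
        if not np.any(sel):
            continue
        x = positions[sel]
        o, e = _as_vec3(term.origin), _as_vec3(term.extent)
        excess = np.minimum(x - o, 0.0) + np.maximum(x - e, 0.0)
        energy += 0.5 * term.force_constant * float(np.sum(excess * excess))
        grad[sel] += term.force_constant * excess
    for term, mask in zip(compiled.surfaces, compiled.surface_masks):
        sel = mask[type_indices]
        if not np.any(sel):
            continue
        x = positions[sel]
        c = _as_vec3(term.center)
        k = term.force_constant
        g_local = np.zeros_like(x)
        if isinstance(term, SphereSurface):
            delta = x - c
            d = np.linalg.norm(delta, axis=1)
            excess = d - term.radius
            energy += 0.5 * k * float(np.sum(excess**2))
            safe = np.where(d > 0, d, 1.0)
            direction = delta / safe[:, None]
            direction[d == 0] = _FALLBACK_AXIS
            g_local = k * excess[:, None] * direction
        elif isinstance(term, DiskMembrane):
            z = x[:, 2] - c[2]
            rho_vec = x[:, :2] - c[:2]
            rho = np.linalg.norm(rho_vec, axis=1)
            energy += 0.5 * k * float(np.sum(z**2))
            g_local[:, 2] = k * z
            out = rho > term.radius
            if np.any(out):
                excess = rho[out] - term.radius
                energy += 0.5 * k * float(np.sum(excess**2))
                g_local[out, :2] = k * excess[:, None] * rho_vec[out] / rho[out, None]
        else:  # CylinderWall
            rho_vec = x[:, :2] - c[:2]
            rho = np.linalg.norm(rho_vec, axis=1)
            out = rho > term.radius
            if np.any(out):
                excess = rho[out] - term.radius
                energy += 0.5 * k * float(np.sum(excess**2))
                g_local[out, :2] = k * excess[:, None] * rho_vec[out] / rho[out, None]
        grad[sel] += g_local
    return energy, grad


def pair_energy_gradient(positions: np.ndarray, type_indices: np.ndarray,
                         compiled: CompiledPotentials, pairs: np.ndarray):
    """Sum of repulsion/attraction terms over the supplied pair list."""
    n = len(positions)
    grad = np.zeros((n, 3))
    if len(pairs) == 0 or not compiled.has_pair_terms:
        return 0.0, grad
    if pairs.max() >= n:
        raise ValueError("pair list refers to particle indices beyond the state (stale list)")
    i, j = pairs[:, 0], pairs[:, 1]
    ti, tj = type_indices[i], type_indices[j]
    mode = compiled.pair_mode[ti, tj]
    active = mode != PAIR_NONE
    if not np.any(active):
        return 0.0, grad
    i, j, ti, tj, mode = i[active], j[active], ti[active], tj[active], mode[active]
    delta = positions[i] - positions[j]
    d = np.linalg.norm(delta, axis=1)
    sigma = compiled.pair_sigma[ti, tj]
    k_rep = compiled.pair_k_rep[ti, tj]
    k_att = compiled.pair_k_att[ti, tj]
    r_cut = compiled.pair_r_cut[ti, tj]
    well = 0.5 * k_att * (r_cut - sigma) ** 2

    core = d < sigma
    shell = (mode == PAIR_ATTRACTION) & (d >= sigma) & (d < r_cut)
    energy_terms = np.zeros_like(d)
    coeff = np.zeros_like(d)
    energy_terms[core] = 0.5 * k_rep[core] * (d[core] - sigma[core]) ** 2
    coeff[core] = k_rep[core] * (d[core] - sigma[core])
    is_att = mode == PAIR_ATTRACTION
    energy_terms[core & is_att] -= well[core & is_att]
    energy_terms[shell] = 0.5 * k_att[shell] * (d[shell] - sigma[shell]) ** 2 - well[shell]
    coeff[shell] = k_att[shell] * (d[shell] - sigma[shell])

    touched = core | shell
    direction = np.zeros_like(delta)
    dn = d.copy()
    coincident = touched & (d == 0)
    dn[d == 0] = 1.0
    direction = delta / dn[:, None]
    direction[coincident] = _FALLBACK_AXIS
    gvec = coeff[:, None] * direction
    for axis in range(3):
        grad[:, axis] += np.bincount(i, weights=gvec[:, axis], minlength=n)
        grad[:, axis] -= np.bincount(j, weights=gvec[:, axis], minlength=n)
    return float(np.sum(energy_terms)), grad


def bond_energy_gradient(state: SystemState, compiled: CompiledPotentials):
    """Harmonic bonds addressed by explicit particle id."""
    energy = 0.0
    grad = np.zeros((state.n_particles, 3))
    if not compiled.bonds:
        return energy, grad
    id_to_index = {int(pid): k for k, pid in enumerate(state.ids)}
    for bond in compiled.bonds:
        try:
            a, b = id_to_index[bond.id_i], id_to_index[bond.id_j]
        except KeyError as exc:
            raise KeyError(f"bond references missing particle id {exc.args[0]}") from None
        delta = state.positions[a] - state.positions[b]
        d = float(np.linalg.norm(delta))
        direction = delta / d if d > 0 else _FALLBACK_AXIS.copy()
        excess = d - bond.length
        energy += 0.5 * bond.force_constant * excess**2
        g = bond.force_constant * excess * direction
        grad[a] += g
        grad[b] -= g
    return energy, grad


def total_energy_and_gradient(state: SystemState, potentials: PotentialSet,
                              pairs: np.ndarray | NeighborList | None = None,
                              compiled: CompiledPotentials | None = None):
    """Total potential energy and per-particle gradient array.

    ``pairs`` must cover every pair within the set's cutoff; if omitted, a
    neighbor list is built internally.
    """
    if compiled is None:
        compiled = potentials.compile(state.registry)
    if isinstance(pairs, NeighborList):
        pairs = pairs.pairs
    if pairs is None:
        if compiled.cutoff > 0 and compiled.has_pair_terms:
            pairs = build_neighbor_list(state.positions, compiled.cutoff).pairs
        else:
            pairs = np.empty((0, 2), dtype=np.int64)
    u1, g1 = order1_energy_gradient(state.positions, state.type_indices, compiled)
    u2, g2 = pair_energy_gradient(state.positions, state.type_indices, compiled, pairs)
    ub, gb = bond_energy_gradient(state, compiled)
    return u1 + u2 + ub, g1 + g2 + gb
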