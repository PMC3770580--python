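"""Propagators: Brownian dynamics and Metropolis Monte Carlo.

Brownian dynamics uses the Euler discretization of overdamped isotropic
diffusion: each step a particle with diffusion constant D moves by

    dx = -dt * D / (k_B T) * grad U  +  sqrt(2 D dt) * xi,

with xi a vector of three independent standard normals. The drift and the
noise are linked by the fluctuation-dissipation relation, so for dt small
enough the chain samples the Boltzmann distribution exp(-U / k_B T).

The Monte Carlo sweep is a Metropolis kernel targeting the same Boltzmann
distribution exactly (no time-discretization error): one attempted Gaussian
displacement per particle, in a seeded random order, accepted with
min(1, exp(-dU / k_B T)). It is used to relax overlapping initial
configurations and as the discretization-free reference sampler for
stationary observables such as the radial distribution function.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from numba import njit

from .model import SimulationParameters, SystemState, make_rng, thermal_energy, DEFAULT_TEMPERATURE
from .neighbors import build_neighbor_list
from .potentials import (
    CompiledPotentials,
    PotentialSet,
    total_energy_and_gradient,
    surface_eval,
    box_wall_eval,
)

__all__ = ["bd_step", "bd_displacements", "bd_run", "mc_sweep", "relax", "sample_mc"]

logger = logging.getLogger(__name__)

#: Nominal time step used to size the default MC proposal width, us.
_MC_NOMINAL_DT = 1e-4
#: Safety margin on the frozen MC neighbor list, in units of the proposal SD.
_MC_MARGIN_SDS = 8.0


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

def bd_displacements(state: SystemState, gradient: np.ndarray, dt: float,
                     temperature: float, rng: np.random.Generator) -> np.ndarray:
    """Drift plus noise displacements for one Euler step (does not move particles)."""
    d_per_type = state.registry.diffusion_constants
    d = d_per_type[state.type_indices][:, None]
    kbt = thermal_energy(temperature)
    drift = -(dt / kbt) * d * gradient
    noise = np.sqrt(2.0 * d * dt) * rng.standard_normal(state.positions.shape)
    return drift + noise


def bd_step(state: SystemState, potentials: PotentialSet, params: SimulationParameters,
            rng: np.random.Generator, *, compiled: CompiledPotentials | None = None,
            pairs: np.ndarray | None = None) -> SystemState:
    """Advance a copy of ``state`` by one Brownian-dynamics step of ``params.dt``.

    Particle count, ids and types are unchanged; the clock advances by dt.
    """
    if compiled is None:
        compiled = potentials.compile(state.registry)
    _, grad = total_energy_and_gradient(state, potentials, pairs=pairs, compiled=compiled)
    if not np.all(np.isfinite(grad)):
        bad = int(np.nonzero(~np.all(np.isfinite(grad), axis=1))[0][0])
        raise FloatingPointError(
            f"non-finite potential gradient for particle id {int(state.ids[bad])} "
            f"(type {state.registry.names[state.type_indices[bad]]}) at step {state.step_index}"
        )
    new = state.copy()
    new.positions = state.positions + bd_displacements(state, grad, params.dt,
                                                       params.temperature, rng)
    new.time = state.time + params.dt
    new.step_index = state.step_index + 1
    return new


def bd_run(state: SystemState, potentials: PotentialSet, params: SimulationParameters,
           rng: np.random.Generator, *, record_stride: int = 1,
           record_dtype=np.float32) -> tuple[SystemState, np.ndarray]:
    """Integrate ``params.n_steps`` reaction-free BD steps, recording positions.

    Returns the final state and an (F, N, 3) trajectory array containing the
    initial frame plus every ``record_stride``-th step. Composition is fixed,
    so the trajectory is a plain array; use the engine for reactive runs.
    Coordinates beyond 1e6 nm abort with a hint to reduce the timestep.
    """
    compiled = potentials.compile(state.registry)
    rng = make_rng(rng)
    new = state.copy()
    positions = new.positions
    d = state.registry.diffusion_constants[new.type_indices][:, None]
    kbt = thermal_energy(params.temperature)
    drift_scale = params.dt / kbt
    noise_scale = np.sqrt(2.0 * d * params.dt)
    frames = [positions.astype(record_dtype)]
    needs_pairs = compiled.has_pair_terms and compiled.cutoff > 0
    from .potentials import order1_energy_gradient, pair_energy_gradient, bond_energy_gradient

    for step in range(params.n_steps):
        _, grad = order1_energy_gradient(positions, new.type_indices, compiled)
        if needs_pairs:
            pairs = build_neighbor_list(positions, compiled.cutoff).pairs
            _, g2 = pair_energy_gradient(positions, new.type_indices, compiled, pairs)
            grad += g2
        if compiled.bonds:
            _, gb = bond_energy_gradient(new, compiled)
            grad += gb
        positions += (-drift_scale * d) * grad
        positions += noise_scale * rng.standard_normal(positions.shape)
        if (step + 1) % record_stride == 0:
            frames.append(positions.astype(record_dtype))
        if (step + 1) % 200 == 0:
            peak = np.max(np.abs(positions))
            if not np.isfinite(peak) or peak > 1e6:
                raise FloatingPointError(
                    f"coordinates diverged beyond 1e6 nm at step {step + 1}; "
                    "the timestep is likely too large for the potential stiffness"
                )
    new.positions = positions
    new.time = state.time + params.n_steps * params.dt
    new.step_index = state.step_index + params.n_steps
    return new, np.stack(frames)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_energy(dx, dy, dz, mode, sigma, k_rep, k_att, r_cut):
    d = math.sqrt(dx * dx + dy * dy + dz * dz)
    if mode == 1:  # repulsion
        if d < sigma:
            return 0.5 * k_rep * (d - sigma) ** 2
        return 0.0
    if mode == 2:  # attraction well
        if d >= r_cut:
            return 0.0
        well = 0.5 * k_att * (r_cut - sigma) ** 2
        if d < sigma:
            return 0.5 * k_rep * (d - sigma) ** 2 - well
        return 0.5 * k_att * (d - sigma) ** 2 - well
    return 0.0


@njit(cache=True)
def _mc_sweep_kernel(positions, type_indices, order, proposals, uniforms,
                     indptr, indices, pair_mode, pair_sigma, pair_k_rep,
                     pair_k_att, pair_r_cut, wall_lo, wall_hi, wall_k,
                     wall_mask, beta):
    n_accepted = 0
    for m in range(order.shape[0]):
        p = order[m]
        t = type_indices[p]
        ox, oy, oz = positions[p, 0], positions[p, 1], positions[p, 2]
        nx = ox + proposals[m, 0]
        ny = oy + proposals[m, 1]
        nz = oz + proposals[m, 2]
        du = 0.0
        for w in range(wall_k.shape[0]):
            if wall_mask[w, t]:
                for c in range(3):
                    xo = positions[p, c]
                    xn = xo + proposals[m, c]
                    lo = wall_lo[w, c]
                    hi = wall_hi[w, c]
                    eo = 0.0
                    en = 0.0
                    if xo < lo:
                        eo = (lo - xo) ** 2
                    elif xo > hi:
                        eo = (xo - hi) ** 2
                    if xn < lo:
                        en = (lo - xn) ** 2
                    elif xn > hi:
                        en = (xn - hi) ** 2
                    du += 0.5 * wall_k[w] * (en - eo)
        for s in range(indptr[p], indptr[p + 1]):
            q = indices[s]
            tq = type_indices[q]
            mode = pair_mode[t, tq]
            if mode == 0:
                continue
            sig = pair_sigma[t, tq]
            krep = pair_k_rep[t, tq]
            katt = pair_k_att[t, tq]
            rcut = pair_r_cut[t, tq]
            qx, qy, qz = positions[q, 0], positions[q, 1], positions[q, 2]
            du += _pair_energy(nx - qx, ny - qy, nz - qz, mode, sig, krep, katt, rcut)
            du -= _pair_energy(ox - qx, oy - qy, oz - qz, mode, sig, krep, katt, rcut)
        if du <= 0.0 or uniforms[m] < math.exp(-beta * du):
            positions[p, 0] = nx
            positions[p, 1] = ny
            positions[p, 2] = nz
            n_accepted += 1
    return n_accepted


def _wall_arrays(compiled: CompiledPotentials):
    n_walls = len(compiled.walls)
    lo = np.zeros((n_walls, 3))
    hi = np.zeros((n_walls, 3))
    k = np.zeros(n_walls)
    mask = np.zeros((n_walls, compiled.n_types), dtype=np.bool_)
    for w, (term, m) in enumerate(zip(compiled.walls, compiled.wall_masks)):
        lo[w] = term.origin
        hi[w] = term.extent
        k[w] = term.force_constant
        mask[w] = m
    return lo, hi, k, mask


def _proposal_sd_per_type(state: SystemState, proposal_sd) -> np.ndarray:
    if proposal_sd is None:
        d = state.registry.diffusion_constants
        return np.sqrt(2.0 * d * _MC_NOMINAL_DT)
    arr = np.asarray(proposal_sd, dtype=float)
    if arr.ndim == 0:
        arr = np.full(len(state.registry), float(arr))
    if np.any(arr <= 0):
        raise ValueError("proposal_sd must be > 0")
    return arr


def _particle_energy_python(state, compiled, p, pos_p):
    """Energy of particle p at position pos_p against the rest (fallback path)."""
    energy = 0.0
    t = int(state.type_indices[p])
    for term, mask in zip(compiled.walls, compiled.wall_masks):
        if mask[t]:
            u, _ = box_wall_eval(pos_p, term.origin, term.extent, term.force_constant)
            energy += u
    for term, mask in zip(compiled.surfaces, compiled.surface_masks):
        if mask[t]:
            u, _ = surface_eval(pos_p, term)
            energy += u
    if compiled.has_pair_terms and state.n_particles > 1:
        delta = state.positions - pos_p
        delta[p] = np.inf
        d = np.linalg.norm(delta, axis=1)
        tq = state.type_indices
        mode = compiled.pair_mode[t, tq]
        sigma = compiled.pair_sigma[t, tq]
        krep = compiled.pair_k_rep[t, tq]
        katt = compiled.pair_k_att[t, tq]
        rcut = compiled.pair_r_cut[t, tq]
        well = 0.5 * katt * (rcut - sigma) ** 2
        core = (mode != 0) & (d < sigma)
        shell = (mode == 2) & (d >= sigma) & (d < rcut)
        energy += float(np.sum(0.5 * krep[core] * (d[core] - sigma[core]) ** 2))
        energy -= float(np.sum(well[core & (mode == 2)]))
        energy += float(np.sum(0.5 * katt[shell] * (d[shell] - sigma[shell]) ** 2 - well[shell]))
    if compiled.bonds:
        pid = int(state.ids[p])
        id_to_index = {int(i): k for k, i in enumerate(state.ids)}
        for bond in compiled.bonds:
            if pid in (bond.id_i, bond.id_j):
                other = bond.id_j if pid == bond.id_i else bond.id_i
                q = id_to_index[other]
                dvec = pos_p - state.positions[q]
                dd = float(np.linalg.norm(dvec))
                energy += 0.5 * bond.force_constant * (dd - bond.length) ** 2
    return energy


def _mc_sweeps_inplace(state: SystemState, compiled: CompiledPotentials,
                       n_sweeps: int, rng: np.random.Generator,
                       sd_per_type: np.ndarray, beta: float,
                       frame_stride: int | None = None) -> tuple[float, list]:
    """Run Metropolis sweeps mutating ``state.positions``.

    Returns (mean acceptance fraction, recorded frames). A frame (a position
    copy) is recorded every ``frame_stride`` sweeps when requested.
    """
    n = state.n_particles
    frames: list[np.ndarray] = []
    if n == 0 or n_sweeps == 0:
        return 1.0, frames
    sd_particle = sd_per_type[state.type_indices][:, None]
    accepted = 0
    use_kernel = compiled.mc_kernel_supported
    wall_lo, wall_hi, wall_k, wall_mask = _wall_arrays(compiled)
    margin = _MC_MARGIN_SDS * float(sd_per_type.max())
    for sweep in range(n_sweeps):
        order = rng.permutation(n)
        proposals = rng.standard_normal((n, 3)) * sd_particle[order]
        uniforms = rng.random(n)
        if use_kernel:
            if compiled.has_pair_terms and n > 1:
                nlist = build_neighbor_list(state.positions, compiled.cutoff + margin)
                indptr, indices = nlist.adjacency_csr()
            else:
                indptr = np.zeros(n + 1, dtype=np.int64)
                indices = np.empty(0, dtype=np.int64)
            accepted += _mc_sweep_kernel(
                state.positions, state.type_indices, order, proposals, uniforms,
                indptr, indices, compiled.pair_mode, compiled.pair_sigma,
                compiled.pair_k_rep, compiled.pair_k_att, compiled.pair_r_cut,
                wall_lo, wall_hi, wall_k, wall_mask, beta,
            )
        else:
            for m, p in enumerate(order):
                old = state.positions[p].copy()
                new = old + proposals[m]
                du = (_particle_energy_python(state, compiled, p, new)
                      - _particle_energy_python(state, compiled, p, old))
                if du <= 0.0 or uniforms[m] < math.exp(-beta * du):
                    state.positions[p] = new
                    accepted += 1
        if frame_stride is not None and (sweep + 1) % frame_stride == 0:
            frames.append(state.positions.copy())
    return accepted / (n * n_sweeps), frames


def mc_sweep(state: SystemState, potentials: PotentialSet, rng: np.random.Generator,
             *, proposal_sd=None, temperature: float = DEFAULT_TEMPERATURE
             ) -> tuple[SystemState, float]:
    """One Metropolis sweep over a copy of ``state``.

    Returns the updated state and the acceptance fraction. The proposal is
    an isotropic Gaussian displacement with per-type SD sqrt(2 D dt_nominal)
    unless ``proposal_sd`` (scalar or per-type array, nm) is given.
    """
    compiled = potentials.compile(state.registry)
    new = state.copy()
    sd = _proposal_sd_per_type(state, proposal_sd)
    beta = 1.0 / thermal_energy(temperature)
    frac, _ = _mc_sweeps_inplace(new, compiled, 1, make_rng(rng), sd, beta)
    return new, frac


def relax(state: SystemState, potentials: PotentialSet, n_sweeps: int,
          rng: np.random.Generator, *, proposal_sd=None,
          temperature: float = DEFAULT_TEMPERATURE) -> SystemState:
    """Relax an (overlapping) configuration by ``n_sweeps`` Metropolis sweeps.

    Used before Brownian dynamics on dense random starts, where initial
    overlaps would otherwise produce destabilizing forces. The default of
    3000 sweeps (see :mod:`rdx.systems`) brings a dense random start to a
    low-energy state.
    """
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be >= 0")
    new = state.copy()
    if n_sweeps == 0:
        return new
    compiled = potentials.compile(state.registry)
    sd = _proposal_sd_per_type(state, proposal_sd)
    beta = 1.0 / thermal_energy(temperature)
    frac, _ = _mc_sweeps_inplace(new, compiled, n_sweeps, make_rng(rng), sd, beta)
    logger.debug("relax: %d sweeps, acceptance %.3f", n_sweeps, frac)
    return new


def sample_mc(state: SystemState, potentials: PotentialSet, n_sweeps: int,
              rng: np.random.Generator, *, frame_stride: int = 10,
              proposal_sd=None, temperature: float = DEFAULT_TEMPERATURE):
    """Sample stationary configurations with the Metropolis kernel.

    Returns ``(final_state, frames, acceptance)`` where ``frames`` is a list
    of position snapshots taken every ``frame_stride`` sweeps.
    """
    compiled = potentials.compile(state.registry)
    new = state.copy()
    sd = _proposal_sd_per_type(state, proposal_sd)
    beta = 1.0 / thermal_energy(temperature)
    frac, frames = _mc_sweeps_inplace(new, compiled, n_sweeps, make_rng(rng), sd, beta,
                                      frame_stride=frame_stride)
    return new, frames, frac
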