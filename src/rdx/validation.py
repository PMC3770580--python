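"""End-to-end validation studies at desk scale.

Each study builds its system programmatically, runs the method and measures
the observable the validation protocol asks for:

* ``crowding_study`` — triphasic MSD analysis of the dense benchmark:
  microscopic D from the shortest lags, effective D from the intermediate
  linear phase, and their ratio per species;
* ``apparent_radius_study`` — Monte Carlo sampled same-type RDF and the
  50%-area apparent collision radius;
* ``bd_mc_rdf_study`` — Brownian dynamics vs Monte Carlo stationary
  distributions (RDF RMS difference against the MC-vs-MC statistical floor);
* ``kinetics_ode_study`` — slow-rate A + B <-> C kinetics against the
  well-mixed mass-action ODE;
* ``crowding_kinetics_comparison`` — the same reaction with repulsion on
  vs off (crowding slows the approach and lowers the product level).

Problem sizes default to reduced boxes at the published densities so each
study completes in minutes on one core; the box edge, step counts and
replicate numbers are explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (
    ApparentRadius,
    MsdResult,
    OdeSolution,
    RdfResult,
    apparent_radius,
    fit_diffusion,
    mean_square_displacement,
    ode_mass_action,
    radial_distribution,
    rdf_rms_difference,
)
from .dynamics import bd_run, sample_mc
from .engine import ConcentrationRecorder, run_simulation
from .model import SimulationParameters, make_rng
from .reactions import fission, fusion, invert_erban
from .systems import BenchmarkSpec, build_benchmark_state

__all__ = [
    "CrowdingResult",
    "crowding_study",
    "apparent_radius_study",
    "RdfConsistency",
    "bd_mc_rdf_study",
    "KineticsResult",
    "kinetics_ode_study",
    "KineticsComparison",
    "crowding_kinetics_comparison",
]


# ---------------------------------------------------------------------------
# Diffusion and crowding
# ---------------------------------------------------------------------------

@dataclass
class CrowdingResult:
    """Per-species microscopic and effective diffusion constants."""

    msd: dict  # type name -> MsdResult
    d_micro: dict  # nm^2/us
    d_eff: dict
    ratio_percent: dict  # 100 * D_eff / D_micro
    micro_window: tuple
    eff_window: tuple
    phi: float
    box_edge: float
    n_particles: int


def crowding_study(phi: float = 0.5, box_edge: float = 50.0, seed: int = 1, *,
                   dt: float = 1e-4, n_steps: int = 20_000,
                   relax_sweeps: int = 3000, micro_lag_steps: int = 5,
                   caging_window_factors: tuple = (1.0, 4.0),
                   origin_stride: int = 10,
                   include_repulsion: bool = True) -> CrowdingResult:
    """Measure D_micro, D_eff and their ratio for species A and B.

    The benchmark at occupied volume fraction ``phi`` is MC-relaxed and then
    integrated reaction-free; positions are recorded every step. D_micro is
    the MSD slope over the first ``micro_lag_steps`` lags (free-path
    motion). D_eff is fitted over the intermediate phase selected by a
    caging-length rule: the lag range where the species' MSD lies between
    ``caging_window_factors`` times sigma^2, with sigma its same-type
    contact distance — past the micro-to-effective transition (the particle
    has displaced beyond its own contact shell) but before box confinement.
    """
    rng = make_rng(seed)
    spec = BenchmarkSpec(phi=phi, box_edge=box_edge, relax_sweeps=relax_sweeps,
                         include_repulsion=include_repulsion)
    system = build_benchmark_state(spec, rng)
    params = SimulationParameters(dt=dt, n_steps=n_steps, seed=seed)
    _, traj = bd_run(system.state, system.potentials, params, rng, record_stride=1)

    lags = np.unique(np.concatenate([
        np.arange(1, micro_lag_steps + 1),
        np.round(np.geomspace(10, n_steps // 2, 40)).astype(int),
    ]))
    micro_window = (0.5 * dt, (micro_lag_steps + 0.5) * dt)

    msd, d_micro, d_eff, ratio, eff_windows = {}, {}, {}, {}, {}
    for name in ("A", "B"):
        mask = system.state.type_mask(name)
        res = mean_square_displacement(traj, dt, particle_mask=mask, lags=lags,
                                       origin_stride=origin_stride)
        msd[name] = res
        d_micro[name] = fit_diffusion(res, micro_window)
        sigma_sq = (2.0 * system.state.registry[name].collision_radius) ** 2
        lo_m, hi_m = (f * sigma_sq for f in caging_window_factors)
        in_window = (res.msd >= lo_m) & (res.msd <= hi_m) & (res.lag_times > 0)
        if in_window.sum() < 3:
            raise ValueError(
                f"run too short: MSD of {name} never spans "
                f"[{lo_m:g}, {hi_m:g}] nm^2 with >= 3 lags; increase n_steps"
            )
        window = (float(res.lag_times[in_window].min()),
                  float(res.lag_times[in_window].max()))
        eff_windows[name] = window
        d_eff[name] = fit_diffusion(res, window)
        ratio[name] = 100.0 * d_eff[name] / d_micro[name]
    return CrowdingResult(
        msd=msd, d_micro=d_micro, d_eff=d_eff, ratio_percent=ratio,
        micro_window=micro_window, eff_window=eff_windows,
        phi=phi, box_edge=box_edge, n_particles=system.state.n_particles,
    )


# ---------------------------------------------------------------------------
# Apparent collision radius
# ---------------------------------------------------------------------------

def apparent_radius_study(phi: float = 0.5, box_edge: float = 50.0, seed: int = 1, *,
                          force_constant: float = 10.0, relax_sweeps: int = 3000,
                          sample_sweeps: int = 4000, frame_stride: int = 20,
                          dr: float = 0.05, r_max: float = 6.0,
                          type_name: str = "A") -> tuple[ApparentRadius, RdfResult]:
    """MC-sample the dense benchmark and extract r_app from the same-type RDF."""
    rng = make_rng(seed)
    spec = BenchmarkSpec(phi=phi, box_edge=box_edge, force_constant=force_constant,
                         relax_sweeps=relax_sweeps)
    system = build_benchmark_state(spec, rng)
    _, frames, _ = sample_mc(system.state, system.potentials, sample_sweeps, rng,
                             frame_stride=frame_stride)
    rdf = radial_distribution(
        frames, system.state.registry, [type_name], [type_name],
        system.state.box_origin, system.state.box_extent,
        type_indices=system.state.type_indices, dr=dr, r_max=r_max)
    return apparent_radius(rdf), rdf


# ---------------------------------------------------------------------------
# Stationary-distribution consistency (timestep validation protocol)
# ---------------------------------------------------------------------------

@dataclass
class RdfConsistency:
    """BD-vs-MC RDF error and the MC-vs-MC statistical floor."""

    rms_bd_mc: float
    rms_floor: float
    rdf_bd: RdfResult
    rdf_mc_a: RdfResult
    rdf_mc_b: RdfResult


def bd_mc_rdf_study(phi: float = 0.5, box_edge: float = 30.0, seed: int = 1, *,
                    dt: float = 1e-4, n_bd_steps: int = 20_000,
                    bd_record_stride: int = 50, mc_sweeps: int = 6000,
                    mc_frame_stride: int = 20, relax_sweeps: int = 3000,
                    dr: float = 0.05, r_max: float = 6.0,
                    type_name: str = "A") -> RdfConsistency:
    """Compare the BD-sampled RDF at timestep ``dt`` against the MC reference.

    Two independent MC chains quantify the statistical floor; the BD error
    should sit at that floor when ``dt`` is on the discretization plateau.
    """
    rng = make_rng(seed)
    spec = BenchmarkSpec(phi=phi, box_edge=box_edge, relax_sweeps=relax_sweeps)
    system = build_benchmark_state(spec, rng)
    state = system.state

    def rdf_of(frames):
        return radial_distribution(
            frames, state.registry, [type_name], [type_name],
            state.box_origin, state.box_extent,
            type_indices=state.type_indices, dr=dr, r_max=r_max)

    _, frames_a, _ = sample_mc(state, system.potentials, mc_sweeps,
                               make_rng(seed + 1), frame_stride=mc_frame_stride)
    _, frames_b, _ = sample_mc(state, system.potentials, mc_sweeps,
                               make_rng(seed + 2), frame_stride=mc_frame_stride)
    params = SimulationParameters(dt=dt, n_steps=n_bd_steps, seed=seed + 3)
    _, traj = bd_run(state, system.potentials, params, make_rng(seed + 3),
                     record_stride=bd_record_stride)
    rdf_bd = rdf_of(np.asarray(traj[1:], dtype=float))
    rdf_a, rdf_b = rdf_of(frames_a), rdf_of(frames_b)
    return RdfConsistency(
        rms_bd_mc=rdf_rms_difference(rdf_bd, rdf_a),
        rms_floor=rdf_rms_difference(rdf_a, rdf_b),
        rdf_bd=rdf_bd, rdf_mc_a=rdf_a, rdf_mc_b=rdf_b,
    )


# ---------------------------------------------------------------------------
# Reaction kinetics vs the mass-action ODE
# ---------------------------------------------------------------------------

@dataclass
class KineticsResult:
    """Replicate-averaged stochastic kinetics with its ODE reference."""

    times: np.ndarray
    mean_counts: dict  # type -> mean particle count over replicates
    se_counts: dict  # standard error of the mean
    ode: OdeSolution
    volume: float
    n_initial: int
    microscopic_rate: float
    kf_effective: float  # geometry-corrected forward rate used by the ODE


def _kinetics_rates(kf_macro, kb, n_pairs, volume, registry):
    spec_a, spec_b = registry["A"], registry["B"]
    d_sum = spec_a.diffusion_constant + spec_b.diffusion_constant
    radius = spec_a.reaction_radius + spec_b.reaction_radius
    lam = invert_erban(kf_macro, d_sum, radius)
    if kb is None:
        # place the equilibrium near 50% conversion: kb = kf * c0 / 2
        kb = 0.5 * kf_macro * (n_pairs / volume)
    return lam, kb


def soft_wall_encounter_probability(box_edge: float, radius: float, *,
                                    force_constant: float = 10.0,
                                    temperature: float = 293.15,
                                    n_samples: int = 3_000_000,
                                    seed: int = 20_2020) -> float:
    """P(|x1 - x2| < R) for two independent particles in the soft-wall box.

    Sampled from the exact Boltzmann single-particle density of the
    harmonic wall (uniform inside, Gaussian tails outside). In a bounded
    box this probability is smaller than (4/3) pi R^3 / V: part of every
    near-wall particle's reaction sphere lies outside the accessible
    volume, and the soft wall slightly enlarges that volume. The bulk
    bimolecular flux law n_A n_B kf / V therefore acquires a finite-size
    geometry factor that this probability captures exactly.
    """
    from .model import thermal_energy

    kbt = thermal_energy(temperature)
    rng = np.random.default_rng(seed)
    pad = 6.0 * np.sqrt(kbt / force_constant)
    grid = np.linspace(-pad, box_edge + pad, 6001)
    cell = grid[1] - grid[0]
    outside = np.maximum(-grid, 0.0) + np.maximum(grid - box_edge, 0.0)
    weights = np.exp(-0.5 * force_constant * outside**2 / kbt)
    weights /= weights.sum()

    def draw(n):
        idx = rng.choice(len(grid), size=(n, 3), p=weights)
        return grid[idx] + rng.uniform(-cell / 2, cell / 2, (n, 3))

    hits = 0
    remaining = n_samples
    while remaining > 0:
        m = min(500_000, remaining)
        d = np.linalg.norm(draw(m) - draw(m), axis=1)
        hits += int(np.sum(d < radius))
        remaining -= m
    return hits / n_samples


def kinetics_ode_study(phi: float = 0.3, box_edge: float = 25.0, *,
                       kf_macro: float = 60.0, kb: float | None = None,
                       t_total: float = 20.0, dt: float = 1e-3,
                       n_replicates: int = 10, seed: int = 1,
                       n_output_points: int = 200,
                       include_repulsion: bool = False) -> KineticsResult:
    """Simulate slow A + B <-> C kinetics and average over replicates.

    Rates default to the slow (reaction-limited) regime where the reaction
    waiting times far exceed the mixing time, so the well-mixed ODE is the
    valid reference. The microscopic association rate is derived from
    ``kf_macro`` with the Erban-Chapman inversion; the dissociation rate is
    used as-is (unimolecular rates are already microscopic). The ODE's
    forward rate carries the exact finite-size geometry factor of the
    bounded soft-wall box (see ``soft_wall_encounter_probability``), which
    tends to 1 in the bulk limit.
    """
    spec = BenchmarkSpec(phi=phi, box_edge=box_edge,
                         include_repulsion=include_repulsion)
    n_steps = int(round(t_total / dt))
    stride = max(1, n_steps // n_output_points)
    all_counts: dict[str, list] = {"A": [], "B": [], "C": []}
    times = None
    volume = box_edge**3
    lam = kb_eff = None
    rules = None
    for rep in range(n_replicates):
        system = build_benchmark_state(spec, seed + 1000 * rep)
        state = system.state
        if rules is None:
            n_pairs = state.type_counts()["A"]
            lam, kb_eff = _kinetics_rates(kf_macro, kb, n_pairs, volume, state.registry)
            rules = [fusion("A", "B", "C", lam), fission("C", "A", "B", kb_eff)]
            reg = state.registry
            radius = reg["A"].reaction_radius + reg["B"].reaction_radius
            p_enc = soft_wall_encounter_probability(
                box_edge, radius, force_constant=spec.force_constant,
                temperature=spec.temperature)
            v_react = 4.0 / 3.0 * np.pi * radius**3
            kf_eff = kf_macro * (p_enc * volume / v_react)  # geometry factor -> 1 in bulk
        params = SimulationParameters(dt=dt, n_steps=n_steps, seed=seed + 1000 * rep)
        recorder = ConcentrationRecorder(stride=stride)
        run_simulation(state, system.potentials, params, rules=rules,
                       analyzers=[recorder])
        series = recorder.series(volume=volume)
        if times is None:
            times = series.times
        for name in all_counts:
            all_counts[name].append(series.counts[name])
    mean_counts = {k: np.mean(v, axis=0) for k, v in all_counts.items()}
    se_counts = {
        k: np.std(v, axis=0, ddof=1) / np.sqrt(n_replicates) if n_replicates > 1
        else np.full_like(mean_counts[k], np.inf)
        for k, v in all_counts.items()
    }
    c0 = (n_pairs / volume, n_pairs / volume, 0.0)
    ode = ode_mass_action(kf_eff, kb_eff, c0, times)
    return KineticsResult(times=times, mean_counts=mean_counts, se_counts=se_counts,
                          ode=ode, volume=volume, n_initial=n_pairs,
                          microscopic_rate=lam, kf_effective=kf_eff)


@dataclass
class KineticsComparison:
    """Identical rates with repulsion on vs off."""

    times: np.ndarray
    mean_c_repulsion: np.ndarray  # mean C count over replicates
    mean_c_free: np.ndarray
    tail_c_repulsion: float  # time-averaged C count over the last quarter
    tail_c_free: float
    half_time_repulsion: float  # first time C reaches half the free tail level
    half_time_free: float


def crowding_kinetics_comparison(phi: float = 0.3, box_edge: float = 20.0, *,
                                 kf_macro: float = 300.0, kb: float | None = None,
                                 t_total: float = 6.0, dt: float = 1e-4,
                                 n_replicates: int = 3, seed: int = 1,
                                 n_output_points: int = 150) -> KineticsComparison:
    """Run A + B <-> C at identical rates with and without pair repulsion.

    Repulsion shrinks the overlap volume in which encounters can react,
    which slows the approach to equilibrium and lowers the product level.
    """
    n_steps = int(round(t_total / dt))
    stride = max(1, n_steps // n_output_points)
    volume = box_edge**3
    results = {}
    rules_cache = {}
    times = None
    for label, repulsive in (("free", False), ("repulsion", True)):
        spec = BenchmarkSpec(phi=phi, box_edge=box_edge, include_repulsion=repulsive)
        traces = []
        for rep in range(n_replicates):
            system = build_benchmark_state(spec, seed + 1000 * rep)
            state = system.state
            if label not in rules_cache:
                n_pairs = state.type_counts()["A"]
                lam, kb_eff = _kinetics_rates(kf_macro, kb, n_pairs, volume,
                                              state.registry)
                rules_cache["free"] = rules_cache["repulsion"] = [
                    fusion("A", "B", "C", lam), fission("C", "A", "B", kb_eff)]
            params = SimulationParameters(dt=dt, n_steps=n_steps, seed=seed + 1000 * rep)
            recorder = ConcentrationRecorder(stride=stride)
            run_simulation(state, system.potentials, params,
                           rules=rules_cache[label], analyzers=[recorder])
            series = recorder.series(volume=volume)
            if times is None:
                times = series.times
            traces.append(series.counts["C"])
        results[label] = np.mean(traces, axis=0)

    tail = slice(3 * len(times) // 4, None)
    tail_free = float(np.mean(results["free"][tail]))
    tail_rep = float(np.mean(results["repulsion"][tail]))

    def half_time(trace):
        target = tail_free / 2.0
        above = np.nonzero(trace >= target)[0]
        return float(times[above[0]]) if len(above) else float("inf")

    return KineticsComparison(
        times=times,
        mean_c_repulsion=results["repulsion"],
        mean_c_free=results["free"],
        tail_c_repulsion=tail_rep,
        tail_c_free=tail_free,
        half_time_repulsion=half_time(results["repulsion"]),
        half_time_free=half_time(results["free"]),
    )
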