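"""Observables and validation analytics.

* radial distribution function g(r) with a numerical boundary correction
  for wall-bounded (non-periodic) boxes;
* apparent collision radius from the 50%-area rule on g(r);
* mean square displacement with microscopic / effective diffusion-constant
  fits (crowded systems show a triphasic MSD: free diffusion at short
  times, a slower effective linear phase at intermediate times, and a
  finite-size plateau);
* the well-mixed mass-action ODE for A + B <-> C, the validation oracle
  for slow reaction kinetics;
* a timestep-selection scan comparing Brownian-dynamics RDFs against the
  discretization-free Monte Carlo reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import SystemState, TypeRegistry

__all__ = [
    "RdfResult",
    "radial_distribution",
    "ApparentRadius",
    "apparent_radius",
    "MsdResult",
    "mean_square_displacement",
    "fit_diffusion",
    "effective_window",
    "ConcentrationSeries",
    "OdeSolution",
    "ode_mass_action",
    "PlateauScanResult",
    "timestep_plateau_scan",
    "rdf_rms_difference",
]

#: Default RDF bin width, nm.
DEFAULT_DR = 0.05
#: Fixed seed for the ideal-gas reference sampler (an estimator constant,
#: not part of the simulation's random stream).
_REFERENCE_SEED = 1234567


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RdfResult:
    """Histogram estimate of g(r) between two particle selections."""

    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    reference_probability: np.ndarray
    n_frames: int
    n_pairs_per_frame: float
    set_a: tuple
    set_b: tuple

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def dr(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def standard_error(self) -> np.ndarray:
        """Poisson standard error on g per bin (frames treated as independent)."""
        total_pairs = self.n_frames * self.n_pairs_per_frame
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(self.counts, 1.0)) / (
                total_pairs * self.reference_probability
            )
        return np.where(self.reference_probability > 0, se, np.inf)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.bin_centers, "g": self.g})


def _frames_to_arrays(frames, type_indices):
    """Coerce frames to a list of (N, 3) arrays plus one type-index array."""
    if isinstance(frames, np.ndarray) and frames.ndim == 3:
        return [frames[k] for k in range(len(frames))], type_indices
    out = []
    tidx = type_indices
    for f in frames:
        if isinstance(f, SystemState):
            if tidx is None:
                tidx = f.type_indices
            elif len(tidx) != f.n_particles or np.any(tidx != f.type_indices):
                raise ValueError("RDF frames must share one particle composition")
            out.append(f.positions)
        else:
            out.append(np.asarray(f, dtype=float))
    return out, tidx


def radial_distribution(frames, registry: TypeRegistry, set_a, set_b,
                        box_origin, box_extent, *, type_indices=None,
                        dr: float = DEFAULT_DR, r_max: float | None = None,
                        n_reference_pairs: int = 2_000_000,
                        reference_seed: int = _REFERENCE_SEED) -> RdfResult:
    """Estimate g(r) between type sets A and B from configuration frames.

    The ideal-gas normalization per bin is computed numerically: uniform
    random point pairs are sampled in the actual box and histogrammed with
    the same bins, which corrects for wall/boundary effects in any box
    shape. Self-pairs are excluded when the two sets coincide.

    Parameters
    ----------
    frames
        Sequence of SystemState, sequence of (N, 3) position arrays, or an
        (F, N, 3) array. All frames must share one particle composition.
    set_a, set_b
        Type-name sequences (e.g. ``["A"]``). Must be equal or disjoint.
    dr
        Bin width in nm.
    r_max
        Histogram range; defaults to half the smallest box edge.
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    box_origin = np.asarray(box_origin, dtype=float)
    box_extent = np.asarray(box_extent, dtype=float)
    lengths = box_extent - box_origin
    if r_max is None:
        r_max = float(lengths.min()) / 2.0
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    if len(edges) < 2:
        raise ValueError("r_max must cover at least one bin")

    frame_list, tidx = _frames_to_arrays(frames, type_indices)
    if not frame_list:
        raise ValueError("no frames supplied")
    if tidx is None:
        raise ValueError("type_indices required when frames are raw position arrays")
    set_a = tuple(set_a)
    set_b = tuple(set_b)
    mask_a = registry.mask(set_a)[tidx]
    mask_b = registry.mask(set_b)[tidx]
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"empty selection: |A|={n_a}, |B|={n_b}")
    same = set(set_a) == set(set_b)
    if not same and np.any(mask_a & mask_b):
        raise ValueError("selections must be identical or disjoint")
    if same and n_a < 2:
        raise ValueError("same-set RDF needs at least two particles")

    counts = np.zeros(len(edges) - 1)
    if same:
        n_pairs_per_frame = n_a * (n_a - 1) / 2.0
    else:
        n_pairs_per_frame = float(n_a * n_b)
    idx_a = np.nonzero(mask_a)[0]
    idx_b = np.nonzero(mask_b)[0]
    for pos in frame_list:
        a = pos[idx_a].astype(float)
        if same:
            from scipy.spatial.distance import pdist
            d = pdist(a)
        else:
            from scipy.spatial.distance import cdist
            d = cdist(a, pos[idx_b].astype(float)).ravel()
        counts += np.histogram(d, bins=edges)[0]

    ref_rng = np.random.default_rng(reference_seed)
    chunk = 500_000
    ref_counts = np.zeros(len(edges) - 1)
    remaining = n_reference_pairs
    while remaining > 0:
        m = min(chunk, remaining)
        p1 = ref_rng.uniform(box_origin, box_extent, size=(m, 3))
        p2 = ref_rng.uniform(box_origin, box_extent, size=(m, 3))
        ref_counts += np.histogram(np.linalg.norm(p1 - p2, axis=1), bins=edges)[0]
        remaining -= m
    p_ref = ref_counts / n_reference_pairs

    total_pairs = len(frame_list) * n_pairs_per_frame
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (total_pairs * p_ref)
    g = np.where(p_ref > 0, g, 0.0)
    return RdfResult(
        bin_edges=edges, g=g, counts=counts, reference_probability=p_ref,
        n_frames=len(frame_list), n_pairs_per_frame=n_pairs_per_frame,
        set_a=set_a, set_b=set_b,
    )


def rdf_rms_difference(rdf_a: RdfResult, rdf_b: RdfResult,
                       r_range: tuple[float, float] | None = None) -> float:
    """Root-mean-square difference between two g(r) curves on shared bins."""
    if len(rdf_a.bin_edges) != len(rdf_b.bin_edges) or not np.allclose(
        rdf_a.bin_edges, rdf_b.bin_edges
    ):
        raise ValueError("RDFs must share identical bins")
    sel = np.ones(len(rdf_a.g), dtype=bool)
    if r_range is not None:
        centers = rdf_a.bin_centers
        sel = (centers >= r_range[0]) & (centers <= r_range[1])
    return float(np.sqrt(np.mean((rdf_a.g[sel] - rdf_b.g[sel]) ** 2)))


# ---------------------------------------------------------------------------
# Apparent collision radius
# ---------------------------------------------------------------------------

@dataclass
class ApparentRadius:
    """50%-area apparent radius extracted from a same-type RDF.

    ``r_app`` is half the pair distance at which the area under g(r) from 0
    to its first maximum is split in half; ``interval`` brackets the overlap
    region between the two configured area quantiles (pair distances, nm).
    """

    r_app: float
    r_half: float
    interval: tuple
    first_max_r: float
    quantiles: tuple


def _area_quantile(centers, g, dr, i_max, fraction):
    masses = g[: i_max + 1] * dr
    total = masses.sum()
    target = fraction * total
    cum = np.cumsum(masses)
    j = int(np.searchsorted(cum, target))
    before = cum[j - 1] if j > 0 else 0.0
    left_edge = centers[j] - dr / 2.0
    frac_in_bin = (target - before) / masses[j] if masses[j] > 0 else 0.0
    return float(left_edge + frac_in_bin * dr)


def apparent_radius(rdf: RdfResult, quantiles: tuple = (0.005, 0.975),
                    smoothing_bins: int = 5) -> ApparentRadius:
    """Apparent collision radius from the 50%-area rule.

    The first local maximum of g(r) is located after moving-average
    smoothing; the cumulative area of the raw g on [0, r_firstmax] is then
    split at 50% (and at the configured outer quantiles, default 0.5% and
    97.5%, bracketing the overlap region). The apparent radius is half the
    50% pair distance. Soft repulsion admits some particle overlap, so
    r_app lies below the collision radius; stiffer potentials close the gap.
    """
    g = rdf.g
    centers = rdf.bin_centers
    dr = rdf.dr
    kernel = np.ones(smoothing_bins) / smoothing_bins
    g_s = np.convolve(g, kernel, mode="same")
    candidates = np.nonzero(
        (g_s[1:-1] >= g_s[:-2]) & (g_s[1:-1] >= g_s[2:])
        & (g_s[1:-1] >= 0.5 * g_s.max()) & (g_s[1:-1] > 0)
    )[0]
    if len(candidates) == 0:
        raise ValueError(
            "no local maximum found in g(r); extend r_max or collect more frames"
        )
    i_max = int(candidates[0]) + 1
    if np.sum(g[: i_max + 1]) <= 0:
        raise ValueError("g(r) has no mass below its first maximum")
    r_half = _area_quantile(centers, g, dr, i_max, 0.5)
    q_lo = _area_quantile(centers, g, dr, i_max, quantiles[0])
    q_hi = _area_quantile(centers, g, dr, i_max, quantiles[1])
    return ApparentRadius(
        r_app=r_half / 2.0,
        r_half=r_half,
        interval=(q_lo, q_hi),
        first_max_r=float(centers[i_max]),
        quantiles=tuple(quantiles),
    )


# ---------------------------------------------------------------------------
# Mean square displacement
# ---------------------------------------------------------------------------

@dataclass
class MsdResult:
    """MSD(tau) averaged over particles and sliding time origins."""

    lag_times: np.ndarray  # us, starts at 0
    msd: np.ndarray  # nm^2
    n_samples: np.ndarray  # displacement samples per lag
    frame_dt: float
    n_particles: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.lag_times, "msd": self.msd,
                             "n": self.n_samples})


def mean_square_displacement(trajectory: np.ndarray, frame_dt: float,
                             *, particle_mask: np.ndarray | None = None,
                             lags: Sequence[int] | None = None,
                             origin_stride: int = 1) -> MsdResult:
    """MSD over lag times from an (F, N, 3) trajectory.

    Positions must be raw (the box is wall-bounded, not periodic, so no
    unwrapping is needed). ``lags`` are frame counts; by default every lag
    up to F // 4 is used. Averaging runs over all particles in
    ``particle_mask`` and over time origins spaced ``origin_stride`` frames.
    """
    traj = np.asarray(trajectory)
    if traj.ndim != 3 or traj.shape[2] != 3:
        raise ValueError("trajectory must have shape (frames, particles, 3)")
    n_frames = traj.shape[0]
    if n_frames < 2:
        raise ValueError("need at least two frames for an MSD")
    if frame_dt <= 0:
        raise ValueError("frame_dt must be > 0")
    if particle_mask is not None:
        traj = traj[:, np.asarray(particle_mask, dtype=bool), :]
    if traj.shape[1] == 0:
        raise ValueError("empty particle selection")
    if lags is None:
        lags = np.arange(1, max(2, n_frames // 4))
    lags = np.unique(np.asarray(lags, dtype=int))
    if np.any(lags < 1) or np.any(lags >= n_frames):
        raise ValueError("lags must lie in [1, n_frames - 1]")

    msd = np.zeros(len(lags) + 1)
    n_samples = np.zeros(len(lags) + 1, dtype=np.int64)
    n_samples[0] = traj.shape[1]
    for k, lag in enumerate(lags, start=1):
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = traj[origins + lag].astype(np.float64) - traj[origins].astype(np.float64)
        sq = np.sum(disp * disp, axis=-1)
        msd[k] = float(sq.mean())
        n_samples[k] = sq.size
    lag_times = np.concatenate([[0.0], lags * frame_dt])
    return MsdResult(lag_times=lag_times, msd=msd, n_samples=n_samples,
                     frame_dt=frame_dt, n_particles=traj.shape[1])


def fit_diffusion(msd: MsdResult, window: tuple[float, float], ndim: int = 3) -> float:
    """Least-squares MSD slope over a lag-time window, divided by 2*ndim.

    ``window`` is (tau_lo, tau_hi) in us, inclusive; at least three lag
    points must fall inside. ``ndim=3`` for bulk systems, 2 for planar
    (membrane) systems.
    """
    sel = (msd.lag_times >= window[0]) & (msd.lag_times <= window[1]) & (msd.lag_times > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"window {window} contains only {int(sel.sum())} lag points; need >= 3"
        )
    slope = np.polyfit(msd.lag_times[sel], msd.msd[sel], 1)[0]
    return float(slope) / (2.0 * ndim)


def effective_window(msd: MsdResult, *, min_lag: float,
                     plateau_msd: float | None = None,
                     plateau_fraction: float = 0.3,
                     slope_band: tuple = (0.9, 1.1)) -> tuple[float, float]:
    """Select the intermediate linear MSD phase for the effective-D fit.

    Candidate lags start at ``min_lag`` (past the microscopic phase) and
    stop where the MSD reaches ``plateau_fraction`` of the finite-size
    plateau (if ``plateau_msd`` is given). Within the candidates the longest
    contiguous run whose local log-log slope stays in ``slope_band`` is
    returned; if the slope filter leaves nothing, the full candidate range
    is returned.
    """
    tau = msd.lag_times
    m = msd.msd
    sel = tau >= min_lag
    if plateau_msd is not None:
        sel &= m <= plateau_fraction * plateau_msd
    sel &= m > 0
    idx = np.nonzero(sel)[0]
    if len(idx) < 3:
        raise ValueError("too few lags beyond min_lag for a window")
    log_tau = np.log(tau[idx])
    log_m = np.log(m[idx])
    slope = np.gradient(log_m, log_tau)
    ok = (slope >= slope_band[0]) & (slope <= slope_band[1])
    best_lo, best_hi, run_lo = None, None, None
    for k, flag in enumerate(ok):
        if flag and run_lo is None:
            run_lo = k
        if (not flag or k == len(ok) - 1) and run_lo is not None:
            run_hi = k if flag else k - 1
            if best_lo is None or run_hi - run_lo > best_hi - best_lo:
                best_lo, best_hi = run_lo, run_hi
            run_lo = None
    if best_lo is None or best_hi - best_lo < 2:
        return float(tau[idx[0]]), float(tau[idx[-1]])
    return float(tau[idx[best_lo]]), float(tau[idx[best_hi]])


# ---------------------------------------------------------------------------
# Concentration series and the mass-action ODE oracle
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSeries:
    """Per-type particle counts over time in a box of known volume."""

    times: np.ndarray  # us
    counts: dict  # type name -> integer array
    volume: float  # nm^3

    def concentrations(self) -> dict:
        """Number concentrations in particles/nm^3."""
        return {k: np.asarray(v, dtype=float) / self.volume for k, v in self.counts.items()}

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t": self.times}
        data.update({f"n_{k}": v for k, v in self.counts.items()})
        return pd.DataFrame(data)


@dataclass
class OdeSolution:
    """Deterministic well-mixed kinetics of A + B <-> C."""

    t: np.ndarray
    c_a: np.ndarray
    c_b: np.ndarray
    c_c: np.ndarray
    kf: float  # nm^3/us
    kb: float  # 1/us


def ode_mass_action(kf: float, kb: float, c0: Sequence[float], t_grid,
                    rtol: float = 1e-10) -> OdeSolution:
    """Integrate dc_A/dt = -kf c_A c_B + kb c_C (and counterparts).

    Concentrations are in particles/nm^3, kf in nm^3/us, kb in 1/us. The
    integration tolerance (1e-10 relative) keeps the oracle at least two
    orders tighter than simulation noise.
    """
    if kf < 0 or kb < 0 or any(c < 0 for c in c0):
        raise ValueError("rates and initial concentrations must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_t, y):
        a, b, c = y
        flux = kf * a * b - kb * c
        return [-flux, -flux, flux]

    scale = max(max(c0), 1e-30)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), list(c0), t_eval=t_grid,
                    method="RK45", rtol=rtol, atol=rtol * scale * 1e-2)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return OdeSolution(t=sol.t, c_a=sol.y[0], c_b=sol.y[1], c_c=sol.y[2], kf=kf, kb=kb)


# ---------------------------------------------------------------------------
# Timestep selection
# ---------------------------------------------------------------------------

@dataclass
class PlateauScanResult:
    """Per-timestep RDF error against the Monte Carlo reference."""

    dts: np.ndarray
    rms_error: np.ndarray
    plateau_dt: float
    statistical_floor: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"dt": self.dts, "rms_error": self.rms_error})


def timestep_plateau_scan(run_bd_rdf: Callable[[float], RdfResult],
                          dt_candidates: Sequence[float],
                          reference_rdf: RdfResult, *,
                          statistical_floor: float | None = None,
                          plateau_factor: float = 2.0) -> PlateauScanResult:
    """Scan timesteps and locate the error plateau against an MC reference.

    ``run_bd_rdf(dt)`` must run a Brownian-dynamics simulation at the given
    timestep and return its RDF on the reference's bins. Candidates are
    sorted descending; the plateau timestep is the largest dt whose RMS
    error is within ``plateau_factor`` of the smallest-dt error (or of the
    supplied ``statistical_floor``).
    """
    dts = np.sort(np.asarray(dt_candidates, dtype=float))[::-1]
    errors = np.array([
        rdf_rms_difference(run_bd_rdf(float(dt)), reference_rdf) for dt in dts
    ])
    floor = statistical_floor if statistical_floor is not None else float(errors[-1])
    within = errors <= plateau_factor * floor
    plateau_dt = float(dts[np.argmax(within)]) if np.any(within) else float(dts[-1])
    return PlateauScanResult(dts=dts, rms_error=errors, plateau_dt=plateau_dt,
                             statistical_floor=float(floor))
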