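"""Stochastic reactions and the microscopic/macroscopic rate bridge.

Reaction kinds
--------------
* ``conversion``  A -> B          (type change)
* ``fusion``      A + B -> C     (bimolecular association)
* ``fission``     C -> A + B     (dissociation with product separation)
* ``birth``       S -> S + A     (a source particle emits a new particle)
* ``decay``       A -> 0         (removal)

Every rule carries a *microscopic* rate constant lambda (1/us): the
first-order rate at which an eligible particle (or an encounter pair within
the summed reaction radii) converts to products. Within one step of length
dt the reaction fires with the Poisson probability p = 1 - exp(-lambda dt).

For bimolecular reactions the measurable *macroscopic* rate constant
k_macro (nm^3/us) is related to lambda, the mutual diffusion constant
D = D_A + D_B and the reaction distance R = r_react(A) + r_react(B) by the
interpolation between the diffusion-limited (Smoluchowski) encounter rate
k_enc = 4 pi D R and the reaction-limited rate lambda * (4/3) pi R^3:

    k_macro = 4 pi D R * [1 - sqrt(D/lambda)/R * tanh(R sqrt(lambda/D))]

(valid in 3D only). ``invert_erban`` solves this relation for lambda given
an experimental k_macro.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .model import AVOGADRO, SystemState, TypeRegistry

__all__ = [
    "ReactionRule",
    "conversion",
    "fusion",
    "fission",
    "birth",
    "decay",
    "ReactionEvent",
    "reaction_probability",
    "smoluchowski_encounter_rate",
    "erban_macroscopic_rate",
    "invert_erban",
    "molar_rate_conversion",
    "molar_rate_conversion_inverse",
    "fusion_position",
    "fission_positions",
    "detect_and_draw_events",
    "execute_events",
]

_KINDS = ("conversion", "fusion", "fission", "birth", "decay")


@dataclass(frozen=True)
class ReactionRule:
    """One reaction rule with a microscopic rate constant.

    ``separation`` (fission only) is the distance at which the two products
    are placed; it defaults to the sum of their reaction radii at execution
    time.
    """

    kind: str
    educts: tuple
    products: tuple
    rate: float  # microscopic lambda, 1/us
    separation: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}; expected one of {_KINDS}")
        if self.rate < 0:
            raise ValueError(f"reaction rate must be >= 0, got {self.rate}")
        n_educt = {"conversion": 1, "fusion": 2, "fission": 1, "birth": 1, "decay": 1}
        n_product = {"conversion": 1, "fusion": 1, "fission": 2, "birth": 1, "decay": 0}
        if len(self.educts) != n_educt[self.kind]:
            raise ValueError(f"{self.kind} takes {n_educt[self.kind]} educt(s), got {self.educts}")
        if len(self.products) != n_product[self.kind]:
            raise ValueError(
                f"{self.kind} takes {n_product[self.kind]} product(s), got {self.products}"
            )
        if self.separation is not None and self.separation <= 0:
            raise ValueError("fission separation must be > 0")

    def resolve(self, registry: TypeRegistry) -> None:
        """Raise KeyError naming the first educt/product type not in the registry."""
        for t in (*self.educts, *self.products):
            registry.index(t)

    def label(self) -> str:
        if self.name:
            return self.name
        lhs = " + ".join(self.educts) if self.educts else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        return f"{lhs} -> {rhs}"


def conversion(educt: str, product: str, rate: float, **kw) -> ReactionRule:
    return ReactionRule("conversion", (educt,), (product,), rate, **kw)


def fusion(educt_a: str, educt_b: str, product: str, rate: float, **kw) -> ReactionRule:
    return ReactionRule("fusion", (educt_a, educt_b), (product,), rate, **kw)


def fission(educt: str, product_a: str, product_b: str, rate: float,
            separation: float | None = None, **kw) -> ReactionRule:
    return ReactionRule("fission", (educt,), (product_a, product_b), rate,
                        separation=separation, **kw)


def birth(source: str, product: str, rate: float, **kw) -> ReactionRule:
    return ReactionRule("birth", (source,), (product,), rate, **kw)


def decay(educt: str, rate: float, **kw) -> ReactionRule:
    return ReactionRule("decay", (educt,), (), rate, **kw)


@dataclass(frozen=True)
class ReactionEvent:
    """A drawn reaction candidate for one step."""

    rule_index: int
    educt_ids: tuple
    draw: float
    accepted: bool
    step_index: int


# ---------------------------------------------------------------------------
# Rate bridge
# ---------------------------------------------------------------------------

def reaction_probability(rate: float, dt: float) -> float:
    """Poisson probability of at least one event with rate ``rate`` within ``dt``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return -math.expm1(-rate * dt)


def smoluchowski_encounter_rate(d_a: float, d_b: float, radius: float) -> float:
    """Diffusion-limited encounter rate 4 pi (D_A + D_B) R, in nm^3/us."""
    if d_a < 0 or d_b < 0:
        raise ValueError("diffusion constants must be >= 0")
    if radius <= 0:
        raise ValueError(f"reaction distance must be > 0, got {radius}")
    return 4.0 * math.pi * (d_a + d_b) * radius


def erban_macroscopic_rate(rate: float, d_sum: float, radius: float) -> float:
    """Macroscopic rate constant (nm^3/us) for a microscopic rate ``rate`` (1/us).

    Interpolates between the reaction-limited limit rate * (4/3) pi R^3
    (rate -> 0) and the Smoluchowski limit 4 pi D R (rate -> inf); numerically
    stable in both regimes.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if radius <= 0:
        raise ValueError("reaction distance must be > 0")
    if d_sum < 0:
        raise ValueError("d_sum must be >= 0")
    if rate == 0.0:
        return 0.0
    if d_sum == 0.0:
        return 0.0
    a = radius * math.sqrt(rate / d_sum)
    if a < 1e-4:
        # 1 - tanh(a)/a = a^2/3 - 2 a^4/15 + O(a^6)
        bracket = a * a / 3.0 - 2.0 * a**4 / 15.0
    else:
        bracket = 1.0 - math.tanh(a) / a
    return 4.0 * math.pi * d_sum * radius * bracket


def invert_erban(k_macro: float, d_sum: float, radius: float,
                 rtol: float = 1e-12) -> float:
    """Microscopic rate lambda (1/us) reproducing a macroscopic ``k_macro`` (nm^3/us).

    Raises ValueError when ``k_macro`` reaches or exceeds the diffusion limit
    4 pi D R, which no finite microscopic rate can reproduce.
    """
    if k_macro < 0:
        raise ValueError("k_macro must be >= 0")
    if k_macro == 0.0:
        return 0.0
    k_enc = smoluchowski_encounter_rate(d_sum, 0.0, radius)
    if k_macro >= k_enc:
        raise ValueError(
            f"k_macro = {k_macro:g} nm^3/us reaches the diffusion limit "
            f"4*pi*D*R = {k_enc:g} nm^3/us; no finite microscopic rate exists"
        )
    # reaction-limited bound: k_macro <= lambda * (4/3) pi R^3, so the root
    # lies above k_macro / V_react
    v_react = 4.0 / 3.0 * math.pi * radius**3
    lam_lo = k_macro / v_react
    lam_hi = lam_lo
    while erban_macroscopic_rate(lam_hi, d_sum, radius) < k_macro:
        lam_hi *= 4.0
        if lam_hi > 1e30:  # pragma: no cover - cannot happen below the limit
            raise RuntimeError("failed to bracket the microscopic rate")
    if lam_hi == lam_lo:
        return lam_lo

    def f(log_lam: float) -> float:
        return erban_macroscopic_rate(math.exp(log_lam), d_sum, radius) - k_macro

    log_root = brentq(f, math.log(lam_lo) - 1e-12, math.log(lam_hi), rtol=1e-15, xtol=rtol)
    return math.exp(log_root)


#: 1 nm^3/us in 1/(M s): 1e-24 L * 6.022e23 /mol * 1e6 (/us -> /s).
_NM3_US_TO_PER_MOLAR_S = AVOGADRO * 1e-18


def molar_rate_conversion(k_nm3_us: float) -> float:
    """Convert a bimolecular rate constant from nm^3/us to 1/(M s)."""
    if k_nm3_us < 0:
        raise ValueError("rate constant must be >= 0")
    return k_nm3_us * _NM3_US_TO_PER_MOLAR_S


def molar_rate_conversion_inverse(k_per_molar_s: float) -> float:
    """Convert a bimolecular rate constant from 1/(M s) to nm^3/us."""
    if k_per_molar_s < 0:
        raise ValueError("rate constant must be >= 0")
    return k_per_molar_s / _NM3_US_TO_PER_MOLAR_S


# ---------------------------------------------------------------------------
# Product placement
# ---------------------------------------------------------------------------

def fusion_position(x_a, x_b, r_a: float, r_b: float) -> np.ndarray:
    """Volume-weighted product position: the larger educt moves less."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    wa, wb = r_a**3, r_b**3
    total = wa + wb
    if total == 0.0:
        return 0.5 * (x_a + x_b)
    return (wa * x_a + wb * x_b) / total


def fission_positions(x_c, separation: float, r_a: float, r_b: float,
                      rng: np.random.Generator):
    """Place two products on a uniformly random axis through ``x_c``.

    Offsets are volume-weighted so that ``fusion_position`` of the products
    recovers ``x_c`` exactly; the products end up ``separation`` apart.
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    x_c = np.asarray(x_c, dtype=float)
    axis = rng.standard_normal(3)
    norm = np.linalg.norm(axis)
    while norm < 1e-12:  # pragma: no cover - probability-zero redraw
        axis = rng.standard_normal(3)
        norm = np.linalg.norm(axis)
    axis /= norm
    wa, wb = r_a**3, r_b**3
    total = wa + wb
    frac_a = wb / total if total > 0 else 0.5
    x_a = x_c + axis * separation * frac_a
    x_b = x_c - axis * separation * (1.0 - frac_a)
    return x_a, x_b


# ---------------------------------------------------------------------------
# Per-step scheduler
# ---------------------------------------------------------------------------

def max_fusion_distance(rules: Sequence[ReactionRule], registry: TypeRegistry) -> float:
    """Largest summed reaction radius over all fusion rules (neighbor cutoff floor)."""
    r_react = registry.reaction_radii
    best = 0.0
    for rule in rules:
        if rule.kind == "fusion":
            ra = r_react[registry.index(rule.educts[0])]
            rb = r_react[registry.index(rule.educts[1])]
            best = max(best, float(ra + rb))
    return best


def detect_and_draw_events(state: SystemState, rules: Sequence[ReactionRule],
                           pairs: np.ndarray, dt: float,
                           rng: np.random.Generator) -> list[ReactionEvent]:
    """Enumerate reaction candidates for one step and draw their uniforms.

    Unimolecular rules yield one candidate per educt particle; fusion rules
    one candidate per unordered educt pair within the summed reaction radii
    (the supplied pair list must cover that distance). A candidate is marked
    accepted when its draw falls below 1 - exp(-lambda dt). Candidate
    enumeration order is deterministic, so a fixed seed reproduces the draws.
    """
    events: list[ReactionEvent] = []
    registry = state.registry
    r_react = registry.reaction_radii
    if len(pairs):
        pair_dist = np.linalg.norm(
            state.positions[pairs[:, 0]] - state.positions[pairs[:, 1]], axis=1
        )
    for rule_index, rule in enumerate(rules):
        if rule.rate == 0.0:
            continue
        p_react = reaction_probability(rule.rate, dt)
        if rule.kind == "fusion":
            if len(pairs) == 0:
                continue
            ta = registry.index(rule.educts[0])
            tb = registry.index(rule.educts[1])
            radius = float(r_react[ta] + r_react[tb])
            ti = state.type_indices[pairs[:, 0]]
            tj = state.type_indices[pairs[:, 1]]
            match = ((ti == ta) & (tj == tb)) | ((ti == tb) & (tj == ta))
            match &= pair_dist < radius
            idx = np.nonzero(match)[0]
            draws = rng.random(len(idx))
            for k, pair_row in enumerate(idx):
                i, j = pairs[pair_row]
                events.append(ReactionEvent(
                    rule_index=rule_index,
                    educt_ids=(int(state.ids[i]), int(state.ids[j])),
                    draw=float(draws[k]),
                    accepted=bool(draws[k] < p_react),
                    step_index=state.step_index,
                ))
        else:
            t_educt = registry.index(rule.educts[0])
            members = np.nonzero(state.type_indices == t_educt)[0]
            draws = rng.random(len(members))
            for k, i in enumerate(members):
                events.append(ReactionEvent(
                    rule_index=rule_index,
                    educt_ids=(int(state.ids[i]),),
                    draw=float(draws[k]),
                    accepted=bool(draws[k] < p_react),
                    step_index=state.step_index,
                ))
    return events


def execute_events(state: SystemState, rules: Sequence[ReactionRule],
                   events: Sequence[ReactionEvent], rng: np.random.Generator
                   ) -> tuple[SystemState, list[ReactionEvent]]:
    """Execute accepted events in a seeded random order; returns (state', executed).

    Conflict rule: a particle participates in at most one executed reaction
    per step; later events referencing an already-consumed particle are
    skipped. New particles receive fresh ids (ids are never reused).
    """
    accepted = [e for e in events if e.accepted]
    new = state.copy()
    if not accepted:
        return new, []
    order = rng.permutation(len(accepted))
    registry = state.registry
    r_coll = registry.collision_radii
    r_react = registry.reaction_radii
    id_to_index = {int(pid): k for k, pid in enumerate(new.ids)}
    consumed: set[int] = set()
    removals: list[int] = []
    additions: list[tuple[int, np.ndarray]] = []  # (type index, position)
    executed: list[ReactionEvent] = []

    for e_idx in order:
        event = accepted[e_idx]
        rule = rules[event.rule_index]
        if any(pid in consumed for pid in event.educt_ids):
            continue
        if rule.kind == "conversion":
            (pid,) = event.educt_ids
            i = id_to_index[pid]
            new.type_indices[i] = registry.index(rule.products[0])
            consumed.add(pid)
        elif rule.kind == "decay":
            (pid,) = event.educt_ids
            removals.append(id_to_index[pid])
            consumed.add(pid)
        elif rule.kind == "fusion":
            pid_a, pid_b = event.educt_ids
            ia, ib = id_to_index[pid_a], id_to_index[pid_b]
            ta, tb = new.type_indices[ia], new.type_indices[ib]
            pos = fusion_position(new.positions[ia], new.positions[ib],
                                  r_coll[ta], r_coll[tb])
            additions.append((registry.index(rule.products[0]), pos))
            removals.extend([ia, ib])
            consumed.update((pid_a, pid_b))
        elif rule.kind == "fission":
            (pid,) = event.educt_ids
            i = id_to_index[pid]
            t_a = registry.index(rule.products[0])
            t_b = registry.index(rule.products[1])
            separation = rule.separation
            if separation is None:
                separation = float(r_react[t_a] + r_react[t_b])
            x_a, x_b = fission_positions(new.positions[i], separation,
                                         r_coll[t_a], r_coll[t_b], rng)
            additions.append((t_a, x_a))
            additions.append((t_b, x_b))
            removals.append(i)
            consumed.add(pid)
        elif rule.kind == "birth":
            (pid,) = event.educt_ids
            i = id_to_index[pid]
            t_src = new.type_indices[i]
            t_new = registry.index(rule.products[0])
            direction = rng.standard_normal(3)
            norm = np.linalg.norm(direction)
            while norm < 1e-12:  # pragma: no cover
                direction = rng.standard_normal(3)
                norm = np.linalg.norm(direction)
            offset = float(r_react[t_src] + r_react[t_new])
            additions.append((t_new, new.positions[i] + direction / norm * offset))
            consumed.add(pid)  # a source emits at most once per step
        executed.append(event)

    if removals:
        keep = np.ones(new.n_particles, dtype=bool)
        keep[removals] = False
        new.ids = new.ids[keep]
        new.type_indices = new.type_indices[keep]
        new.positions = new.positions[keep]
    for t_new, pos in additions:
        new.add_particles(registry.names[t_new], pos)
    return new, executed
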