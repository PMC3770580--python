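import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from rdx.model import ParticleTypeSpec, SimulationParameters, SystemState, TypeRegistry, make_rng
from rdx.neighbors import build_neighbor_list
from rdx.reactions import (
    ReactionRule,
    conversion,
    decay,
    detect_and_draw_events,
    erban_macroscopic_rate,
    execute_events,
    fission,
    fission_positions,
    fusion,
    fusion_position,
    invert_erban,
    molar_rate_conversion,
    molar_rate_conversion_inverse,
    reaction_probability,
    smoluchowski_encounter_rate,
)


class TestReactionProbability:
    def test_zero_rate(self):
        assert reaction_probability(0.0, 1e-4) == 0.0

    def test_half_life_closed_form(self):
        assert reaction_probability(math.log(2), 1.0) == pytest.approx(0.5)

    def test_small_rate_first_order(self):
        p = reaction_probability(1e-6, 1.0)
        assert p == pytest.approx(1e-6, rel=1e-6)

    @given(st.floats(0, 1e3), st.floats(1e-9, 1e3))
    def test_bounded_and_monotone(self, lam, dt):
        p = reaction_probability(lam, dt)
        assert 0.0 <= p <= 1.0
        if lam * dt < 30:  # below float saturation the bound is strict
            assert p < 1.0
        assert reaction_probability(lam + 1.0, dt) >= p

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reaction_probability(-1.0, 1.0)
        with pytest.raises(ValueError):
            reaction_probability(1.0, 0.0)


class TestRateBridge:
    def test_smoluchowski_values(self):
        assert smoluchowski_encounter_rate(0.0, 0.0, 4.5) == 0.0
        assert smoluchowski_encounter_rate(143.1, 71.6, 4.5) == pytest.approx(
            4 * math.pi * 214.7 * 4.5)
        # linear homogeneity in R and D
        assert smoluchowski_encounter_rate(10, 10, 9.0) == pytest.approx(
            2 * smoluchowski_encounter_rate(10, 10, 4.5))

    def test_diffusion_limited_regime(self):
        d, r = 214.7, 4.5
        lam = 1e8 * d / r**2
        assert erban_macroscopic_rate(lam, d, r) == pytest.approx(
            4 * math.pi * d * r, rel=1e-3)

    def test_reaction_limited_regime(self):
        d, r = 214.7, 4.5
        lam = 1e-6 * d / r**2
        assert erban_macroscopic_rate(lam, d, r) / lam == pytest.approx(
            4.0 / 3.0 * math.pi * r**3, rel=1e-3)

    def test_monotone_in_rate(self):
        d, r = 100.0, 3.0
        ks = [erban_macroscopic_rate(l, d, r) for l in np.geomspace(1e-6, 1e8, 60)]
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_inversion_round_trip(self):
        d, r = 214.7, 4.5
        for lam in np.geomspace(1e-4, 1e6, 40):
            k = erban_macroscopic_rate(lam, d, r)
            assert invert_erban(k, d, r) == pytest.approx(lam, rel=1e-8)

    def test_inversion_edge_cases(self):
        d, r = 214.7, 4.5
        k_enc = smoluchowski_encounter_rate(d, 0.0, r)
        assert invert_erban(0.0, d, r) == 0.0
        lam = invert_erban(0.999 * k_enc, d, r)
        assert np.isfinite(lam) and lam > 0
        with pytest.raises(ValueError, match="diffusion limit"):
            invert_erban(k_enc, d, r)

    def test_molar_conversion(self):
        assert molar_rate_conversion(0.0) == 0.0
        assert molar_rate_conversion(1.0) == pytest.approx(6.022e5, rel=1e-3)
        for k in (0.5, 60.0, 1e4):
            assert molar_rate_conversion_inverse(molar_rate_conversion(k)) == pytest.approx(k)


class TestProductPlacement:
    def test_fusion_midpoint_for_equal_radii(self):
        pos = fusion_position([0, 0, 0], [2, 0, 0], 1.5, 1.5)
        np.testing.assert_allclose(pos, [1, 0, 0])

    def test_fusion_degenerate_partner(self):
        np.testing.assert_allclose(fusion_position([1, 2, 3], [9, 9, 9], 2.0, 0.0),
                                   [1, 2, 3])

    @given(st.tuples(*[st.floats(-5, 5)] * 3), st.tuples(*[st.floats(-5, 5)] * 3),
           st.floats(0.1, 5), st.floats(0.1, 5))
    def test_fusion_point_on_segment(self, xa, xb, ra, rb):
        xa, xb = np.array(xa), np.array(xb)
        pos = fusion_position(xa, xb, ra, rb)
        t = rb**3 / (ra**3 + rb**3)
        np.testing.assert_allclose(pos, xa + t * (xb - xa), atol=1e-9)

    def test_fission_geometry_inverts_fusion(self, rng):
        xc = np.array([1.0, -2.0, 3.0])
        for _ in range(50):
            xa, xb = fission_positions(xc, 4.5, 1.5, 3.0, rng)
            assert np.linalg.norm(xa - xb) == pytest.approx(4.5)
            np.testing.assert_allclose(fusion_position(xa, xb, 1.5, 3.0), xc,
                                       atol=1e-12)

    def test_fission_axis_directions_uniform(self, rng):
        """Mean resultant of 1e4 fission axes vanishes (isotropy)."""
        axes = np.array([
            fission_positions(np.zeros(3), 1.0, 1.0, 1.0, rng)[0]
            for _ in range(10_000)])
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        assert np.linalg.norm(axes.mean(axis=0)) < 0.03


def _reactive_state(positions_by_type, box=50.0):
    reg = TypeRegistry([
        ParticleTypeSpec("A", 1.5, 1.5, 143.1),
        ParticleTypeSpec("B", 3.0, 3.0, 71.6),
        ParticleTypeSpec("C", 3.12, 3.12, 68.82),
    ])
    state = SystemState.empty(reg, (0, 0, 0), (box, box, box))
    for name, positions in positions_by_type.items():
        state.add_particles(name, np.asarray(positions, dtype=float))
    return state


class TestScheduler:
    def test_no_rules_yields_no_events(self, rng):
        state = _reactive_state({"A": [[1, 1, 1]], "B": [[2, 1, 1]]})
        pairs = build_neighbor_list(state.positions, 10.0).pairs
        assert detect_and_draw_events(state, [], pairs, 1e-4, rng) == []

    def test_close_pair_with_certain_rate_fuses(self, rng):
        state = _reactive_state({"A": [[10, 10, 10]], "B": [[14.4, 10, 10]]})
        rule = fusion("A", "B", "C", rate=1e9)  # lambda*dt >> 1
        pairs = build_neighbor_list(state.positions, 10.0).pairs
        events = detect_and_draw_events(state, [rule], pairs, 1e-4, rng)
        assert len(events) == 1 and events[0].accepted
        new, executed = execute_events(state, [rule], events, rng)
        assert len(executed) == 1
        assert new.type_counts() == {"A": 0, "B": 0, "C": 1}

    def test_pair_beyond_reaction_distance_ignored(self, rng):
        state = _reactive_state({"A": [[10, 10, 10]], "B": [[14.6, 10, 10]]})
        rule = fusion("A", "B", "C", rate=1e9)  # R = 4.5 < distance
        pairs = build_neighbor_list(state.positions, 10.0).pairs
        assert detect_and_draw_events(state, [rule], pairs, 1e-4, rng) == []

    def test_conflicting_fusions_execute_once(self, rng):
        state = _reactive_state({"A": [[10, 10, 10], [12, 10, 10]],
                                 "B": [[11, 10, 10]]})
        rule = fusion("A", "B", "C", rate=1e9)
        pairs = build_neighbor_list(state.positions, 10.0).pairs
        events = detect_and_draw_events(state, [rule], pairs, 1e-4, rng)
        assert sum(e.accepted for e in events) == 2  # both pairs share the B
        new, executed = execute_events(state, [rule], events, rng)
        assert len(executed) == 1
        assert new.type_counts() == {"A": 1, "B": 0, "C": 1}

    def test_all_rates_zero_is_identity(self, rng):
        state = _reactive_state({"A": [[1, 1, 1]], "C": [[3, 3, 3]]})
        rules = [fusion("A", "B", "C", 0.0), decay("A", 0.0), fission("C", "A", "B", 0.0)]
        pairs = build_neighbor_list(state.positions, 10.0).pairs
        events = detect_and_draw_events(state, rules, pairs, 1e-4, rng)
        new, executed = execute_events(state, rules, events, rng)
        assert executed == []
        np.testing.assert_array_equal(new.ids, state.ids)

    def test_conversion_and_birth_stoichiometry(self, rng):
        state = _reactive_state({"A": [[10, 10, 10]], "C": [[30, 30, 30]]})
        rules = [conversion("A", "B", 1e9),
                 ReactionRule("birth", ("C",), ("A",), 1e9)]
        pairs = np.empty((0, 2), dtype=np.int64)
        events = detect_and_draw_events(state, rules, pairs, 1e-4, rng)
        new, executed = execute_events(state, rules, events, rng)
        assert len(executed) == 2
        assert new.type_counts() == {"A": 1, "B": 1, "C": 1}
        # the birthed particle sits one summed reaction radius from the source
        born = new.positions[-1]
        assert np.linalg.norm(born - [30, 30, 30]) == pytest.approx(3.12 + 1.5)

    def test_fresh_ids_for_products(self, rng):
        state = _reactive_state({"A": [[10, 10, 10]], "B": [[12, 10, 10]]})
        rule = fusion("A", "B", "C", 1e9)
        pairs = build_neighbor_list(state.positions, 10.0).pairs
        events = detect_and_draw_events(state, [rule], pairs, 1e-4, rng)
        new, _ = execute_events(state, [rule], events, rng)
        assert new.ids.tolist() == [2]  # 0 and 1 consumed, never reused

    def test_decay_lifetimes_exponential(self):
        """Mean lifetime 1/lambda within 3 SE and KS-consistent with Exp."""
        from rdx.engine import ReactionEventLog, run_simulation
        from rdx.potentials import PotentialSet
        lam, dt, n = 1.0, 0.01, 10_000
        reg = TypeRegistry([ParticleTypeSpec("A", 1.0, 1.0, 1.0)])
        state = SystemState.empty(reg, (0, 0, 0), (1000, 1000, 1000))
        gen = np.random.default_rng(0)
        state.add_particles("A", gen.uniform(0, 1000, (n, 3)))
        params = SimulationParameters(dt=dt, n_steps=1200, seed=0)
        log = ReactionEventLog()
        result = run_simulation(state, PotentialSet(), params,
                                rules=[decay("A", lam)], analyzers=[log])
        assert result.state.n_particles < 20  # essentially all decayed
        lifetimes = np.array([ (s + 0.5) * dt for s, _, _ in log.events])
        se = lifetimes.std(ddof=1) / np.sqrt(len(lifetimes))
        assert lifetimes.mean() == pytest.approx(1 / lam, abs=3 * se)
        ks = stats.kstest(lifetimes, "expon", args=(0, 1 / lam))
        assert ks.pvalue > 0.01

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ReactionRule("fusion", ("A",), ("C",), 1.0)  # fusion needs 2 educts
        with pytest.raises(ValueError):
            ReactionRule("decay", ("A",), (), -1.0)
        with pytest.raises(ValueError):
            ReactionRule("unknown", ("A",), (), 1.0)
        reg = TypeRegistry([ParticleTypeSpec("A", 1, 1, 1)])
        with pytest.raises(KeyError, match="X"):
            fusion("A", "X", "A", 1.0).resolve(reg)
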