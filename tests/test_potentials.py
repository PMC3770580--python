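import numpy as np
import pytest
from hypothesis import given, strategies as st

from rdx.model import SystemState
from rdx.neighbors import brute_force_pairs
from rdx.potentials import (
    BoxWall,
    CylinderWall,
    DiskMembrane,
    HarmonicBond,
    PairAttraction,
    PairRepulsion,
    PotentialSet,
    SphereSurface,
    box_wall_eval,
    pair_attraction_eval,
    pair_repulsion_eval,
    surface_eval,
    total_energy_and_gradient,
)

positions3 = st.tuples(*[st.floats(-8.0, 8.0)] * 3).map(np.array)


class TestBoxWall:
    def test_flat_interior(self):
        u, g = box_wall_eval([5, 5, 5], [0, 0, 0], [10, 10, 10], 10.0)
        assert u == 0.0 and np.all(g == 0.0)

    def test_one_nm_beyond_face(self):
        u, g = box_wall_eval([11.0, 5, 5], [0, 0, 0], [10, 10, 10], 10.0)
        assert u == pytest.approx(5.0)
        assert np.linalg.norm(g) == pytest.approx(10.0)
        assert g[0] > 0  # pushes back inside

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            box_wall_eval([0, 0, 0], [0, 0, 0], [1, 0, 1], 10.0)
        with pytest.raises(ValueError):
            BoxWall(origin=(0, 0, 0), extent=(0, 1, 1))


class TestPairRepulsion:
    def test_contact_and_beyond_are_zero(self):
        for d in (3.0, 3.5, 10.0):
            u, gi, gj = pair_repulsion_eval([0, 0, 0], [d, 0, 0], 3.0, 10.0)
            assert u == 0.0 and np.all(gi == 0.0) and np.all(gj == 0.0)

    def test_overlap_hand_value(self):
        u, gi, gj = pair_repulsion_eval([0, 0, 0], [2.0, 0, 0], 3.0, 10.0)
        assert u == pytest.approx(5.0)
        assert np.linalg.norm(gi) == pytest.approx(10.0)
        np.testing.assert_allclose(gi, -gj)
        assert gi[0] > 0  # force -grad pushes i toward -x, away from j

    def test_coincident_fallback_is_deterministic(self):
        u, gi, gj = pair_repulsion_eval([1, 1, 1], [1, 1, 1], 3.0, 10.0)
        assert u == pytest.approx(0.5 * 10 * 9)
        np.testing.assert_allclose(gi, [-30.0, 0.0, 0.0])
        np.testing.assert_allclose(gj, [30.0, 0.0, 0.0])


class TestPairAttraction:
    def test_zero_at_cutoff_and_beyond(self):
        for d in (5.0, 6.0):
            u, gi, _ = pair_attraction_eval([0, 0, 0], [d, 0, 0], 3.0, 5.0, 10.0, 2.0)
            assert u == 0.0 and np.all(gi == 0.0)

    def test_well_minimum_at_contact(self):
        u, _, _ = pair_attraction_eval([0, 0, 0], [3.0, 0, 0], 3.0, 5.0, 10.0, 2.0)
        assert u == pytest.approx(-0.5 * 2.0 * 4.0)

    def test_energy_continuity_across_knots(self):
        for d0 in (3.0, 5.0):
            u_lo = pair_attraction_eval([0, 0, 0], [d0 - 1e-9, 0, 0], 3.0, 5.0, 10.0, 2.0)[0]
            u_hi = pair_attraction_eval([0, 0, 0], [d0 + 1e-9, 0, 0], 3.0, 5.0, 10.0, 2.0)[0]
            assert u_lo == pytest.approx(u_hi, abs=1e-6)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            pair_attraction_eval([0, 0, 0], [1, 0, 0], 3.0, 3.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            PairAttraction(width=0.0)


class TestSurfaces:
    def test_disk_in_plane_inside_radius(self):
        term = DiskMembrane(center=(0, 0, 0), radius=5.0, force_constant=10.0)
        u, g = surface_eval([1.0, 2.0, 0.0], term)
        assert u == 0.0 and np.all(g == 0.0)

    def test_disk_off_plane_hand_value(self):
        term = DiskMembrane(center=(0, 0, 0), radius=5.0, force_constant=10.0)
        u, g = surface_eval([0.0, 0.0, 1.0], term)
        assert u == pytest.approx(5.0)
        np.testing.assert_allclose(g, [0.0, 0.0, 10.0])

    def test_sphere_on_surface(self):
        term = SphereSurface(center=(1, 1, 1), radius=4.0, force_constant=10.0)
        u, g = surface_eval([5.0, 1.0, 1.0], term)
        assert u == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(g, 0.0, atol=1e-9)

    def test_cylinder_inside_is_flat(self):
        term = CylinderWall(center=(0, 0, 0), radius=5.0, force_constant=10.0)
        u, g = surface_eval([3.0, 0.0, 40.0], term)  # z is unconstrained
        assert u == 0.0 and np.all(g == 0.0)


def _numeric_gradient(f, x, h=1e-6):
    g = np.zeros(3)
    for c in range(3):
        e = np.zeros(3)
        e[c] = h
        g[c] = (f(x + e) - f(x - e)) / (2 * h)
    return g


@pytest.mark.parametrize("name", ["box_wall", "repulsion", "attraction",
                                  "sphere", "disk", "cylinder"])
def test_analytic_gradient_matches_finite_differences(name, rng):
    """Every analytic gradient agrees with central differences away from knots."""
    sphere = SphereSurface(center=(0.5, -0.3, 0.2), radius=2.0, force_constant=7.0)
    disk = DiskMembrane(center=(0.1, 0.2, -0.3), radius=2.5, force_constant=6.0)
    cyl = CylinderWall(center=(-0.2, 0.4, 0.0), radius=1.5, force_constant=8.0)
    x_j = np.array([0.3, -0.4, 0.1])
    cases = {
        "box_wall": lambda x: box_wall_eval(x, [-1, -1, -1], [1, 1, 1], 10.0),
        "repulsion": lambda x: pair_repulsion_eval(x, x_j, 4.0, 10.0)[:2],
        "attraction": lambda x: pair_attraction_eval(x, x_j, 2.0, 4.0, 10.0, 3.0)[:2],
        "sphere": lambda x: surface_eval(x, sphere),
        "disk": lambda x: surface_eval(x, disk),
        "cylinder": lambda x: surface_eval(x, cyl),
    }
    knot_distances = {"repulsion": [4.0], "attraction": [2.0, 4.0],
                      "sphere": [], "disk": [], "cylinder": []}
    evaluate = cases[name]
    checked = 0
    for _ in range(100):
        x = rng.uniform(-5, 5, 3)
        if name in knot_distances:
            d = np.linalg.norm(x - x_j) if name in ("repulsion", "attraction") else None
            if d is not None and any(abs(d - kd) < 0.05 for kd in knot_distances[name]):
                continue
        if name == "box_wall" and np.any(np.abs(np.abs(x) - 1.0) < 0.05):
            continue
        if name == "sphere" and abs(np.linalg.norm(x - sphere.center) - 2.0) < 0.05:
            continue
        if name == "disk" and abs(np.linalg.norm(x[:2] - np.array(disk.center[:2])) - 2.5) < 0.05:
            continue
        if name == "cylinder" and abs(np.linalg.norm(x[:2] - np.array(cyl.center[:2])) - 1.5) < 0.05:
            continue
        u, g = evaluate(x)
        g_num = _numeric_gradient(lambda y: evaluate(y)[0], x)
        np.testing.assert_allclose(g, g_num, rtol=1e-5, atol=1e-6)
        checked += 1
    assert checked > 50


@given(positions3, positions3, positions3)
def test_newtons_third_law_and_translation_invariance(xi, xj, shift):
    u1, gi, gj = pair_repulsion_eval(xi, xj, 5.0, 10.0)
    np.testing.assert_allclose(gi + gj, 0.0, atol=1e-12)
    u2, _, _ = pair_repulsion_eval(xi + shift, xj + shift, 5.0, 10.0)
    assert u2 == pytest.approx(u1, rel=1e-9, abs=1e-9)
    ua1, ai, aj = pair_attraction_eval(xi, xj, 3.0, 6.0, 10.0, 2.0)
    np.testing.assert_allclose(ai + aj, 0.0, atol=1e-12)


class TestTotalEnergy:
    def test_no_potentials_is_zero(self, random_state):
        u, grad = total_energy_and_gradient(random_state, PotentialSet())
        assert u == 0.0
        np.testing.assert_allclose(grad, 0.0)

    def test_single_pair_composition(self, empty_state):
        empty_state.add_particles("A", np.array([[5.0, 5.0, 5.0], [7.0, 5.0, 5.0]]))
        pots = PotentialSet([PairRepulsion(force_constant=10.0)])
        u, grad = total_energy_and_gradient(empty_state, pots)
        u_ref, gi, gj = pair_repulsion_eval([5, 5, 5], [7, 5, 5], 3.0, 10.0)
        assert u == pytest.approx(u_ref)
        np.testing.assert_allclose(grad[0], gi)
        np.testing.assert_allclose(grad[1], gj)

    def test_matches_brute_force_all_pairs(self, simple_registry, rng):
        from tests.conftest import make_random_state
        state = make_random_state(simple_registry, {"A": 30, "B": 20}, 15.0, 3)
        pots = PotentialSet([
            BoxWall(origin=(0, 0, 0), extent=(15, 15, 15), force_constant=10.0),
            PairRepulsion(force_constant=10.0),
        ])
        compiled = pots.compile(simple_registry)
        all_pairs = brute_force_pairs(state.positions, compiled.cutoff)
        u_ref, g_ref = total_energy_and_gradient(state, pots, pairs=all_pairs)
        u, g = total_energy_and_gradient(state, pots)  # internal neighbor list
        assert u == pytest.approx(u_ref, rel=1e-12)
        np.testing.assert_allclose(g, g_ref, rtol=1e-12, atol=1e-12)
        assert u >= 0.0  # walls + repulsion only

    def test_stale_pair_list_rejected(self, random_state):
        pots = PotentialSet([PairRepulsion()])
        bad = np.array([[0, random_state.n_particles + 3]])
        with pytest.raises(ValueError, match="stale"):
            total_energy_and_gradient(random_state, pots, pairs=bad)

    def test_harmonic_bond_contributes(self, empty_state):
        ids = empty_state.add_particles("A", np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        pots = PotentialSet([HarmonicBond(int(ids[0]), int(ids[1]),
                                          force_constant=10.0, length=2.0)])
        u, grad = total_energy_and_gradient(empty_state, pots)
        assert u == pytest.approx(0.5 * 10 * 4.0)
        np.testing.assert_allclose(grad[0], [-20.0, 0, 0])
        np.testing.assert_allclose(grad[0], -grad[1])

    def test_missing_bond_particle_reported(self, empty_state):
        empty_state.add_particles("A", np.zeros((1, 3)))
        pots = PotentialSet([HarmonicBond(0, 99, force_constant=1.0)])
        with pytest.raises(KeyError, match="99"):
            total_energy_and_gradient(empty_state, pots)
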