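import numpy as np
import pytest

from rdx.analysis import (
    MsdResult,
    RdfResult,
    apparent_radius,
    effective_window,
    fit_diffusion,
    mean_square_displacement,
    ode_mass_action,
    radial_distribution,
    rdf_rms_difference,
    timestep_plateau_scan,
)
from rdx.model import ParticleTypeSpec, TypeRegistry


@pytest.fixture
def xy_registry():
    return TypeRegistry([ParticleTypeSpec("X", 1.0, 1.0, 1.0),
                         ParticleTypeSpec("Y", 1.0, 1.0, 1.0)])


class TestRdf:
    def test_ideal_gas_is_flat(self, xy_registry):
        """Uniform points: g = 1 on interior bins within pooled 3 SE."""
        gen = np.random.default_rng(5)
        box = 10.0
        frames = [gen.uniform(0, box, (150, 3)) for _ in range(40)]
        tidx = np.zeros(150, dtype=np.int32)
        rdf = radial_distribution(frames, xy_registry, ["X"], ["X"],
                                  (0, 0, 0), (box,) * 3, type_indices=tidx,
                                  dr=0.2, r_max=4.0)
        interior = rdf.bin_centers > 0.6  # skip low-count small-r bins
        resid = rdf.g[interior] - 1.0
        pooled_se = np.sqrt(np.mean(rdf.standard_error()[interior] ** 2)
                            / interior.sum())
        assert abs(resid.mean()) < 3 * pooled_se
        assert np.all(np.abs(resid) < 5 * rdf.standard_error()[interior])

    def test_frozen_pair_lands_in_its_bin(self, xy_registry):
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 3.3]])
        tidx = np.zeros(2, dtype=np.int32)
        rdf = radial_distribution([pos], xy_registry, ["X"], ["X"],
                                  (0, 0, 0), (10,) * 3, type_indices=tidx,
                                  dr=0.1, r_max=5.0)
        assert rdf.counts.sum() == 1
        hot = rdf.bin_centers[rdf.counts > 0]
        assert hot[0] == pytest.approx(2.25, abs=0.05)

    def test_cross_rdf_is_symmetric(self, xy_registry):
        gen = np.random.default_rng(6)
        pos = gen.uniform(0, 8, (60, 3))
        tidx = np.array([0] * 30 + [1] * 30, dtype=np.int32)
        common = dict(box_origin=(0, 0, 0), box_extent=(8,) * 3,
                      type_indices=tidx, dr=0.2, r_max=3.0)
        g_xy = radial_distribution([pos], xy_registry, ["X"], ["Y"], (0, 0, 0),
                                   (8,) * 3, type_indices=tidx, dr=0.2, r_max=3.0)
        g_yx = radial_distribution([pos], xy_registry, ["Y"], ["X"], (0, 0, 0),
                                   (8,) * 3, type_indices=tidx, dr=0.2, r_max=3.0)
        np.testing.assert_allclose(g_xy.g, g_yx.g)

    def test_empty_selection_rejected(self, xy_registry):
        with pytest.raises(ValueError, match="selection"):
            radial_distribution([np.zeros((3, 3))], xy_registry, ["Y"], ["Y"],
                                (0, 0, 0), (5,) * 3,
                                type_indices=np.zeros(3, dtype=np.int32))

    def test_rms_difference_requires_shared_bins(self, xy_registry):
        gen = np.random.default_rng(7)
        frames = [gen.uniform(0, 5, (20, 3))]
        tidx = np.zeros(20, dtype=np.int32)
        a = radial_distribution(frames, xy_registry, ["X"], ["X"], (0, 0, 0),
                                (5,) * 3, type_indices=tidx, dr=0.1, r_max=2.0)
        b = radial_distribution(frames, xy_registry, ["X"], ["X"], (0, 0, 0),
                                (5,) * 3, type_indices=tidx, dr=0.2, r_max=2.0)
        assert rdf_rms_difference(a, a) == 0.0
        with pytest.raises(ValueError):
            rdf_rms_difference(a, b)


def _toy_rdf(dr=0.002):
    """g(r) = r - 2 on [2, 3], zero elsewhere (closed-form area midpoint)."""
    edges = np.arange(0.0, 3.5 + dr, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    g = np.where((centers >= 2.0) & (centers <= 3.0), centers - 2.0, 0.0)
    return RdfResult(bin_edges=edges, g=g, counts=g.copy(),
                     reference_probability=np.ones_like(g), n_frames=1,
                     n_pairs_per_frame=1.0, set_a=("X",), set_b=("X",))


class TestApparentRadius:
    def test_closed_form_triangle_profile(self):
        res = apparent_radius(_toy_rdf())
        assert res.r_half == pytest.approx(2.0 + np.sqrt(0.5), abs=0.01)
        assert res.r_app == pytest.approx((2.0 + np.sqrt(0.5)) / 2, abs=0.005)

    def test_single_bin_mass(self):
        edges = np.arange(0.0, 5.0, 0.1)
        g = np.zeros(len(edges) - 1)
        g[30] = 5.0  # all mass at r ~ 3.05
        rdf = RdfResult(bin_edges=edges, g=g, counts=g.copy(),
                        reference_probability=np.ones_like(g), n_frames=1,
                        n_pairs_per_frame=1.0, set_a=("X",), set_b=("X",))
        res = apparent_radius(rdf, smoothing_bins=1)
        assert res.r_app == pytest.approx(3.05 / 2, abs=0.05)

    def test_monotone_profile_rejected(self):
        edges = np.arange(0.0, 2.0, 0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rdf = RdfResult(bin_edges=edges, g=centers.copy(), counts=centers.copy(),
                        reference_probability=np.ones_like(centers), n_frames=1,
                        n_pairs_per_frame=1.0, set_a=("X",), set_b=("X",))
        with pytest.raises(ValueError, match="maximum"):
            apparent_radius(rdf, smoothing_bins=1)

    def test_quantile_interval_brackets_median(self):
        res = apparent_radius(_toy_rdf())
        lo, hi = res.interval
        assert lo < res.r_half < hi
        assert res.quantiles == (0.005, 0.975)


class TestMsd:
    def test_static_particles_have_zero_msd(self):
        traj = np.ones((10, 4, 3))
        res = mean_square_displacement(traj, 0.1)
        np.testing.assert_allclose(res.msd, 0.0)

    def test_exact_linear_input_recovers_D(self):
        # fabricate MSD = 6 D tau via a deterministic sqrt-scaled walk
        res = MsdResult(lag_times=np.arange(6) * 0.1,
                        msd=6 * 2.5 * np.arange(6) * 0.1,
                        n_samples=np.ones(6, dtype=int), frame_dt=0.1,
                        n_particles=1)
        assert fit_diffusion(res, (0.05, 0.55)) == pytest.approx(2.5)
        assert fit_diffusion(res, (0.05, 0.55), ndim=2) == pytest.approx(3.75)

    def test_random_walk_recovers_D(self):
        gen = np.random.default_rng(8)
        d, dt, n = 50.0, 0.01, 800
        steps = gen.standard_normal((120, n, 3)) * np.sqrt(2 * d * dt)
        traj = np.cumsum(steps, axis=0)
        res = mean_square_displacement(traj, dt, origin_stride=4)
        fitted = fit_diffusion(res, (0.5 * dt, 10.5 * dt))
        assert fitted == pytest.approx(d, rel=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mean_square_displacement(np.zeros((1, 3, 3)), 0.1)
        with pytest.raises(ValueError):
            mean_square_displacement(np.zeros((5, 3, 3)), 0.0)
        res = mean_square_displacement(np.zeros((10, 3, 3)), 0.1)
        with pytest.raises(ValueError, match="window"):
            fit_diffusion(res, (0.09, 0.11))  # single lag point

    def test_effective_window_selects_linear_phase(self):
        # synthetic triphasic MSD: fast early slope, slower late slope
        tau = np.geomspace(1e-4, 1.0, 60)
        msd = np.where(tau < 1e-2, 6 * 100 * tau, 6 * 40 * tau + 6 * 60 * 1e-2)
        res = MsdResult(lag_times=np.concatenate([[0], tau]),
                        msd=np.concatenate([[0], msd]),
                        n_samples=np.ones(61, dtype=int), frame_dt=1e-4,
                        n_particles=1)
        lo, hi = effective_window(res, min_lag=5e-2, plateau_msd=1e9)
        assert lo >= 5e-2
        fitted = fit_diffusion(res, (lo, hi))
        assert fitted == pytest.approx(40.0, rel=0.1)


class TestOde:
    def test_zero_rates_constant(self):
        sol = ode_mass_action(0.0, 0.0, (1e-3, 2e-3, 5e-4), np.linspace(0, 10, 50))
        np.testing.assert_allclose(sol.c_a, 1e-3)
        np.testing.assert_allclose(sol.c_c, 5e-4)

    def test_equilibrium_fixed_point(self):
        kf, kb = 50.0, 0.05
        sol = ode_mass_action(kf, kb, (2e-3, 2e-3, 0.0), np.linspace(0, 500, 200))
        a, b, c = sol.c_a[-1], sol.c_b[-1], sol.c_c[-1]
        assert kf * a * b == pytest.approx(kb * c, rel=1e-6)

    def test_conservation_along_trajectory(self):
        sol = ode_mass_action(30.0, 0.02, (1e-3, 2e-3, 1e-4), np.linspace(0, 100, 100))
        np.testing.assert_allclose(sol.c_a + sol.c_c, 1e-3 + 1e-4, rtol=1e-9)
        np.testing.assert_allclose(sol.c_b + sol.c_c, 2e-3 + 1e-4, rtol=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ode_mass_action(-1.0, 0.0, (0, 0, 0), [0, 1])


class TestPlateauScan:
    def test_null_comparison_sits_at_floor(self, xy_registry):
        gen = np.random.default_rng(9)
        tidx = np.zeros(80, dtype=np.int32)

        def mc_like_rdf(seed):
            g = np.random.default_rng(seed)
            frames = [g.uniform(0, 8, (80, 3)) for _ in range(30)]
            return radial_distribution(frames, xy_registry, ["X"], ["X"],
                                       (0, 0, 0), (8,) * 3, type_indices=tidx,
                                       dr=0.2, r_max=3.0)

        reference = mc_like_rdf(100)
        rdfs = {dt: mc_like_rdf(200 + i) for i, dt in enumerate([4e-4, 2e-4, 1e-4])}
        scan = timestep_plateau_scan(lambda dt: rdfs[dt], list(rdfs),
                                     reference, plateau_factor=2.0)
        # identical propagators: every candidate is statistically at the floor,
        # so the plateau is the largest dt
        assert scan.plateau_dt == 4e-4
        assert np.all(scan.rms_error <= 2.0 * scan.rms_error[-1] + 1e-12)

    def test_biased_candidate_excluded_from_plateau(self, xy_registry):
        edges = np.arange(0, 3.0, 0.1)
        ones = np.ones(len(edges) - 1)

        def make(g):
            return RdfResult(bin_edges=edges, g=g, counts=g.copy(),
                             reference_probability=ones / 10, n_frames=1,
                             n_pairs_per_frame=1.0, set_a=("X",), set_b=("X",))

        reference = make(ones.copy())
        curves = {1e-3: make(ones + 0.5), 1e-4: make(ones + 0.01),
                  1e-5: make(ones + 0.012)}
        scan = timestep_plateau_scan(lambda dt: curves[dt], list(curves), reference)
        assert scan.plateau_dt == 1e-4
        assert scan.rms_error[0] == pytest.approx(0.5)
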