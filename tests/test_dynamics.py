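import numpy as np
import pytest

from rdx.dynamics import bd_run, bd_step, mc_sweep, relax, sample_mc
from rdx.model import (
    ParticleTypeSpec,
    SimulationParameters,
    SystemState,
    TypeRegistry,
    make_rng,
    thermal_energy,
)
from rdx.potentials import PairRepulsion, PotentialSet, SphereSurface, BoxWall, total_energy_and_gradient
from tests.conftest import make_random_state

KBT = thermal_energy(293.15)


def _free_state(n, d=100.0, box=1e4, seed=0):
    reg = TypeRegistry([ParticleTypeSpec("X", 1.0, 1.0, d)])
    state = SystemState.empty(reg, (-box, -box, -box), (box, box, box))
    gen = np.random.default_rng(seed)
    state.add_particles("X", gen.uniform(-1, 1, size=(n, 3)))
    return state


class TestBdStep:
    def test_clock_and_identity_bookkeeping(self):
        state = _free_state(10)
        params = SimulationParameters(dt=1e-4, n_steps=1, seed=1)
        new = bd_step(state, PotentialSet(), params, make_rng(1))
        assert new.time == pytest.approx(1e-4)
        assert new.step_index == 1
        np.testing.assert_array_equal(new.ids, state.ids)
        assert not np.allclose(new.positions, state.positions)

    def test_free_displacement_variance_is_2Ddt(self):
        """Fluctuation-dissipation: per-component variance 2 D dt (n = 1e5)."""
        d, dt, n = 100.0, 1e-4, 100_000
        state = _free_state(n, d=d)
        params = SimulationParameters(dt=dt, n_steps=1, seed=2)
        new = bd_step(state, PotentialSet(), params, make_rng(2))
        disp = new.positions - state.positions
        var = disp.var(axis=0)
        se = 2 * d * dt * np.sqrt(2.0 / n)
        np.testing.assert_allclose(var, 2 * d * dt, atol=3 * se)
        assert abs(disp.mean()) < 4 * np.sqrt(2 * d * dt / (3 * n))

    def test_harmonic_well_samples_boltzmann_variance(self):
        """Long-run position variance in an isotropic well approaches kBT/k."""
        k, d, dt = 10.0, 100.0, 1e-5
        state = _free_state(400, d=d, seed=3)
        state.positions[:] = 0.0
        well = PotentialSet([SphereSurface(center=(0, 0, 0), radius=0.0,
                                           force_constant=k)])
        params = SimulationParameters(dt=dt, n_steps=8000, seed=3)
        _, traj = bd_run(state, well, params, make_rng(3))
        samples = traj[2000:].astype(np.float64)  # (F, N, 3), burn-in removed
        # second moment about the known well center (unbiased under correlation)
        per_particle_var = (samples**2).mean(axis=(0, 2))  # independent particles
        target = KBT / k
        se = per_particle_var.std(ddof=1) / np.sqrt(len(per_particle_var))
        assert per_particle_var.mean() == pytest.approx(target, abs=3 * se)

    def test_free_diffusion_msd_matches_6Dtau(self):
        """MSD of >= 1000 free particles equals 6 D tau within 3 SE per lag."""
        from rdx.analysis import mean_square_displacement
        d, dt = 100.0, 1e-3
        state = _free_state(1200, d=d, seed=4)
        params = SimulationParameters(dt=dt, n_steps=200, seed=4)
        _, traj = bd_run(state, PotentialSet(), params, make_rng(4))
        traj = traj.astype(np.float64)
        for lag in (10, 60, 150):
            sq = np.sum((traj[lag] - traj[0]) ** 2, axis=1)
            se = sq.std(ddof=1) / np.sqrt(len(sq))
            assert sq.mean() == pytest.approx(6 * d * lag * dt, abs=3 * se)

    def test_blowup_aborts_with_diagnostic(self):
        state = _free_state(5, d=100.0, seed=5)
        stiff = PotentialSet([SphereSurface(radius=0.0, force_constant=1e4)])
        params = SimulationParameters(dt=1.0, n_steps=1000, seed=5)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="diverged"):
                bd_run(state, stiff, params, make_rng(5))


class TestMcSweep:
    def test_zero_potential_accepts_everything(self):
        state = _free_state(50, seed=6)
        _, frac = mc_sweep(state, PotentialSet(), make_rng(6))
        assert frac == 1.0

    def test_harmonic_well_samples_boltzmann_variance(self):
        """Metropolis chain in an isotropic well reproduces variance kBT/k."""
        k = 10.0
        state = _free_state(1, seed=7)
        state.positions[:] = 0.0
        well = PotentialSet([SphereSurface(radius=0.0, force_constant=k)])
        _, frames, frac = sample_mc(state, well, 30_000, make_rng(7),
                                    frame_stride=1, proposal_sd=0.3)
        assert 0.3 < frac < 1.0
        samples = np.stack(frames[5000:])[:, 0, :]
        block_vars = np.array([
            (blk**2).mean() for blk in np.array_split(samples, 25)])
        se = block_vars.std(ddof=1) / np.sqrt(len(block_vars))
        assert (samples**2).mean() == pytest.approx(KBT / k, abs=3 * se)

    def test_sweep_is_reproducible(self, simple_registry):
        state = make_random_state(simple_registry, {"A": 40, "B": 20}, 12.0, 8)
        pots = PotentialSet([PairRepulsion(force_constant=10.0)])
        a, _ = mc_sweep(state, pots, make_rng(9))
        b, _ = mc_sweep(state, pots, make_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)


class TestRelax:
    def _dense_system(self, simple_registry):
        state = make_random_state(simple_registry, {"A": 31, "B": 31}, 20.0, 10)
        pots = PotentialSet([
            BoxWall(origin=(0, 0, 0), extent=(20, 20, 20), force_constant=10.0),
            PairRepulsion(force_constant=10.0),
        ])
        return state, pots

    def test_zero_sweeps_is_identity(self, simple_registry):
        state, pots = self._dense_system(simple_registry)
        relaxed = relax(state, pots, 0, make_rng(11))
        np.testing.assert_array_equal(relaxed.positions, state.positions)

    def test_overlapping_start_loses_most_energy(self, simple_registry):
        """3000 sweeps drop a dense random start to a small residual energy."""
        state, pots = self._dense_system(simple_registry)
        u0, _ = total_energy_and_gradient(state, pots)
        relaxed = relax(state, pots, 3000, make_rng(12))
        u1, _ = total_energy_and_gradient(relaxed, pots)
        assert u1 < 0.15 * u0
        assert relaxed.n_particles == state.n_particles
        np.testing.assert_array_equal(relaxed.type_indices, state.type_indices)

    def test_relax_is_reproducible(self, simple_registry):
        state, pots = self._dense_system(simple_registry)
        a = relax(state, pots, 50, make_rng(13))
        b = relax(state, pots, 50, make_rng(13))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_python_fallback_matches_boltzmann(self):
        """Potential sets outside the fast kernel use the generic sweep."""
        reg = TypeRegistry([ParticleTypeSpec("X", 1.0, 1.0, 100.0)])
        state = SystemState.empty(reg, (-10, -10, -10), (10, 10, 10))
        state.add_particles("X", np.zeros((1, 3)))
        well = PotentialSet([SphereSurface(radius=0.0, force_constant=10.0),
                             BoxWall(origin=(-10, -10, -10), extent=(10, 10, 10))])
        compiled = well.compile(reg)
        assert not compiled.mc_kernel_supported
        _, frames, _ = sample_mc(state, well, 20_000, make_rng(14),
                                 frame_stride=1, proposal_sd=0.3)
        samples = np.stack(frames[4000:])[:, 0, :]
        assert (samples**2).mean() == pytest.approx(KBT / 10.0, rel=0.12)
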