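import numpy as np
import pytest

from glycoflow import synthetic_microflow as sm
from glycoflow.synthetic_microflow import (IntegrationError, SimConfig,
                                           build_system, compute_forces,
                                           lowe_andersen_collide,
                                           run_simulation,
                                           step_velocity_verlet)

from conftest import free_state


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(Lx=7.0, Ly=7.0, Lz=10.0, n_solvent=150, n_cores=1,
                     chains_per_core=6, beads_per_chain=6, core_beads=4,
                     n_steps=200, record_interval=100, equil_steps=0, seed=5)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize("kw", [
        {"n_cores": 2}, {"dt": -0.1}, {"T": 0.0},
        {"n_steps": 150, "record_interval": 100},
        {"gamma": 300.0},  # gamma*dt >= 1
        {"n_solvent": 0},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw).validate()


class TestBuildSystem:
    def test_control_has_no_chain_beads(self, small_cfg):
        cfg = small_cfg.with_updates(n_cores=0)
        state = build_system(cfg)
        assert np.sum(state.roles == "chain") == 0
        assert np.sum(state.roles == "core") == 0
        n_wall = np.sum(state.roles == "wall")
        n_ceil = np.sum(state.roles == "ceiling")
        assert state.n_particles == cfg.n_solvent + n_wall + n_ceil

    def test_chain_bead_count(self):
        cfg = SimConfig(Lx=12.0, Ly=12.0, Lz=18.0, n_solvent=100, n_cores=3,
                        chains_per_core=6, beads_per_chain=20)
        state = build_system(cfg)
        assert np.sum(state.roles == "chain") == 3 * 6 * 20

    def test_deterministic(self, small_cfg):
        a = build_system(small_cfg)
        b = build_system(small_cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_immobile_walls(self, small_cfg):
        state = build_system(small_cfg)
        frozen = ~state.mobile
        assert np.all(state.velocities[frozen] == 0.0)
        assert set(state.roles[frozen]) == {"wall", "ceiling"}

    def test_min_separation(self, small_cfg):
        state = build_system(small_cfg)
        from glycoflow import _kernels
        pi, pj = _kernels.build_pairs(state.positions, state.mobile,
                                      state.box, small_cfg.r_c)
        d = state.positions[pi] - state.positions[pj]
        for ax in range(2):
            d[:, ax] -= state.box[ax] * np.rint(d[:, ax] / state.box[ax])
        r = np.linalg.norm(d, axis=1)
        # solvent obeys the 0.8 r_c insertion floor; relaxed chain/core
        # beads obey the softer relaxation floor
        assert r.min() > 0.55 * small_cfg.r_c

    def test_packing_failure_reports_density(self):
        cfg = SimConfig(Lx=4.0, Ly=4.0, Lz=5.0, n_solvent=2000, n_cores=0)
        with pytest.raises(sm.PackingError, match="density"):
            build_system(cfg)


class TestForces:
    def test_far_pair_no_force(self, small_cfg):
        state = free_state([[1.0, 1.0, 5.0], [1.0 + 2.5, 1.0, 5.0]],
                           np.zeros((2, 3)), [7.0, 7.0, 10.0])
        F = compute_forces(state, small_cfg.with_updates(f_x=0.0))
        np.testing.assert_allclose(F, 0.0, atol=1e-14)

    def test_lone_solvent_gets_body_force(self, small_cfg):
        state = free_state([[3.0, 3.0, 5.0]], np.zeros((1, 3)),
                           [7.0, 7.0, 10.0])
        F = compute_forces(state, small_cfg.with_updates(f_x=0.25))
        np.testing.assert_allclose(F, [[0.25, 0.0, 0.0]], atol=1e-14)

    def test_bond_at_rest_length(self, small_cfg):
        state = free_state([[1.0, 1.0, 5.0], [1.0, 1.0, 6.5]],
                           np.zeros((2, 3)), [7.0, 7.0, 10.0])
        state.roles[:] = "chain"  # no body force
        state.bonds = np.array([[0, 1]], dtype=np.int64)
        state.bond_r0 = np.array([1.5])
        state.bond_k = np.array([100.0])
        F = compute_forces(state, small_cfg)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_overlap_raises(self, small_cfg):
        state = free_state([[1.0, 1.0, 5.0], [1.0, 1.0, 5.05]],
                           np.zeros((2, 3)), [7.0, 7.0, 10.0])
        with pytest.raises(IntegrationError, match="blow-up"):
            compute_forces(state, small_cfg)


class TestVelocityVerlet:
    def test_free_particle_one_step(self):
        cfg = SimConfig(Lx=50.0, Ly=50.0, Lz=50.0, n_solvent=1, f_x=0.25,
                        dt=0.01)
        state = free_state([[10.0, 10.0, 25.0]], [[0.5, -0.2, 0.1]],
                           [50.0, 50.0, 50.0])
        step_velocity_verlet(state, cfg)
        dt, f, m = 0.01, 0.25, 1.0
        expected = (np.array([10.0, 10.0, 25.0])
                    + np.array([0.5, -0.2, 0.1]) * dt
                    + np.array([f, 0, 0]) * dt ** 2 / (2 * m))
        np.testing.assert_allclose(state.positions[0], expected, rtol=1e-14)

    def test_zero_force_zero_velocity(self):
        cfg = SimConfig(f_x=0.0, dt=0.01)
        state = free_state([[3.0, 3.0, 8.0]], [[0.0, 0.0, 0.0]],
                           [10.0, 10.0, 16.0])
        t0 = state.time
        step_velocity_verlet(state, cfg)
        np.testing.assert_array_equal(state.positions[0], [3.0, 3.0, 8.0])
        assert state.time == pytest.approx(t0 + cfg.dt)

    def test_harmonic_oscillator_oracle(self):
        # tethered particle, omega = sqrt(k/m) = 1, dt = period/100
        period = 2.0 * np.pi
        dt = period / 100.0
        amp = 1.5
        cfg = SimConfig(f_x=0.0, dt=dt)
        state = free_state([[5.0, 5.0, 8.0 + amp]], [[0.0, 0.0, 0.0]],
                           [10.0, 10.0, 20.0])
        state.roles[:] = "chain"
        state.tether_idx = np.array([0], dtype=np.int64)
        state.tether_anchor = np.array([[5.0, 5.0, 8.0]])
        state.tether_k = np.array([1.0])
        energies, zs = [], []
        forces = None
        n_steps = 10_000
        for _ in range(n_steps):
            forces = step_velocity_verlet(state, cfg, forces=forces)
            z = state.positions[0, 2] - 8.0
            v = state.velocities[0, 2]
            energies.append(0.5 * v ** 2 + 0.5 * z ** 2)
            zs.append(z)
        e0 = 0.5 * amp ** 2
        energies = np.array(energies)
        zs = np.array(zs)
        # energy drift < 1e-3 relative over the whole run
        assert np.max(np.abs(energies - e0)) / e0 < 1e-3
        # amplitude (energy envelope) error < 1e-2 relative
        amp_t = np.sqrt(2.0 * energies)
        assert np.max(np.abs(amp_t - amp)) / amp < 1e-2
        # pointwise match over the first 5 periods (before the O(dt^2)
        # symplectic phase drift accumulates)
        t = dt * np.arange(1, n_steps + 1)
        first = t < 5 * period
        assert np.max(np.abs(zs[first] - amp * np.cos(t[first]))) \
            < 1e-2 * amp

    def test_immobile_untouched(self, small_cfg):
        state = build_system(small_cfg)
        frozen = ~state.mobile
        ref = state.positions[frozen].copy()
        step_velocity_verlet(state, small_cfg)
        np.testing.assert_array_equal(state.positions[frozen], ref)
        np.testing.assert_array_equal(state.velocities[frozen], 0.0)


class TestLoweAndersen:
    def test_gamma_zero_noop(self, small_cfg):
        state = free_state([[1.0, 1.0, 5.0], [1.8, 1.0, 5.0]],
                           [[0.3, 0.0, 0.0], [-0.1, 0.2, 0.0]],
                           [7.0, 7.0, 10.0])
        v0 = state.velocities.copy()
        cfg = SimConfig(gamma=1e-12, dt=0.005)
        # gamma=0 is modelled by the integrate loop skipping the sweep;
        # a vanishing rate must leave velocities unchanged almost surely
        rng = np.random.default_rng(0)
        lowe_andersen_collide(state, cfg, rng)
        np.testing.assert_array_equal(state.velocities, v0)

    def test_pair_momentum_conserved_exactly(self):
        cfg = SimConfig(gamma=150.0, dt=0.005)  # p_coll = 0.75
        rng = np.random.default_rng(1)
        collided = False
        for _ in range(10):
            state = free_state([[1.0, 1.0, 5.0], [1.6, 1.3, 5.2]],
                               [[0.4, -0.3, 0.1], [-0.2, 0.5, 0.3]],
                               [7.0, 7.0, 10.0])
            p_before = state.velocities.sum(axis=0)
            v0 = state.velocities.copy()
            n = lowe_andersen_collide(state, cfg, rng)
            if n:
                collided = True
                assert not np.array_equal(state.velocities, v0)
                p_after = state.velocities.sum(axis=0)
                np.testing.assert_allclose(p_after, p_before, atol=1e-14)
        assert collided

    def test_galilean_invariance_of_update(self):
        """A uniform boost commutes with the collision update."""
        cfg = SimConfig(gamma=150.0, dt=0.005)
        boost = np.array([3.0, -1.0, 0.5])
        pos = np.array([[1.0, 1.0, 5.0], [1.6, 1.3, 5.2]])
        vel = np.array([[0.4, -0.3, 0.1], [-0.2, 0.5, 0.3]])
        a = free_state(pos, vel, [7.0, 7.0, 10.0])
        b = free_state(pos, vel + boost, [7.0, 7.0, 10.0])
        lowe_andersen_collide(a, cfg, np.random.default_rng(2))
        lowe_andersen_collide(b, cfg, np.random.default_rng(2))
        np.testing.assert_allclose(b.velocities, a.velocities + boost,
                                   atol=1e-12)

    def test_gamma_dt_over_one_rejected(self):
        state = free_state([[1.0, 1.0, 5.0]], [[0.0, 0.0, 0.0]],
                           [7.0, 7.0, 10.0])
        cfg = SimConfig(gamma=500.0, dt=0.005)
        with pytest.raises(ValueError, match="probability"):
            lowe_andersen_collide(state, cfg, np.random.default_rng(0))


class TestRunSimulation:
    def test_zero_steps_initial_frame_only(self, small_cfg):
        traj = run_simulation(small_cfg.with_updates(n_steps=0,
                                                     equil_steps=0))
        assert traj.n_frames == 1
        assert traj.times[0] == 0.0

    def test_deterministic(self, small_cfg):
        cfg = small_cfg.with_updates(n_steps=300, record_interval=100)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_forced_flow_monotone_in_force(self):
        base = SimConfig(Lx=7.0, Ly=7.0, Lz=10.0, n_solvent=180, n_cores=0,
                         n_steps=6000, record_interval=200,
                         equil_steps=500, seed=11)
        means = []
        for fx in (0.02, 0.08):
            traj = run_simulation(base.with_updates(f_x=fx))
            sol = traj.topology.solvent_mask
            half = traj.n_frames // 2
            means.append(traj.velocities[half:, sol, 0].mean())
        assert means[0] > 0.0
        assert means[1] > means[0]

    def test_momentum_conserved_without_walls(self):
        rng = np.random.default_rng(4)
        n = 40
        pos = np.column_stack([rng.uniform(0, 6, n), rng.uniform(0, 6, n),
                               rng.uniform(2, 18, n)])
        vel = rng.normal(0, 1, (n, 3))
        state = free_state(pos, vel, [6.0, 6.0, 20.0])
        cfg = SimConfig(Lx=6.0, Ly=6.0, Lz=20.0, n_solvent=n, gamma=1.0,
                        f_x=0.0)
        p0 = state.velocities.sum(axis=0)
        sm._integrate(state, cfg, rng, 10_000, body_force=0.0,
                      thermostat=True)
        np.testing.assert_allclose(state.velocities.sum(axis=0), p0,
                                   atol=1e-9)

    def test_tethered_chain_stays_anchored(self, tiny_traj, tiny_config):
        topo = tiny_traj.topology
        apex = None
        for cid in topo.chain_ids():
            members = topo.chain_members(cid)
            base = members[0]
            apex = topo.anchor_index[base]
            assert apex >= 0
            d = tiny_traj.positions[:, base, :] - tiny_traj.positions[:, apex, :]
            for ax in range(2):
                d[:, ax] -= tiny_traj.box[ax] * np.rint(
                    d[:, ax] / tiny_traj.box[ax])
            dist = np.linalg.norm(d, axis=1)
            assert dist.max() < 2.0 * tiny_config.bond_length
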