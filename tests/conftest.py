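import numpy as np
import pytest

from glycoflow import synthetic_microflow as sm
from glycoflow.model import Topology, Trajectory


def make_solvent_trajectory(positions, velocities, times, box):
    """Trajectory of free solvent beads from raw arrays (analysis tests)."""
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    n = positions.shape[1]
    topo = Topology(
        roles=np.array(["solvent"] * n, dtype="U8"),
        chain_id=np.full(n, -1, dtype=np.int64),
        chain_pos=np.full(n, -1, dtype=np.int64),
        anchor_index=np.full(n, -1, dtype=np.int64),
        masses=np.ones(n),
    )
    return Trajectory(times=np.asarray(times, dtype=float),
                      positions=positions, velocities=velocities,
                      box=np.asarray(box, dtype=float), topology=topo)


def free_state(positions, velocities, box, masses=None):
    """Minimal SystemState of unbonded mobile beads."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    return sm.SystemState(
        positions=positions.copy(),
        velocities=np.asarray(velocities, dtype=float).copy(),
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        roles=np.array(["solvent"] * n, dtype="U8"),
        mobile=np.ones(n, dtype=bool),
        bonds=np.empty((0, 2), dtype=np.int64),
        bond_r0=np.empty(0), bond_k=np.empty(0),
        angles=np.empty((0, 3), dtype=np.int64), angle_k=np.empty(0),
        tether_idx=np.empty(0, dtype=np.int64),
        tether_anchor=np.empty((0, 3)), tether_k=np.empty(0),
        box=np.asarray(box, dtype=float),
        chain_id=np.full(n, -1, dtype=np.int64),
        chain_pos=np.full(n, -1, dtype=np.int64),
        anchor_index=np.full(n, -1, dtype=np.int64),
    )


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete system: one core, short chains, fast to run."""
    return sm.SimConfig(Lx=7.0, Ly=7.0, Lz=10.0, n_solvent=200, n_cores=1,
                        chains_per_core=6, beads_per_chain=6, core_beads=4,
                        n_steps=4000, record_interval=100, equil_steps=500,
                        seed=3)


@pytest.fixture(scope="session")
def tiny_traj(tiny_config):
    return sm.run_simulation(tiny_config)


@pytest.fixture(scope="session")
def tiny_control_traj(tiny_config):
    return sm.run_simulation(tiny_config.with_updates(n_cores=0))
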