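"""Desk-scale nonequilibrium particle simulator.

Generates trajectories with the statistical structure the analysis stack
assumes: thermally noisy solvent driven by a constant x-direction body force
past wall-anchored stiff "core" oligomers bearing flexible tethered chains,
confined between a frozen lower wall lattice and a frozen ceiling lattice.

Everything runs in reduced units (epsilon = sigma = m = k_B = 1); the
returned :class:`~glycoflow.model.Trajectory` carries a unit-scale map
(1 length = 1 nm, 1 time = 1 ps by default) so downstream reports can be
expressed in physical units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from glycoflow import _kernels
from glycoflow.model import DEFAULT_UNITS, Topology, Trajectory

log = logging.getLogger(__name__)

#: WCA repulsion range: the pair cut-off r_c is the zero-force distance, so
#: the effective sigma is r_c / 2^(1/6).
_WCA_FACTOR = 2.0 ** (1.0 / 6.0)

#: Pair separation (in units of the effective sigma) below which the
#: integration is declared blown up.
_HARD_FLOOR = 0.35

#: Verlet-list skin added to the pair cut-off.
_SKIN = 0.35


class PackingError(RuntimeError):
    """Raised when non-overlapping solvent placement fails."""


class IntegrationError(RuntimeError):
    """Raised when the integrator produces non-finite or overlapping states."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (reduced units unless noted)."""

    Lx: float = 10.0
    Ly: float = 10.0
    Lz: float = 16.0
    n_solvent: int = 650
    n_cores: int = 3
    chains_per_core: int = 6
    beads_per_chain: int = 8
    core_beads: int = 5
    f_x: float = 0.02
    T: float = 1.0
    gamma: float = 2.0
    r_c: float = 1.12
    dt: float = 0.005
    n_steps: int = 20_000
    record_interval: int = 100
    equil_steps: int = 2_000
    seed: int = 0
    # force-field constants
    k_bond: float = 200.0
    bond_length: float = 0.8
    k_angle: float = 60.0
    k_tether: float = 200.0
    wall_spacing: float = 1.0
    mass: float = 1.0

    def validate(self) -> None:
        positive = ("Lx", "Ly", "Lz", "T", "gamma", "r_c", "dt", "k_bond",
                    "bond_length", "k_angle", "k_tether", "wall_spacing",
                    "mass")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.f_x < 0:
            raise ValueError("f_x must be non-negative")
        if self.n_solvent <= 0:
            raise ValueError("n_solvent must be strictly positive")
        if self.n_cores not in (0, 1, 3):
            raise ValueError("n_cores must be 0 (control), 1 or 3")
        if self.chains_per_core < 0 or self.beads_per_chain <= 0:
            raise ValueError("chain counts must be positive")
        if self.core_beads < 2:
            raise ValueError("core oligomers need at least 2 beads")
        if self.n_steps < 0 or self.equil_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.record_interval <= 0:
            raise ValueError("record_interval must be positive")
        if self.n_steps % self.record_interval != 0:
            raise ValueError(
                f"record_interval ({self.record_interval}) must divide "
                f"n_steps ({self.n_steps})")
        if self.gamma * self.dt >= 1.0:
            raise ValueError(
                f"gamma * dt = {self.gamma * self.dt:.3g} >= 1 is not a "
                "collision probability")

    @property
    def sigma(self) -> float:
        return self.r_c / _WCA_FACTOR

    @property
    def wall_surface(self) -> float:
        """z of the effective lower no-flow plane (one sigma above lattice)."""
        return self.sigma

    def with_updates(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SystemState:
    """Mutable simulation state.

    ``tether_idx``/``tether_anchor`` hold harmonic restraints to fixed points
    in space (core bases); particle-particle tethers are ordinary bonds.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    roles: np.ndarray
    mobile: np.ndarray
    bonds: np.ndarray            # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray           # (na, 3) int
    angle_k: np.ndarray
    tether_idx: np.ndarray
    tether_anchor: np.ndarray    # (nt, 3)
    tether_k: np.ndarray
    box: np.ndarray
    time: float = 0.0
    step: int = 0
    chain_id: np.ndarray = None
    chain_pos: np.ndarray = None
    anchor_index: np.ndarray = None

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        if np.any(self.velocities[~self.mobile] != 0.0):
            raise ValueError("immobile particles must have zero velocity")
        for arr in (self.bonds, self.angles):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError("bond/angle list references invalid indices")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def topology(self) -> Topology:
        return Topology(
            roles=self.roles.copy(),
            chain_id=self.chain_id.copy(),
            chain_pos=self.chain_pos.copy(),
            anchor_index=self.anchor_index.copy(),
            masses=self.masses.copy(),
        )

    def kinetic_temperature(self) -> float:
        """Equipartition estimate T = sum(m v^2) / (3 N_mobile)."""
        m = self.masses[self.mobile]
        v2 = np.sum(self.velocities[self.mobile] ** 2, axis=1)
        return float(np.sum(m * v2) / (3.0 * m.size))


def _wall_lattice(Lx: float, Ly: float, spacing: float, z: float):
    nx = max(int(round(Lx / spacing)), 1)
    ny = max(int(round(Ly / spacing)), 1)
    xs = (np.arange(nx) + 0.5) * (Lx / nx)
    ys = (np.arange(ny) + 0.5) * (Ly / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(),
                           np.full(nx * ny, float(z))])
    return pts


def _core_sites(config: SimConfig) -> np.ndarray:
    cx, cy = config.Lx / 2.0, config.Ly / 2.0
    if config.n_cores == 0:
        return np.empty((0, 2))
    if config.n_cores == 1:
        return np.array([[cx, cy]])
    r = min(config.Lx, config.Ly) / 4.0
    ang = np.array([0.5, 0.5 + 2.0 / 3.0, 0.5 + 4.0 / 3.0]) * np.pi
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def build_system(config: SimConfig, rng: np.random.Generator | None = None
                 ) -> SystemState:
    """Construct the initial state.

    Wall and ceiling are frozen regular lattices at z = 0 and z = Lz.  Each
    core is a stiff vertical oligomer whose base bead is tethered to a fixed
    point just above the wall; ``chains_per_core`` flexible chains are bonded
    to the core apex.  Solvent is inserted by rejection sampling with a
    minimum pair distance of 0.8 r_c, and receives Maxwell-Boltzmann
    velocities at T.  Deterministic for a fixed seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    pos_blocks, roles, chain_id, chain_pos, anchor_index = [], [], [], [], []
    bonds, bond_r0, bond_k = [], [], []
    angles, angle_k = [], []
    tether_idx, tether_anchor, tether_k = [], [], []

    def add(block, role, cid=-1, cpos=-1, anchor=-1):
        start = sum(len(b) for b in pos_blocks)
        pos_blocks.append(np.atleast_2d(block))
        n = len(pos_blocks[-1])
        roles.extend([role] * n)
        chain_id.extend([cid] * n)
        chain_pos.extend(cpos if isinstance(cpos, list) else [cpos] * n)
        anchor_index.extend(anchor if isinstance(anchor, list) else [anchor] * n)
        return start

    wall = _wall_lattice(config.Lx, config.Ly, config.wall_spacing, 0.0)
    ceil = _wall_lattice(config.Lx, config.Ly, config.wall_spacing, config.Lz)
    add(wall, "wall")
    add(ceil, "ceiling")

    b = config.bond_length
    core_spacing = 0.55
    next_chain = 0
    for cxy in _core_sites(config):
        zs = config.wall_surface + 0.2 + core_spacing * np.arange(config.core_beads)
        core_block = np.column_stack([
            np.full(config.core_beads, cxy[0]),
            np.full(config.core_beads, cxy[1]), zs])
        start = add(core_block, "core",
                    cpos=list(range(config.core_beads)),
                    anchor=[-1] * config.core_beads)
        # base bead self-anchored to a fixed point
        anchor_index[start] = start
        tether_idx.append(start)
        tether_anchor.append([cxy[0], cxy[1], zs[0]])
        tether_k.append(config.k_tether)
        for k in range(config.core_beads - 1):
            bonds.append((start + k, start + k + 1))
            bond_r0.append(core_spacing)
            bond_k.append(config.k_bond)
        for k in range(config.core_beads - 2):
            angles.append((start + k, start + k + 1, start + k + 2))
            angle_k.append(config.k_angle)
        apex = start + config.core_beads - 1
        apex_z = zs[-1]
        for c in range(config.chains_per_core):
            phi = 2.0 * np.pi * (c + 0.35) / max(config.chains_per_core, 1)
            # fan out and tilt upward at ~50 degrees, clear of the ceiling
            dirv = np.array([np.cos(phi) * 0.64, np.sin(phi) * 0.64, 0.77])
            steps = (np.arange(config.beads_per_chain) + 1.0)[:, None]
            block = np.array([cxy[0], cxy[1], apex_z]) + steps * b * dirv
            block[:, 2] = np.minimum(block[:, 2], config.Lz - 1.2)
            block[:, 0] %= config.Lx
            block[:, 1] %= config.Ly
            cstart = add(block, "chain", cid=next_chain,
                         cpos=list(range(config.beads_per_chain)),
                         anchor=[apex] + [-1] * (config.beads_per_chain - 1))
            bonds.append((apex, cstart))
            bond_r0.append(b)
            bond_k.append(config.k_bond)
            for k in range(config.beads_per_chain - 1):
                bonds.append((cstart + k, cstart + k + 1))
                bond_r0.append(b)
                bond_k.append(config.k_bond)
            next_chain += 1

    # --- solvent insertion (rejection sampling on a neighbour grid) -------
    occupied = np.vstack(pos_blocks)
    min_dist = 0.8 * config.r_c
    lo_z, hi_z = 0.7, config.Lz - 0.7
    if hi_z <= lo_z:
        raise ValueError("box too thin for solvent placement")
    cap_attempts = 200 * config.n_solvent
    max_stall = 2000  # consecutive rejections before giving up
    placed = np.empty((config.n_solvent, 3))
    n_placed = 0
    attempts = 0
    stall = 0
    all_pts = occupied
    while n_placed < config.n_solvent:
        if attempts >= cap_attempts or stall >= max_stall:
            vol = config.Lx * config.Ly * (hi_z - lo_z)
            raise PackingError(
                f"solvent packing failed after {attempts} attempts: placed "
                f"{n_placed}/{config.n_solvent} beads (achieved density "
                f"{n_placed / vol:.3f} per unit volume)")
        attempts += 1
        cand = np.array([rng.uniform(0, config.Lx),
                         rng.uniform(0, config.Ly),
                         rng.uniform(lo_z, hi_z)])
        d = all_pts - cand
        d[:, 0] -= config.Lx * np.rint(d[:, 0] / config.Lx)
        d[:, 1] -= config.Ly * np.rint(d[:, 1] / config.Ly)
        near = np.abs(d).max(axis=1) < min_dist
        if near.any():
            r2 = np.einsum("ij,ij->i", d[near], d[near])
            if (r2 < min_dist * min_dist).any():
                stall += 1
                continue
        placed[n_placed] = cand
        n_placed += 1
        stall = 0
        all_pts = np.vstack([all_pts, cand[None, :]])
    add(placed, "solvent")

    positions = np.vstack(pos_blocks)
    n = positions.shape[0]
    roles = np.array(roles, dtype="U8")
    mobile = ~np.isin(roles, ("wall", "ceiling"))
    masses = np.full(n, config.mass)
    velocities = np.zeros((n, 3))
    n_mobile = int(mobile.sum())
    v = rng.normal(0.0, math.sqrt(config.T / config.mass), size=(n_mobile, 3))
    v -= v.mean(axis=0)
    velocities[mobile] = v

    state = SystemState(
        positions=positions,
        velocities=velocities,
        masses=masses,
        roles=roles,
        mobile=mobile,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.array(bond_r0, dtype=float),
        bond_k=np.array(bond_k, dtype=float),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        angle_k=np.array(angle_k, dtype=float),
        tether_idx=np.array(tether_idx, dtype=np.int64),
        tether_anchor=np.array(tether_anchor, dtype=float).reshape(-1, 3),
        tether_k=np.array(tether_k, dtype=float),
        box=np.array([config.Lx, config.Ly, config.Lz]),
        chain_id=np.array(chain_id, dtype=np.int64),
        chain_pos=np.array(chain_pos, dtype=np.int64),
        anchor_index=np.array(anchor_index, dtype=np.int64),
    )
    _relax_overlaps(state, config)
    return state


def _relax_overlaps(state: SystemState, config: SimConfig,
                    n_iter: int = 300, max_disp: float = 0.04) -> None:
    """Deterministic capped steepest descent to remove initial overlaps.

    Straight-line chain placement can put beads from different cores closer
    than the WCA core allows; a short displacement-capped descent pushes
    them apart without touching the rng stream.
    """
    target_r2 = (0.9 * config.sigma) ** 2
    for _ in range(n_iter):
        pairs = _kernels.build_pairs(state.positions, state.mobile,
                                     state.box, config.r_c)
        F = compute_forces(state, config, pairs=pairs, body_force=0.0,
                           check_overlap=False)
        min_r2 = _min_pair_r2(state, pairs)
        if min_r2 > target_r2:
            break
        norm = np.linalg.norm(F, axis=1, keepdims=True)
        step = F * (np.minimum(norm, max_disp) / np.maximum(norm, 1e-12))
        state.positions[state.mobile] += step[state.mobile]
        state.positions[:, 0] %= state.box[0]
        state.positions[:, 1] %= state.box[1]
        mob_z = state.positions[state.mobile, 2]
        state.positions[state.mobile, 2] = np.clip(mob_z, 0.3,
                                                   state.box[2] - 0.3)


def _min_pair_r2(state: SystemState, pairs) -> float:
    pi, pj = pairs
    if pi.size == 0:
        return np.inf
    d = state.positions[pi] - state.positions[pj]
    d[:, 0] -= state.box[0] * np.rint(d[:, 0] / state.box[0])
    d[:, 1] -= state.box[1] * np.rint(d[:, 1] / state.box[1])
    return float(np.min(np.einsum("ij,ij->i", d, d)))


def compute_forces(state: SystemState, config: SimConfig,
                   pairs=None, body_force: float | None = None,
                   check_overlap: bool = True) -> np.ndarray:
    """Total force on every particle (immobile included, but never applied).

    Components: WCA repulsion within ``r_c``, harmonic bonds, angle
    stiffening on core oligomers, fixed-point tethers and the constant body
    force ``f_x`` on solvent beads above the wall surface.
    """
    if pairs is None:
        pairs = _kernels.build_pairs(state.positions, state.mobile,
                                     state.box, config.r_c)
    pi, pj = pairs
    F = np.zeros_like(state.positions)
    sigma = config.sigma
    min_r2 = _kernels.wca_forces(state.positions, pi, pj,
                                 state.box[0], state.box[1],
                                 config.r_c ** 2, sigma ** 2, 1.0, F)
    if check_overlap and min_r2 < (_HARD_FLOOR * sigma) ** 2:
        raise IntegrationError(
            f"pair distance {math.sqrt(min_r2):.3g} below hard floor "
            f"{_HARD_FLOOR * sigma:.3g} at step {state.step}: integration "
            "blow-up")
    if state.bonds.size:
        _kernels.bond_forces(state.positions, state.bonds[:, 0],
                             state.bonds[:, 1], state.bond_r0, state.bond_k,
                             state.box[0], state.box[1], F)
    if state.angles.size:
        _kernels.angle_forces(state.positions, state.angles[:, 0],
                              state.angles[:, 1], state.angles[:, 2],
                              state.angle_k, state.box[0], state.box[1], F)
    if state.tether_idx.size:
        _kernels.tether_forces(state.positions, state.tether_idx,
                               state.tether_anchor, state.tether_k,
                               state.box[0], state.box[1], F)
    fx = config.f_x if body_force is None else body_force
    if fx:
        driven = (state.roles == "solvent") & \
            (state.positions[:, 2] > config.wall_surface)
        F[driven, 0] += fx
    return F


def step_velocity_verlet(state: SystemState, config: SimConfig,
                         forces: np.ndarray | None = None,
                         body_force: float | None = None) -> np.ndarray:
    """Advance mobile particles by one velocity-Verlet step of size dt.

    Mutates ``state`` in place and returns the forces at the new positions
    (reusable as the next step's input).  Periodic wrap is applied in x, y.
    """
    if forces is None:
        forces = compute_forces(state, config, body_force=body_force)
    dt = config.dt
    m = state.masses[:, None]
    mob = state.mobile
    state.velocities[mob] += 0.5 * dt * forces[mob] / m[mob]
    state.positions[mob] += dt * state.velocities[mob]
    state.positions[:, 0] %= state.box[0]
    state.positions[:, 1] %= state.box[1]
    new_forces = compute_forces(state, config, body_force=body_force)
    state.velocities[mob] += 0.5 * dt * new_forces[mob] / m[mob]
    state.time += dt
    state.step += 1
    if not np.isfinite(state.positions[mob]).all():
        raise IntegrationError(f"non-finite coordinate at step {state.step}")
    return new_forces


def lowe_andersen_collide(state: SystemState, config: SimConfig,
                          rng: np.random.Generator, pairs=None) -> int:
    """One thermostat sweep; returns the number of collisions applied.

    Each candidate pair within ``r_c`` collides with probability
    ``gamma * dt``; the relative velocity component along the pair axis is
    resampled from the thermal distribution at T, symmetrically, so pair
    momentum is conserved exactly.  Pairs are visited in sorted index order
    driven by a single rng stream, making the sweep deterministic.
    """
    p_coll = config.gamma * config.dt
    if p_coll >= 1.0:
        raise ValueError(f"gamma * dt = {p_coll:.3g} >= 1 is not a "
                         "collision probability")
    if p_coll == 0.0:
        return 0
    if pairs is None:
        pairs = _kernels.build_pairs(state.positions, state.mobile,
                                     state.box, config.r_c)
    pi, pj = pairs
    u = rng.random(pi.size)
    g = rng.standard_normal(pi.size)
    return _kernels.lowe_andersen(
        state.positions, state.velocities, state.masses, state.mobile,
        pi, pj, state.box[0], state.box[1], config.r_c ** 2,
        p_coll, config.T, u, g)


class _NeighbourList:
    """Verlet pair list with displacement-triggered rebuilds."""

    def __init__(self, state: SystemState, r_c: float):
        self.r_list = r_c + _SKIN
        self._rebuild(state)

    def _rebuild(self, state: SystemState) -> None:
        self.pairs = _kernels.build_pairs(state.positions, state.mobile,
                                          state.box, self.r_list)
        self.ref = state.positions.copy()

    def update(self, state: SystemState) -> None:
        disp = state.positions - self.ref
        disp[:, 0] -= state.box[0] * np.rint(disp[:, 0] / state.box[0])
        disp[:, 1] -= state.box[1] * np.rint(disp[:, 1] / state.box[1])
        if np.max(np.einsum("ij,ij->i", disp, disp)) > (0.5 * _SKIN) ** 2:
            self._rebuild(state)


def _integrate(state: SystemState, config: SimConfig,
               rng: np.random.Generator, n_steps: int,
               body_force: float, record_interval: int | None = None,
               thermostat: bool = True):
    """Advance ``n_steps``; optionally record frames every record_interval.

    Returns (times, positions, velocities) lists; always records the state
    *before* the first step when recording is requested.
    """
    nlist = _NeighbourList(state, config.r_c)
    times, pos_out, vel_out = [], [], []

    def record():
        times.append(state.time)
        pos_out.append(state.positions.copy())
        vel_out.append(state.velocities.copy())

    recording = record_interval is not None
    if recording:
        record()
    forces = compute_forces(state, config, pairs=nlist.pairs,
                            body_force=body_force)
    for step in range(1, n_steps + 1):
        try:
            dt = config.dt
            m = state.masses[:, None]
            mob = state.mobile
            state.velocities[mob] += 0.5 * dt * forces[mob] / m[mob]
            state.positions[mob] += dt * state.velocities[mob]
            state.positions[:, 0] %= state.box[0]
            state.positions[:, 1] %= state.box[1]
            nlist.update(state)
            forces = compute_forces(state, config, pairs=nlist.pairs,
                                    body_force=body_force)
            state.velocities[mob] += 0.5 * dt * forces[mob] / m[mob]
            state.time += dt
            state.step += 1
            if thermostat and config.gamma > 0:
                lowe_andersen_collide(state, config, rng, pairs=nlist.pairs)
        except IntegrationError as err:
            raise IntegrationError(
                f"{err} (production step {step}/{n_steps})") from err
        if recording and step % record_interval == 0:
            record()
            if not np.isfinite(state.positions[state.mobile]).all():
                raise IntegrationError(
                    f"non-finite coordinate at step {state.step}")
    return times, pos_out, vel_out


def run_simulation(config: SimConfig) -> Trajectory:
    """Build, equilibrate (zero force) and run the production simulation.

    Frames are recorded every ``record_interval`` production steps starting
    from the production t = 0 state.  Identical output for identical
    (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = build_system(config, rng)
    if config.equil_steps:
        _integrate(state, config, rng, config.equil_steps,
                   body_force=0.0, record_interval=None)
    state.time = 0.0
    times, pos_out, vel_out = _integrate(
        state, config, rng, config.n_steps, body_force=config.f_x,
        record_interval=config.record_interval)
    topo = state.topology()
    traj = Trajectory(
        times=np.array(times),
        positions=np.array(pos_out),
        velocities=np.array(vel_out),
        box=state.box.copy(),
        topology=topo,
        units=dict(DEFAULT_UNITS),
    )
    solvent = topo.solvent_mask
    for i in range(traj.n_frames):
        vmean = traj.velocities[i, solvent, 0].mean()
        ke = 0.5 * np.einsum(
            "i,ij,ij->", topo.masses[topo.mobile_mask],
            traj.velocities[i, topo.mobile_mask],
            traj.velocities[i, topo.mobile_mask])
        temp = 2.0 * ke / (3.0 * topo.mobile_mask.sum())
        log.info("frame %d t=%.3f mean_vx=%.4f T_kin=%.4f",
                 i, traj.times[i], vmean, temp)
    return traj


def desk_config(n_cores: int = 3, seed: int = 0, **overrides) -> SimConfig:
    """Default desk-scale configuration used by tests and the pipeline."""
    return SimConfig(n_cores=n_cores, seed=seed).with_updates(**overrides)
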