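"""Shared trajectory data model.

A :class:`Trajectory` is the only interface between the simulator and every
analysis module: ordered frames of per-particle positions and velocities, a
shared :class:`Topology` describing particle roles, and a unit-scale map that
converts reduced simulation units into physical ones for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Particle roles understood by the analysis stack.
ROLES = ("solvent", "wall", "ceiling", "core", "chain")

#: Default mapping from reduced units to physical units used in reports.
DEFAULT_UNITS = {"length_nm": 1.0, "time_ps": 1.0}


@dataclass
class Topology:
    """Static per-particle metadata shared by all frames.

    Parameters
    ----------
    roles : array of str
        One of :data:`ROLES` per particle.
    chain_id : int array
        Chain membership (``-1`` for particles not on a flexible chain).
        Core oligomers use ids ``>= 0`` in ``core_id`` instead.
    chain_pos : int array
        Along-chain bead index (``-1`` if not on a chain/core).
    anchor_index : int array
        Index of the particle this bead is tethered to; a bead tethered to a
        fixed point in space references itself; ``-1`` means untethered.
    masses : float array
        Particle masses (reduced units).
    """

    roles: np.ndarray
    chain_id: np.ndarray
    chain_pos: np.ndarray
    anchor_index: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.roles)
        for name in ("chain_id", "chain_pos", "anchor_index", "masses"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"topology column {name!r} has length "
                                 f"{len(arr)}, expected {n}")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown particle roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.roles)

    @property
    def solvent_mask(self) -> np.ndarray:
        return self.roles == "solvent"

    @property
    def mobile_mask(self) -> np.ndarray:
        return ~np.isin(self.roles, ("wall", "ceiling"))

    def chain_members(self, chain_id: int) -> np.ndarray:
        """Indices of beads on ``chain_id``, ordered along the contour."""
        members = np.flatnonzero(self.chain_id == chain_id)
        if members.size == 0:
            raise ValueError(f"no particles on chain {chain_id}")
        order = np.argsort(self.chain_pos[members])
        members = members[order]
        pos = self.chain_pos[members]
        if not np.array_equal(pos, np.arange(pos.size)):
            raise ValueError(f"chain {chain_id} has broken along-chain "
                             f"indexing: {pos.tolist()}")
        return members

    def chain_ids(self) -> np.ndarray:
        ids = np.unique(self.chain_id)
        return ids[ids >= 0]


@dataclass
class FrameRecord:
    """One trajectory frame as parallel arrays."""

    time: float
    box: np.ndarray
    species: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("frame arrays have inconsistent lengths")
        if np.any(np.asarray(self.box) <= 0):
            raise ValueError("box lengths must be positive")


@dataclass
class Trajectory:
    """Ordered frames with shared topology and box.

    ``positions``/``velocities`` have shape ``(n_frames, n_particles, 3)``;
    ``times`` is strictly increasing.  ``units`` maps one reduced length/time
    unit to nm/ps for physical-unit reporting.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    topology: Topology
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("trajectory must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        nf, n = self.times.size, len(self.topology)
        if self.positions.shape != (nf, n, 3):
            raise ValueError(f"positions shape {self.positions.shape} does "
                             f"not match {nf} frames x {n} particles")
        if self.velocities.shape != (nf, n, 3):
            raise ValueError("velocities shape does not match positions")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_particles(self) -> int:
        return len(self.topology)

    def frame(self, i: int) -> FrameRecord:
        return FrameRecord(
            time=float(self.times[i]),
            box=self.box,
            species=self.topology.roles,
            positions=self.positions[i],
            velocities=self.velocities[i],
        )

    def window_indices(self, window=None) -> np.ndarray:
        """Frame indices with ``t1 <= t <= t2``.

        The first frame at or after ``t1`` is included; frames strictly after
        ``t2`` are excluded.  ``window=None`` selects every frame.
        """
        if window is None:
            return np.arange(self.n_frames)
        t1, t2 = window
        idx = np.flatnonzero((self.times >= t1) & (self.times <= t2))
        if idx.size == 0:
            raise ValueError(f"no frames in time window [{t1}, {t2}]")
        return idx
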