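"""Polar-coordinate tracking of chain/core segments.

Frames are translation-aligned on a reference centre of mass, segment COMs
are expressed as (x-deviation, R, theta) with theta unwrapped against the
fixed +x flow axis, and the tracks feed swirl counting, inter-segment
motion correlation and chain-uncoiling statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from glycoflow.model import Topology, Trajectory

_R_FLOOR = 1e-12


@dataclass(frozen=True)
class SegmentSpec:
    """A labelled, contiguous run of beads on one chain or core."""

    label: str
    members: np.ndarray
    rule: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.members, dtype=np.int64)
        if m.size == 0:
            raise ValueError("segment has no members")
        object.__setattr__(self, "members", m)


def segment_at_fraction(topology: Topology, chain_id: int,
                        fraction: float = 0.4, width: int = 5,
                        label: str = "") -> SegmentSpec:
    """``width`` beads centred at a fractional position along the contour."""
    members = topology.chain_members(chain_id)
    n = members.size
    centre = int(round(fraction * (n - 1)))
    lo = max(0, min(centre - width // 2, n - width))
    return SegmentSpec(label=label or f"chain{chain_id}@{fraction:.0%}",
                       members=members[lo:lo + width],
                       rule=f"fraction={fraction} width={width}")


def tail_segment(topology: Topology, chain_id: int, width: int = 5,
                 label: str = "") -> SegmentSpec:
    """The terminal ``width`` beads of a chain."""
    members = topology.chain_members(chain_id)
    return SegmentSpec(label=label or f"chain{chain_id}-tail",
                       members=members[-width:],
                       rule=f"terminal width={width}")


def transmembrane_reference(topology: Topology) -> np.ndarray:
    """Core base beads — the fixed reference used for frame alignment."""
    members = np.flatnonzero((topology.roles == "core")
                             & (topology.chain_pos == 0))
    if members.size == 0:
        raise ValueError("topology has no core beads")
    return members


def core_segment(topology: Topology, label: str = "ecto-core") -> SegmentSpec:
    """The core apex beads (the tracked ectodomain protein stand-in)."""
    core = np.flatnonzero(topology.roles == "core")
    if core.size == 0:
        raise ValueError("topology has no core beads")
    top = topology.chain_pos[core].max()
    members = core[topology.chain_pos[core] >= max(top - 1, 1)]
    return SegmentSpec(label=label, members=members, rule="core apex beads")


def _com(positions, members, masses, box):
    """Mass-weighted COM of a compact group, made whole across the periodic
    x,y boundaries by minimum-image displacement from the first member."""
    p = positions[members].copy()
    m = masses[members]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total segment mass")
    ref = p[0]
    for ax in range(2):
        d = p[:, ax] - ref[ax]
        d -= box[ax] * np.rint(d / box[ax])
        p[:, ax] = ref[ax] + d
    return (m[:, None] * p).sum(axis=0) / total


def align_frames(traj: Trajectory, reference_selection) -> Trajectory:
    """Translate every frame so the reference COM sits at the origin.

    Translation only — no rotation, so theta stays referenced to the fixed
    +x flow direction.  Velocities are untouched and positions are no
    longer wrapped into the box.
    """
    ref = np.asarray(reference_selection, dtype=np.int64)
    if ref.size == 0:
        raise ValueError("empty reference selection")
    masses = traj.topology.masses
    pos = traj.positions.copy()
    for f in range(traj.n_frames):
        com = _com(traj.positions[f], ref, masses, traj.box)
        pos[f] -= com
    return Trajectory(times=traj.times.copy(), positions=pos,
                      velocities=traj.velocities.copy(),
                      box=traj.box.copy(), topology=traj.topology,
                      units=dict(traj.units))


@dataclass
class SegmentTrack:
    """Per-frame polar coordinates of a segment COM.

    ``theta`` is unwrapped (continuous); frames where R fell below the
    floor have interpolated theta and are flagged in ``undefined``.
    """

    label: str
    times: np.ndarray
    x: np.ndarray
    R: np.ndarray
    theta: np.ndarray
    undefined: np.ndarray

    @property
    def x_dev(self) -> np.ndarray:
        """x-deviation about the track's time mean (swing signal)."""
        return self.x - self.x.mean()


def polar_track(aligned_traj: Trajectory, segment: SegmentSpec,
                masses=None) -> SegmentTrack:
    """Track a segment's COM in polar coordinates on the XOY plane."""
    topo = aligned_traj.topology
    masses = topo.masses if masses is None else np.asarray(masses, float)
    if masses[segment.members].sum() <= 0:
        raise ValueError("zero total segment mass")
    nf = aligned_traj.n_frames
    com = np.empty((nf, 3))
    for f in range(nf):
        com[f] = _com(aligned_traj.positions[f], segment.members, masses,
                      aligned_traj.box)
    R = np.hypot(com[:, 0], com[:, 1])
    undefined = R < _R_FLOOR
    theta_raw = np.arctan2(com[:, 1], com[:, 0])
    if undefined.all():
        raise ValueError("segment COM coincides with the origin in every "
                         "frame; theta undefined")
    good = ~undefined
    theta = np.empty(nf)
    theta_good = np.unwrap(theta_raw[good])
    theta[good] = theta_good
    if undefined.any():
        theta[undefined] = np.interp(aligned_traj.times[undefined],
                                     aligned_traj.times[good], theta_good)
    return SegmentTrack(label=segment.label, times=aligned_traj.times.copy(),
                        x=com[:, 0], R=R, theta=theta, undefined=undefined)


@dataclass
class SwirlSummary:
    winding: int
    reversals: int
    net_angle: float


def swirl_count(track: SegmentTrack) -> SwirlSummary:
    """Signed number of full revolutions of the unwrapped angle.

    ``winding = sign(net) * floor(|net| / 2 pi)``; also counts direction
    reversals of the angular increments.
    """
    if track.times.size < 3:
        raise ValueError("need at least 3 frames")
    if track.undefined.mean() > 0.10:
        raise ValueError(
            f"{track.undefined.sum()}/{track.undefined.size} frames have "
            "undefined angle (> 10%)")
    net = float(track.theta[-1] - track.theta[0])
    winding = int(np.sign(net) * np.floor(abs(net) / (2.0 * np.pi)))
    dtheta = np.diff(track.theta)
    signs = np.sign(dtheta[dtheta != 0.0])
    reversals = int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
    return SwirlSummary(winding=winding, reversals=reversals, net_angle=net)


@dataclass
class CorrelationSummary:
    r_x: float
    r_x_ci: tuple
    r_dx: float
    r_dx_ci: tuple
    n: int


def _block_bootstrap_ci(a, b, stat, block: int, n_boot: int,
                        rng: np.random.Generator) -> tuple:
    n = a.size
    n_blocks = int(np.ceil(n / block))
    vals = np.empty(n_boot)
    for k in range(n_boot):
        starts = rng.integers(0, n, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % n
        idx = idx[:n]
        vals[k] = stat(a[idx], b[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return (float(lo), float(hi))


def motion_correlation(track_a: SegmentTrack, track_b: SegmentTrack,
                       n_boot: int = 500, seed: int = 0
                       ) -> CorrelationSummary:
    """Pearson correlation of the swing signals and their increments.

    Confidence intervals come from a circular block bootstrap with block
    length one tenth of the series.
    """
    if track_a.times.size < 20:
        raise ValueError("need at least 20 shared frames")
    if (track_a.times.size != track_b.times.size
            or not np.allclose(track_a.times, track_b.times)):
        raise ValueError("tracks must share time stamps")

    def pearson(u, v):
        su, sv = np.std(u), np.std(v)
        if su == 0 or sv == 0:
            return np.nan
        return float(np.corrcoef(u, v)[0, 1])

    xa, xb = track_a.x_dev, track_b.x_dev
    dxa, dxb = np.diff(track_a.x), np.diff(track_b.x)
    rng = np.random.default_rng(seed)
    block = max(track_a.times.size // 10, 2)
    return CorrelationSummary(
        r_x=pearson(xa, xb),
        r_x_ci=_block_bootstrap_ci(xa, xb, pearson, block, n_boot, rng),
        r_dx=pearson(dxa, dxb),
        r_dx_ci=_block_bootstrap_ci(dxa, dxb, pearson, block, n_boot, rng),
        n=track_a.times.size)


@dataclass
class UncoilingSeries:
    times: np.ndarray
    end_to_end: np.ndarray
    radius_of_gyration: np.ndarray
    mann_kendall_S: int

    @property
    def uncoiling(self) -> bool:
        """Net extension trend flag (positive Mann-Kendall score)."""
        return self.mann_kendall_S > 0


def mann_kendall_s(series) -> int:
    """S = sum over pairs i<j of sign(x_j - x_i)."""
    x = np.asarray(series, dtype=float)
    diff = x[None, :] - x[:, None]  # diff[i, j] = x[j] - x[i]
    iu = np.triu_indices(x.size, k=1)
    return int(np.sum(np.sign(diff[iu])))


def uncoiling_series(traj: Trajectory, chain_id: int) -> UncoilingSeries:
    """Per-frame end-to-end distance and radius of gyration of one chain.

    The chain is made whole per frame by walking bonds with minimum-image
    displacements before any distance is measured.
    """
    topo = traj.topology
    members = topo.chain_members(chain_id)
    if members.size < 2:
        raise ValueError(f"chain {chain_id} has fewer than 2 beads")
    masses = topo.masses[members]
    nf = traj.n_frames
    e2e = np.empty(nf)
    rg = np.empty(nf)
    box = traj.box
    for f in range(nf):
        p = traj.positions[f, members].copy()
        # unwrap successive beads along the contour
        for k in range(1, p.shape[0]):
            for ax in range(2):
                d = p[k, ax] - p[k - 1, ax]
                d -= box[ax] * np.rint(d / box[ax])
                p[k, ax] = p[k - 1, ax] + d
        e2e[f] = np.linalg.norm(p[-1] - p[0])
        com = (masses[:, None] * p).sum(axis=0) / masses.sum()
        rg[f] = np.sqrt((masses * np.sum((p - com) ** 2, axis=1)).sum()
                        / masses.sum())
    return UncoilingSeries(times=traj.times.copy(), end_to_end=e2e,
                           radius_of_gyration=rg,
                           mann_kendall_S=mann_kendall_s(e2e))


def default_segments(traj: Trajectory) -> list[SegmentSpec]:
    """Auto-selected segments: mid/tail windows on the two most mobile
    chains (largest COM x-range) plus the core segment."""
    topo = traj.topology
    ids = topo.chain_ids()
    if ids.size < 2:
        raise ValueError("need at least two chains for default segments")
    ranges = []
    for cid in ids:
        members = topo.chain_members(cid)
        xs = traj.positions[:, members, 0].mean(axis=1)
        ranges.append(xs.max() - xs.min())
    top2 = ids[np.argsort(ranges)[-2:]][::-1]
    segs = [
        segment_at_fraction(topo, top2[0], label="P1"),
        segment_at_fraction(topo, top2[1], label="P2"),
        tail_segment(topo, top2[0], label="P3"),
        tail_segment(topo, top2[1], label="P4"),
        core_segment(topo),
    ]
    return segs
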