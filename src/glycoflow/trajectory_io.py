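"""Trajectory, topology and table I/O.

Trajectories are stored as extended XYZ: per frame a particle-count line, a
comment line ``time=<t> box="Lx Ly Lz"`` and one row per particle with
``species x y z vx vy vz`` (always 9+ significant digits — the analysis
stack requires velocities).  The topology sidecar is a plain TSV.  All
numeric analysis outputs go through :func:`write_table`.

No mature pre-installed reader handles extended XYZ *with velocity columns*
round-trip (MDAnalysis' XYZ reader drops them), hence the small parser here.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from glycoflow.model import DEFAULT_UNITS, Topology, Trajectory

_FMT = "%.10g"
_TOPOLOGY_COLUMNS = ["index", "role", "chain_id", "chain_pos",
                     "anchor_index", "mass"]


class FormatError(ValueError):
    """Raised when a file violates the trajectory/table format contract."""


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write an extended-XYZ trajectory file."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    box = traj.box
    lines = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_particles))
        lines.append(
            f'time={_FMT % traj.times[f]} '
            f'box="{_FMT % box[0]} {_FMT % box[1]} {_FMT % box[2]}" '
            f'Properties=species:S:1:pos:R:3:vel:R:3')
        p = traj.positions[f]
        v = traj.velocities[f]
        for i in range(traj.n_particles):
            lines.append(" ".join(
                [str(traj.topology.roles[i])]
                + [_FMT % x for x in p[i]] + [_FMT % x for x in v[i]]))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_topology(topology: Topology, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "index": np.arange(len(topology)),
        "role": topology.roles,
        "chain_id": topology.chain_id,
        "chain_pos": topology.chain_pos,
        "anchor_index": topology.anchor_index,
        "mass": topology.masses,
    })
    df.to_csv(path, sep="\t", index=False)
    return path


def read_topology(path) -> Topology:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"topology file {path} missing columns {missing}")
    df = df.sort_values("index")
    return Topology(
        roles=df["role"].to_numpy(dtype="U8"),
        chain_id=df["chain_id"].to_numpy(dtype=np.int64),
        chain_pos=df["chain_pos"].to_numpy(dtype=np.int64),
        anchor_index=df["anchor_index"].to_numpy(dtype=np.int64),
        masses=df["mass"].to_numpy(dtype=float),
    )


_COMMENT_RE = re.compile(
    r'time=(?P<time>[-+0-9.eE]+)\s+box="(?P<box>[^"]+)"')


def read_trajectory(path, topology_path) -> Trajectory:
    """Read an extended-XYZ trajectory plus its topology sidecar.

    Validates constant particle count, monotone frame times and the presence
    of velocity columns; violations raise :class:`FormatError` naming the
    offending frame.
    """
    topology = read_topology(topology_path)
    text = Path(path).read_text().splitlines()
    frames_t, frames_p, frames_v = [], [], []
    box = None
    ln = 0
    frame = 0
    n_expected = None
    while ln < len(text):
        if not text[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(text[ln].strip())
        except ValueError as err:
            raise FormatError(
                f"frame {frame}: expected particle count, got "
                f"{text[ln]!r}") from err
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise FormatError(
                f"frame {frame}: particle count {natoms} differs from "
                f"first frame ({n_expected})")
        m = _COMMENT_RE.search(text[ln + 1])
        if not m:
            raise FormatError(f"frame {frame}: comment line lacks "
                              "time=/box= metadata")
        t = float(m.group("time"))
        box = np.array([float(x) for x in m.group("box").split()])
        p = np.empty((natoms, 3))
        v = np.empty((natoms, 3))
        for i in range(natoms):
            parts = text[ln + 2 + i].split()
            if len(parts) < 7:
                raise FormatError(
                    f"frame {frame}, atom {i}: missing velocity columns "
                    f"(need species + 6 numbers, got {len(parts)} fields)")
            p[i] = [float(x) for x in parts[1:4]]
            v[i] = [float(x) for x in parts[4:7]]
        frames_t.append(t)
        frames_p.append(p)
        frames_v.append(v)
        ln += 2 + natoms
        frame += 1
    if not frames_t:
        raise FormatError(f"{path}: no frames found")
    if n_expected != len(topology):
        raise FormatError(
            f"trajectory has {n_expected} particles but topology has "
            f"{len(topology)}")
    times = np.array(frames_t)
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise FormatError(f"frame {bad}: non-monotone time stamp")
    return Trajectory(
        times=times,
        positions=np.array(frames_p),
        velocities=np.array(frames_v),
        box=box,
        topology=topology,
        units=dict(DEFAULT_UNITS),
    )


def write_table(rows, schema, path) -> Path:
    """Write rows as TSV with a self-describing header.

    ``schema`` is the ordered list of column names; every row must have the
    same arity.  Floats are written with 10 significant digits.
    """
    schema = list(schema)
    path = Path(path)
    out = ["\t".join(schema)]
    for r, row in enumerate(rows):
        row = list(row)
        if len(row) != len(schema):
            raise ValueError(
                f"row {r} has {len(row)} fields, schema has "
                f"{len(schema)} columns ({schema})")
        cells = []
        for name, val in zip(schema, row):
            if isinstance(val, (float, np.floating)):
                cells.append(_FMT % val)
            else:
                cells.append(str(val))
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pdb_frame(traj: Trajectory, frame: int, path) -> Path:
    """Single-frame PDB export (coordinates only, Angstrom after unit map)."""
    path = Path(path)
    scale = 10.0 * traj.units.get("length_nm", 1.0)  # nm -> Angstrom
    p = traj.positions[frame] * scale
    names = {"solvent": "SOL", "wall": "WAL", "ceiling": "CEI",
             "core": "COR", "chain": "CHN"}
    lines = [f"REMARK   glycoflow frame {frame} t={traj.times[frame]:.6g}"]
    for i in range(traj.n_particles):
        res = names.get(str(traj.topology.roles[i]), "UNK")
        serial = (i % 99999) + 1
        lines.append(
            f"ATOM  {serial:5d}  C   {res} A{(i % 9999) + 1:4d}    "
            f"{p[i, 0]:8.3f}{p[i, 1]:8.3f}{p[i, 2]:8.3f}  1.00  0.00"
            f"           C")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
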