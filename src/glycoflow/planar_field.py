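"""Planar velocity fields: gridding, streamlines, vorticity and PDFs.

Horizontal slabs of solvent samples are pooled onto a regular x,y grid;
streamlines are advected through the bilinearly interpolated field with a
fixed-arc-length RK4 scheme, and vorticity is the discrete curl.  PDFs of
streamline length and vorticity come with an L1 convergence trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glycoflow.model import Trajectory

#: Default layer heights as fractions of the analysed (ectodomain) height.
LAYER_FRACTIONS = (8.0 / 50.0, 24.0 / 50.0, 46.0 / 50.0)


@dataclass
class VelocityField2D:
    """Cell-mean planar velocity on a regular periodic grid.

    ``vx``/``vy`` are indexed ``[ix, iy]``; ``filled`` marks cells whose
    value was interpolated from neighbours rather than sampled.
    """

    z_c: float
    thickness: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    counts: np.ndarray
    filled: np.ndarray
    window: tuple | None = None
    periodic: bool = True

    @property
    def shape(self):
        return self.vx.shape

    @property
    def x_centres(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centres(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def cell_width(self) -> float:
        return float(min(self.x_edges[1] - self.x_edges[0],
                         self.y_edges[1] - self.y_edges[0]))

    @property
    def extent(self):
        return (float(self.x_edges[0]), float(self.x_edges[-1]),
                float(self.y_edges[0]), float(self.y_edges[-1]))

    def rms_speed(self) -> float:
        return float(np.sqrt(np.nanmean(self.vx ** 2 + self.vy ** 2)))

    def interpolate(self, x: float, y: float) -> tuple[float, float]:
        """Bilinear interpolation at (x, y) on cell centres.

        Periodic fields wrap; non-periodic fields clamp to the boundary
        cell centres.
        """
        Lx = self.x_edges[-1] - self.x_edges[0]
        Ly = self.y_edges[-1] - self.y_edges[0]
        nx, ny = self.shape
        dx = self.x_edges[1] - self.x_edges[0]
        dy = self.y_edges[1] - self.y_edges[0]
        fx = (x - self.x_edges[0]) / dx - 0.5
        fy = (y - self.y_edges[0]) / dy - 0.5
        if self.periodic:
            i0 = int(np.floor(fx))
            j0 = int(np.floor(fy))
            tx, ty = fx - i0, fy - j0
            i0 %= nx
            j0 %= ny
            i1, j1 = (i0 + 1) % nx, (j0 + 1) % ny
        else:
            fx = min(max(fx, 0.0), nx - 1.0)
            fy = min(max(fy, 0.0), ny - 1.0)
            i0 = min(int(np.floor(fx)), nx - 2) if nx > 1 else 0
            j0 = min(int(np.floor(fy)), ny - 2) if ny > 1 else 0
            tx, ty = fx - i0, fy - j0
            i1, j1 = min(i0 + 1, nx - 1), min(j0 + 1, ny - 1)
        w00 = (1 - tx) * (1 - ty)
        w10 = tx * (1 - ty)
        w01 = (1 - tx) * ty
        w11 = tx * ty
        vx = (w00 * self.vx[i0, j0] + w10 * self.vx[i1, j0]
              + w01 * self.vx[i0, j1] + w11 * self.vx[i1, j1])
        vy = (w00 * self.vy[i0, j0] + w10 * self.vy[i1, j0]
              + w01 * self.vy[i0, j1] + w11 * self.vy[i1, j1])
        return float(vx), float(vy)


def grid_field(traj: Trajectory, z_c: float, thickness: float = 2.0,
               n_cells: int = 16, window=None) -> VelocityField2D:
    """Pool solvent samples with |z - z_c| <= thickness/2 onto a grid.

    Cells still empty after pooling are filled by inverse-distance weighting
    from the 4 nearest sampled cells and flagged; more than 50% empty cells
    is an error (coarsen the grid or lengthen the window).
    """
    frames = traj.window_indices(window)
    solvent = traj.topology.solvent_mask
    Lx, Ly = float(traj.box[0]), float(traj.box[1])
    if not (0 <= z_c - thickness / 2) or z_c + thickness / 2 > traj.box[2]:
        raise ValueError(f"slab [{z_c - thickness / 2}, "
                         f"{z_c + thickness / 2}] outside box")
    p = traj.positions[frames][:, solvent, :].reshape(-1, 3)
    v = traj.velocities[frames][:, solvent, :].reshape(-1, 3)
    sel = np.abs(p[:, 2] - z_c) <= thickness / 2.0
    p, v = p[sel], v[sel]
    ix = np.floor(p[:, 0] % Lx / (Lx / n_cells)).astype(int) % n_cells
    iy = np.floor(p[:, 1] % Ly / (Ly / n_cells)).astype(int) % n_cells
    flat = ix * n_cells + iy
    counts = np.bincount(flat, minlength=n_cells ** 2)
    sx = np.bincount(flat, weights=v[:, 0], minlength=n_cells ** 2)
    sy = np.bincount(flat, weights=v[:, 1], minlength=n_cells ** 2)
    counts = counts.reshape(n_cells, n_cells)
    with np.errstate(invalid="ignore"):
        vx = np.where(counts > 0,
                      sx.reshape(n_cells, n_cells) / np.maximum(counts, 1),
                      np.nan)
        vy = np.where(counts > 0,
                      sy.reshape(n_cells, n_cells) / np.maximum(counts, 1),
                      np.nan)
    empty = counts == 0
    if empty.mean() > 0.5:
        raise ValueError(
            f"{empty.sum()}/{empty.size} grid cells empty "
            f"({100 * empty.mean():.0f}%): use a coarser grid or a longer "
            "averaging window")
    if empty.any():
        xc = (np.arange(n_cells) + 0.5) * (Lx / n_cells)
        yc = (np.arange(n_cells) + 0.5) * (Ly / n_cells)
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        sampled = ~empty
        sx_, sy_ = gx[sampled], gy[sampled]
        for i, j in zip(*np.nonzero(empty)):
            dx = np.abs(sx_ - gx[i, j])
            dx = np.minimum(dx, Lx - dx)
            dy = np.abs(sy_ - gy[i, j])
            dy = np.minimum(dy, Ly - dy)
            d = np.hypot(dx, dy)
            nearest = np.argsort(d)[:4]
            w = 1.0 / np.maximum(d[nearest], 1e-12)
            w /= w.sum()
            vx[i, j] = np.sum(w * vx[sampled][nearest])
            vy[i, j] = np.sum(w * vy[sampled][nearest])
    return VelocityField2D(
        z_c=z_c, thickness=thickness,
        x_edges=np.linspace(0.0, Lx, n_cells + 1),
        y_edges=np.linspace(0.0, Ly, n_cells + 1),
        vx=vx, vy=vy, counts=counts, filled=empty, window=window)


@dataclass
class Streamline:
    vertices: np.ndarray
    arc_length: float
    seed: tuple
    termination: str  # boundary | max-steps | stagnation


@dataclass
class StreamlineSet:
    streamlines: list

    @property
    def arc_lengths(self) -> np.ndarray:
        return np.array([s.arc_length for s in self.streamlines])


def default_roi(field: VelocityField2D, area_fraction: float = 0.5):
    """Central rectangle covering ``area_fraction`` of the box area."""
    x0, x1, y0, y1 = field.extent
    s = np.sqrt(area_fraction)
    cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    hx, hy = 0.5 * s * (x1 - x0), 0.5 * s * (y1 - y0)
    return (cx - hx, cx + hx, cy - hy, cy + hy)


def seed_grid(field: VelocityField2D, roi=None) -> np.ndarray:
    """Cell centres inside the ROI, used as streamline seeds."""
    if roi is None:
        roi = default_roi(field)
    gx, gy = np.meshgrid(field.x_centres, field.y_centres, indexing="ij")
    inside = ((gx >= roi[0]) & (gx <= roi[1])
              & (gy >= roi[2]) & (gy <= roi[3]))
    return np.column_stack([gx[inside], gy[inside]])


def integrate_streamlines(field: VelocityField2D, seeds,
                          step_frac: float = 0.25, max_steps: int = 10_000,
                          roi=None) -> StreamlineSet:
    """Fixed-step RK4 advection along the unit tangent of the field.

    The spatial step is ``step_frac`` times the cell width, so arc lengths
    are invariant under uniform rescaling of the velocities.  Integration
    stops on ROI exit, after ``max_steps``, or when the local speed drops
    below 1e-6 of the field RMS speed (stagnation).
    """
    if np.isnan(field.vx).any() or np.isnan(field.vy).any():
        raise ValueError("field contains unfilled empty cells")
    if roi is None:
        roi = default_roi(field)
    x0, x1, y0, y1 = roi
    h = step_frac * field.cell_width
    v_floor = 1e-6 * field.rms_speed()
    out = []

    def tangent(pt):
        vx, vy = field.interpolate(pt[0], pt[1])
        speed = np.hypot(vx, vy)
        if speed <= v_floor:
            return None
        return np.array([vx / speed, vy / speed])

    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        if not (x0 <= seed[0] <= x1 and y0 <= seed[1] <= y1):
            raise ValueError(f"seed {tuple(seed)} outside ROI {roi}")
        pt = seed.copy()
        verts = [pt.copy()]
        length = 0.0
        termination = "max-steps"
        for _ in range(max_steps):
            k1 = tangent(pt)
            if k1 is None:
                termination = "stagnation"
                break
            k2 = tangent(pt + 0.5 * h * k1)
            k3 = tangent(pt + 0.5 * h * k2) if k2 is not None else None
            k4 = tangent(pt + h * k3) if k3 is not None else None
            if k2 is None or k3 is None or k4 is None:
                termination = "stagnation"
                break
            new = pt + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not (x0 <= new[0] <= x1 and y0 <= new[1] <= y1):
                termination = "boundary"
                break
            length += float(np.linalg.norm(new - pt))
            pt = new
            verts.append(pt.copy())
        out.append(Streamline(vertices=np.array(verts), arc_length=length,
                              seed=tuple(seed), termination=termination))
    return StreamlineSet(streamlines=out)


def vorticity(field: VelocityField2D) -> np.ndarray:
    """Discrete curl w_z = dv_y/dx - dv_x/dy on the grid.

    Periodic fields use wrapped central differences; non-periodic fields use
    central differences with one-sided edges (exact for linear fields).
    """
    nx, ny = field.shape
    if nx < 3 or ny < 3:
        raise ValueError("vorticity needs at least a 3x3 grid")
    dx = field.x_edges[1] - field.x_edges[0]
    dy = field.y_edges[1] - field.y_edges[0]
    if field.periodic:
        dvy_dx = (np.roll(field.vy, -1, axis=0)
                  - np.roll(field.vy, 1, axis=0)) / (2 * dx)
        dvx_dy = (np.roll(field.vx, -1, axis=1)
                  - np.roll(field.vx, 1, axis=1)) / (2 * dy)
    else:
        dvy_dx = np.gradient(field.vy, dx, axis=0)
        dvx_dy = np.gradient(field.vx, dy, axis=1)
    return dvy_dx - dvx_dy


@dataclass
class PdfCurve:
    """Histogram density with an L1 convergence trace over sample prefixes."""

    support: np.ndarray
    density: np.ndarray
    edges: np.ndarray
    n_samples: int
    converged: bool
    l1_trace: list = field(default_factory=list)


def pdf(samples, n_bins: int = 30,
        convergence_fractions=(0.25, 0.5, 0.75, 1.0)) -> PdfCurve:
    """Histogram PDF with convergence check over growing sample prefixes.

    The curve is converged when every L1 distance between densities at
    successive sample fractions is below 0.05.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 20:
        raise ValueError(f"need at least 20 samples, got {samples.size}")
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    width = edges[1] - edges[0]
    curves = []
    for frac in convergence_fractions:
        n = max(int(np.ceil(frac * samples.size)), 1)
        d, _ = np.histogram(samples[:n], bins=edges, density=True)
        curves.append(d)
    trace = [float(np.sum(np.abs(b - a)) * width)
             for a, b in zip(curves[:-1], curves[1:])]
    return PdfCurve(
        support=0.5 * (edges[:-1] + edges[1:]),
        density=curves[-1], edges=edges, n_samples=samples.size,
        converged=bool(all(t < 0.05 for t in trace)), l1_trace=trace)


def exceedance(samples, thresholds, absolute: bool = True) -> np.ndarray:
    """P(|s| > threshold) for each threshold (P(s > t) if absolute=False)."""
    s = np.asarray(samples, dtype=float).ravel()
    if absolute:
        s = np.abs(s)
    return np.array([float(np.mean(s > t)) for t in np.atleast_1d(thresholds)])


def layer_heights(regions) -> tuple[float, float, float]:
    """Default analysis layer heights (one per region) for a RegionSpec."""
    return tuple(regions.z0 + f * regions.z_f for f in LAYER_FRACTIONS)
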