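"""Velocity-profile analysis over stacked z-regions.

Partitions the space above the wall into three named sub-regions (near-wall
``wg``, dendritic ``d``, flow ``f``), builds time-averaged vertical velocity
profiles inside thin x-slices, temporal layer contours, per-region velocity
series with dispersion summaries, and a second-difference roughness
statistic used to compare the smoothness of profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glycoflow.model import Trajectory

#: Default cumulative region upper bounds above the wall surface, in nm.
DEFAULT_BOUNDS = (12.0, 36.0, 50.0)

#: The same bounds as fractions of the total analysed height, used to scale
#: regions onto reduced-unit simulator boxes.
BOUND_FRACTIONS = (DEFAULT_BOUNDS[0] / DEFAULT_BOUNDS[2],
                   DEFAULT_BOUNDS[1] / DEFAULT_BOUNDS[2],
                   1.0)

REGION_NAMES = ("wg", "d", "f")


@dataclass(frozen=True)
class RegionSpec:
    """Half-open z-intervals [z0, z0+z_wg), [z0+z_wg, z0+z_d), ... ."""

    z0: float
    z_wg: float
    z_d: float
    z_f: float

    def __post_init__(self) -> None:
        if not (0 < self.z_wg < self.z_d < self.z_f):
            raise ValueError(
                f"region bounds must be increasing, got "
                f"({self.z_wg}, {self.z_d}, {self.z_f})")

    @property
    def top(self) -> float:
        return self.z0 + self.z_f

    def interval(self, name: str) -> tuple[float, float]:
        lo = {"wg": 0.0, "d": self.z_wg, "f": self.z_d}[name]
        hi = {"wg": self.z_wg, "d": self.z_d, "f": self.z_f}[name]
        return self.z0 + lo, self.z0 + hi

    def region_of(self, z: float) -> str | None:
        """Region name containing z, or None outside [z0, z0+z_f)."""
        for name in REGION_NAMES:
            lo, hi = self.interval(name)
            if lo <= z < hi:
                return name
        return None


def partition_regions(z0: float, bounds=DEFAULT_BOUNDS) -> RegionSpec:
    """Region spec from cumulative upper bounds measured above ``z0``."""
    b = tuple(float(x) for x in bounds)
    if len(b) != 3 or not (b[0] < b[1] < b[2]):
        raise ValueError(f"bounds must be three increasing values, got {b}")
    return RegionSpec(z0=float(z0), z_wg=b[0], z_d=b[1], z_f=b[2])


def default_regions(traj: Trajectory, z0: float | None = None,
                    margin: float = 1.0) -> RegionSpec:
    """Regions for a simulator box: the analysed height spans from one
    ``margin`` above the wall to one below the ceiling, split at the default
    fractional bounds."""
    if z0 is None:
        z0 = margin
    height = float(traj.box[2]) - z0 - margin
    if height <= 0:
        raise ValueError("box too thin for region partition")
    return partition_regions(z0, tuple(f * height for f in BOUND_FRACTIONS))


@dataclass
class VelocityProfile:
    """Binned mean v_x(z); empty bins are NaN with count 0."""

    edges: np.ndarray
    mean_vx: np.ndarray
    counts: np.ndarray
    window: tuple | None = None
    slice_x: float | None = None
    slice_width: float | None = None

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_bins(self) -> int:
        return self.mean_vx.size


def _bin_samples(z, vx, z0, top, n_bins):
    """Pool samples into half-open z bins; the exact top edge is clamped
    into the last bin so no sample is lost."""
    width = (top - z0) / n_bins
    keep = (z >= z0) & (z <= top)
    z, vx = z[keep], vx[keep]
    idx = np.floor((z - z0) / width).astype(np.int64)
    idx = np.minimum(idx, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return counts, means


def slice_profile(traj: Trajectory, regions: RegionSpec, x_centre: float,
                  slice_width: float = 2.0, n_bins: int = 25,
                  window=None) -> VelocityProfile:
    """Time-averaged v_x(z) for solvent beads inside a thin x-slice.

    Samples are pooled over (bead, frame); the periodic-aware distance
    ``|x - x_centre| <= slice_width / 2`` selects beads.
    """
    if slice_width > traj.box[0]:
        raise ValueError(f"slice width {slice_width} exceeds box "
                         f"{traj.box[0]}")
    frames = traj.window_indices(window)
    solvent = traj.topology.solvent_mask
    Lx = float(traj.box[0])
    z0, top = regions.z0, regions.top
    z_all, vx_all = [], []
    for f in frames:
        x = traj.positions[f, solvent, 0]
        dx = x - x_centre
        dx -= Lx * np.rint(dx / Lx)
        sel = np.abs(dx) <= slice_width / 2.0
        z_all.append(traj.positions[f, solvent, 2][sel])
        vx_all.append(traj.velocities[f, solvent, 0][sel])
    counts, means = _bin_samples(np.concatenate(z_all),
                                 np.concatenate(vx_all), z0, top, n_bins)
    return VelocityProfile(
        edges=np.linspace(z0, top, n_bins + 1),
        mean_vx=means, counts=counts, window=window,
        slice_x=x_centre, slice_width=slice_width)


def whole_extent_profile(traj: Trajectory, regions: RegionSpec,
                         n_bins: int = 25, window=None) -> VelocityProfile:
    """Profile pooling every solvent bead (no x-slice)."""
    frames = traj.window_indices(window)
    solvent = traj.topology.solvent_mask
    z = traj.positions[frames][:, solvent, 2].ravel()
    vx = traj.velocities[frames][:, solvent, 0].ravel()
    counts, means = _bin_samples(z, vx, regions.z0, regions.top, n_bins)
    return VelocityProfile(
        edges=np.linspace(regions.z0, regions.top, n_bins + 1),
        mean_vx=means, counts=counts, window=window)


@dataclass
class TemporalContour:
    times: np.ndarray
    layer_centres: np.ndarray
    values: np.ndarray  # (n_layers, n_ticks), NaN where a layer is empty


def temporal_contour(traj: Trajectory, regions: RegionSpec,
                     n_layers: int = 25, cadence: float | None = None
                     ) -> TemporalContour:
    """Layer-mean v_x over the full x,y extent at regular time ticks.

    Each tick uses the nearest recorded frame.  ``cadence`` must be at least
    the frame spacing; by default every frame is a tick.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if cadence is None:
        frame_idx = np.arange(traj.n_frames)
        ticks = traj.times
    else:
        if traj.n_frames > 1:
            spacing = float(np.min(np.diff(traj.times)))
            if cadence < spacing:
                raise ValueError(
                    f"cadence {cadence} below frame spacing {spacing}")
        ticks = np.arange(traj.times[0], traj.times[-1] + 1e-12, cadence)
        frame_idx = np.array([int(np.argmin(np.abs(traj.times - t)))
                              for t in ticks])
    solvent = traj.topology.solvent_mask
    values = np.empty((n_layers, len(frame_idx)))
    for col, f in enumerate(frame_idx):
        _, means = _bin_samples(traj.positions[f, solvent, 2],
                                traj.velocities[f, solvent, 0],
                                regions.z0, regions.top, n_layers)
        values[:, col] = means
    edges = np.linspace(regions.z0, regions.top, n_layers + 1)
    return TemporalContour(times=ticks, layer_centres=0.5 * (edges[:-1]
                                                             + edges[1:]),
                           values=values)


@dataclass
class RegionalVelocitySeries:
    """Per-frame regional mean solvent v_x; NaN where a region is empty."""

    times: np.ndarray
    v_wg: np.ndarray
    v_d: np.ndarray
    v_f: np.ndarray

    def region(self, name: str) -> np.ndarray:
        return {"wg": self.v_wg, "d": self.v_d, "f": self.v_f}[name]

    def dispersion(self) -> dict:
        """Inter-frame std and central 95% width per region."""
        out = {}
        for name in REGION_NAMES:
            v = self.region(name)
            v = v[~np.isnan(v)]
            if v.size == 0:
                out[name] = {"std": np.nan, "width95": np.nan}
            else:
                lo, hi = np.percentile(v, [2.5, 97.5])
                out[name] = {"std": float(np.std(v)),
                             "width95": float(hi - lo)}
        return out


def regional_series(traj: Trajectory, regions: RegionSpec,
                    window=None) -> RegionalVelocitySeries:
    frames = traj.window_indices(window)
    solvent = traj.topology.solvent_mask
    out = {name: np.empty(len(frames)) for name in REGION_NAMES}
    for k, f in enumerate(frames):
        z = traj.positions[f, solvent, 2]
        vx = traj.velocities[f, solvent, 0]
        for name in REGION_NAMES:
            lo, hi = regions.interval(name)
            sel = (z >= lo) & (z < hi)
            out[name][k] = vx[sel].mean() if sel.any() else np.nan
    return RegionalVelocitySeries(times=traj.times[frames],
                                  v_wg=out["wg"], v_d=out["d"],
                                  v_f=out["f"])


def roughness(profile: VelocityProfile) -> float:
    """Mean |second difference| of bin means over non-missing triples.

    A linear profile scores 0; an alternating +-a profile scores 4a.
    """
    v = profile.mean_vx
    if np.sum(~np.isnan(v)) < 3:
        raise ValueError("roughness needs at least 3 non-missing bins")
    d2 = v[:-2] - 2.0 * v[1:-1] + v[2:]
    d2 = d2[~np.isnan(d2)]
    if d2.size == 0:
        raise ValueError("no consecutive non-missing bin triples")
    return float(np.mean(np.abs(d2)))


def roughness_windows(traj: Trajectory, regions: RegionSpec,
                      x_centre: float | None, n_windows: int,
                      window=None, **slice_kwargs) -> list[float]:
    """Roughness of the profile recomputed in equal disjoint sub-windows.

    ``x_centre=None`` uses the whole x,y extent.
    """
    frames = traj.window_indices(window)
    t_lo, t_hi = traj.times[frames[0]], traj.times[frames[-1]]
    edges = np.linspace(t_lo, t_hi, n_windows + 1)
    vals = []
    for w in range(n_windows):
        sub = (edges[w], edges[w + 1] if w == n_windows - 1
               else np.nextafter(edges[w + 1], -np.inf))
        if x_centre is None:
            p = whole_extent_profile(traj, regions, window=sub,
                                     **slice_kwargs)
        else:
            p = slice_profile(traj, regions, x_centre, window=sub,
                              **slice_kwargs)
        vals.append(roughness(p))
    return vals


def compare_roughness(traj: Trajectory, regions: RegionSpec,
                      x_a: float, x_b: float, n_windows: int = 6,
                      window=None, **slice_kwargs) -> dict:
    """K-S comparison of per-sub-window roughness between two slices."""
    from glycoflow.shear_stats import ks_two_sample

    if n_windows < 2:
        raise ValueError("need at least 2 sub-windows for a comparison")
    ra = roughness_windows(traj, regions, x_a, n_windows, window=window,
                           **slice_kwargs)
    rb = roughness_windows(traj, regions, x_b, n_windows, window=window,
                           **slice_kwargs)
    D, p = ks_two_sample(np.asarray(ra), np.asarray(rb))
    return {"D": D, "p": p, "roughness_a": ra, "roughness_b": rb}
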