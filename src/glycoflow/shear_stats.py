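"""Forward-difference shear stress and its regional statistics.

Shear stress is tau = mu * dv_x/dz estimated by forward differences on a
binned velocity profile; per-instant regional averages form a time series
that is compared across regions and scenarios via two-sample K-S tests and
ratio-exceedance probabilities.  A Reynolds-number helper classifies the
flow regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from glycoflow.model import Trajectory
from glycoflow.region_binning import (REGION_NAMES, RegionSpec,
                                      VelocityProfile,
                                      whole_extent_profile)

#: Dynamic viscosity of TIP3P water at 310 K, in Pa s; the default constant
#: for physical-unit shear-stress reporting.
TIP3P_WATER_VISCOSITY = 0.321e-3


def shear_profile(profile: VelocityProfile, mu: float) -> np.ndarray:
    """Per-bin forward-difference shear stress.

    ``tau[i] = mu * (v[i+1] - v[i]) / (z[i+1] - z[i])`` using bin centres;
    the topmost bin has no forward neighbour and reports NaN, as does any
    bin adjacent to a missing one.
    """
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    v = profile.mean_vx
    if np.sum(~np.isnan(v)) < 2:
        raise ValueError("need at least 2 non-missing consecutive bins")
    z = profile.centres
    tau = np.full(v.size, np.nan)
    with np.errstate(invalid="ignore"):
        tau[:-1] = mu * (v[1:] - v[:-1]) / (z[1:] - z[:-1])
    if np.all(np.isnan(tau)):
        raise ValueError("no consecutive non-missing bin pairs")
    return tau


@dataclass
class ShearStressSeries:
    """Per-instant regional shear stress (NaN where a region had no data)."""

    times: np.ndarray
    tau_wg: np.ndarray
    tau_d: np.ndarray
    tau_f: np.ndarray
    mu: float
    cadence: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("series times must be strictly increasing")

    def region(self, name: str) -> np.ndarray:
        return {"wg": self.tau_wg, "d": self.tau_d, "f": self.tau_f}[name]

    def __len__(self) -> int:
        return self.times.size


def regional_series(traj: Trajectory, regions: RegionSpec, mu: float,
                    cadence: float | None = None, n_bins: int = 25,
                    window=None) -> ShearStressSeries:
    """Regional shear-stress series from instantaneous binned profiles.

    At each cadence tick (nearest recorded frame), the whole-extent
    ``n_bins`` profile is built, converted to per-bin forward-difference
    tau, and tau is averaged (unweighted, NaN-aware) over the bins whose
    centres fall in each region.
    """
    frames = traj.window_indices(window)
    times = traj.times[frames]
    if cadence is None:
        picks = frames
        tick_times = times
    else:
        if times.size > 1:
            spacing = float(np.min(np.diff(times)))
            if cadence < spacing:
                raise ValueError(
                    f"cadence {cadence} below frame spacing {spacing}")
        tick_times = np.arange(times[0], times[-1] + 1e-12, cadence)
        picks = frames[[int(np.argmin(np.abs(times - t)))
                        for t in tick_times]]
    edges = np.linspace(regions.z0, regions.top, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    masks = {}
    for name in REGION_NAMES:
        lo, hi = regions.interval(name)
        masks[name] = (centres >= lo) & (centres < hi)
        if not masks[name].any():
            raise ValueError(f"region {name!r} contains no bin centres with "
                             f"{n_bins} bins")
    out = {name: np.empty(len(picks)) for name in REGION_NAMES}
    for k, f in enumerate(picks):
        prof = whole_extent_profile(traj, regions, n_bins=n_bins,
                                    window=(traj.times[f], traj.times[f]))
        tau = shear_profile(prof, mu)
        for name in REGION_NAMES:
            vals = tau[masks[name]]
            vals = vals[~np.isnan(vals)]
            out[name][k] = vals.mean() if vals.size else np.nan
    return ShearStressSeries(times=np.asarray(tick_times, dtype=float),
                             tau_wg=out["wg"], tau_d=out["d"],
                             tau_f=out["f"], mu=mu, cadence=cadence)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the supremum ECDF distance (ties handled by evaluating both ECDFs
    on the pooled support); p uses the asymptotic distribution with
    effective size n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size < 5 or b.size < 5:
        raise ValueError(f"each sample needs >= 5 values, got "
                         f"{a.size} and {b.size}")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    ne = a.size * b.size / (a.size + b.size)
    en = np.sqrt(ne)
    p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * D))
    return D, min(max(p, 0.0), 1.0)


@dataclass
class ExceedanceReport:
    """Empirical P(|tau_num|/|tau_den| > theta) (or < theta) per threshold."""

    thresholds: np.ndarray
    probabilities: np.ndarray
    n_used: int
    n_excluded: int
    direction: str
    label: str = ""

    def __post_init__(self) -> None:
        p = self.probabilities
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities outside [0, 1]")


def ratio_exceedance(series: ShearStressSeries, numerator: str,
                     denominator: str, thresholds, direction: str = ">",
                     label: str = "") -> ExceedanceReport:
    """Fraction of instants with |tau_num|/|tau_den| beyond each threshold.

    Instants whose denominator magnitude is below 1e-12 of its RMS (or NaN)
    are excluded and counted, never turned into infinities.
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("thresholds list is empty")
    if direction not in (">", "<"):
        raise ValueError("direction must be '>' or '<'")
    if len(series) == 0:
        raise ValueError("empty shear-stress series")
    num = np.abs(series.region(numerator))
    den = np.abs(series.region(denominator))
    finite = ~(np.isnan(num) | np.isnan(den))
    rms = np.sqrt(np.nanmean(den[finite] ** 2)) if finite.any() else 0.0
    ok = finite & (den > 1e-12 * rms)
    n_excluded = int(len(series) - ok.sum())
    if not ok.any():
        raise ValueError("all instants excluded (denominator ~ 0)")
    ratio = num[ok] / den[ok]
    if direction == ">":
        probs = np.array([float(np.mean(ratio > t)) for t in thresholds])
    else:
        probs = np.array([float(np.mean(ratio < t)) for t in thresholds])
    return ExceedanceReport(thresholds=thresholds, probabilities=probs,
                            n_used=int(ok.sum()), n_excluded=n_excluded,
                            direction=direction, label=label)


@dataclass
class ScenarioComparison:
    report_a: ExceedanceReport
    report_b: ExceedanceReport
    ks_by_region: dict

    def to_rows(self):
        rows = []
        for rep in (self.report_a, self.report_b):
            for t, p in zip(rep.thresholds, rep.probabilities):
                rows.append((rep.label, f"|tau_wg|/|tau_f| {rep.direction} "
                             f"{t:g}", p, rep.n_used, rep.n_excluded))
        return rows


def compare_scenarios(series_a: ShearStressSeries,
                      series_b: ShearStressSeries, thresholds,
                      labels=("A", "B")) -> ScenarioComparison:
    """Paired exceedance reports plus per-region K-S of |tau|."""
    if len(series_a) == 0 or len(series_b) == 0:
        raise ValueError("scenario series must be non-empty")
    if series_a.mu != series_b.mu:
        raise ValueError(f"viscosity mismatch between scenarios: "
                         f"{series_a.mu} vs {series_b.mu}")
    rep_a = ratio_exceedance(series_a, "wg", "f", thresholds, ">", labels[0])
    rep_b = ratio_exceedance(series_b, "wg", "f", thresholds, ">", labels[1])
    ks = {}
    for name in REGION_NAMES:
        xa = np.abs(series_a.region(name))
        xb = np.abs(series_b.region(name))
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        ks[name] = ks_two_sample(xa, xb)
    return ScenarioComparison(report_a=rep_a, report_b=rep_b,
                              ks_by_region=ks)


def reynolds_number(rho: float, v: float, L: float, mu: float) -> float:
    """Re = rho v L / mu (any consistent unit system)."""
    for name, val in (("rho", rho), ("v", v), ("L", L), ("mu", mu)):
        if val <= 0:
            raise ValueError(f"{name} must be strictly positive")
    return rho * v * L / mu


def classify_flow(re: float) -> str:
    """Coarse regime label; Re < 1 is creeping/laminar."""
    if re < 1.0:
        return "creeping/laminar"
    if re < 2000.0:
        return "laminar"
    return "transitional/turbulent"
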