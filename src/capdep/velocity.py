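"""Velocimetry and saturation kinetics.

Depolymerization velocities from length-vs-time records and kymographs
(2.7 nm of filament per actin subunit), velocities segmented by
occupancy state, the Michaelis–Menten fit of velocity vs depolymerase
concentration, and the occupancy-vs-velocity comparison table.

Velocities are signed internally (negative slope = shrinking) and
reported as positive depolymerization rates at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetics import KineticParams, MMFitResult, occupancy
from .simulate import FilamentTrajectory, ImagingGeometry
from .traces import DwellSet

__all__ = [
    "VelocityMeasurement",
    "OccupancyVelocityRow",
    "SlopeFit",
    "fit_trajectory_velocity",
    "kymograph_slope",
    "segment_velocities",
    "fit_mm",
    "occupancy_velocity_table",
]


@dataclass(frozen=True)
class VelocityMeasurement:
    """Per-condition depolymerization rate summary."""

    rate: float  # subunits/s, positive = depolymerization
    sd: float
    n_filaments: int
    condition: str = ""
    concentration: float | None = None  # molar

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n_filaments < 1:
            raise ValueError("sd must be >= 0 and n_filaments >= 1")


@dataclass(frozen=True)
class OccupancyVelocityRow:
    """One concentration of the occupancy-vs-velocity comparison."""

    c: float  # molar
    occupancy_fraction: float
    velocity_fraction: float

    def __post_init__(self) -> None:
        for v in (self.occupancy_fraction, self.velocity_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


class SlopeFit(NamedTuple):
    rate: float  # subunits/s, positive = depolymerization
    se: float
    n_points: int


def fit_trajectory_velocity(
    times: np.ndarray,
    lengths: np.ndarray,
    interval: tuple[float, float] | None = None,
    lengths_in_nm: bool = False,
) -> SlopeFit:
    """Depolymerization rate from a length-vs-time record.

    Ordinary least-squares slope of length vs time, negated so shrinkage
    is positive.  ``interval`` restricts the fit to a time window; nm
    inputs are converted at 2.7 nm per subunit.
    """
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if interval is not None:
        sel = (times >= interval[0]) & (times <= interval[1])
        times, lengths = times[sel], lengths[sel]
    ok = np.isfinite(lengths)
    times, lengths = times[ok], lengths[ok]
    if times.size < 3:
        raise ValueError("need at least 3 points for a velocity fit")
    if lengths_in_nm:
        lengths = lengths / 2.7
    A = np.vstack([times, np.ones_like(times)]).T
    coef, res, *_ = np.linalg.lstsq(A, lengths, rcond=None)
    slope = coef[0]
    dof = times.size - 2
    if dof > 0 and res.size:
        s2 = res[0] / dof
        se = float(np.sqrt(s2 / np.sum((times - times.mean()) ** 2)))
    else:
        se = 0.0
    return SlopeFit(-float(slope), se, times.size)


def kymograph_slope(
    kymo: np.ndarray,
    geometry: ImagingGeometry,
    frame_interval_s: float,
    threshold: float | None = None,
    robust: bool = False,
    max_missing_fraction: float = 0.2,
) -> SlopeFit:
    """Depolymerization rate from a space-time image.

    Rows are time, columns are space with the filament extending from
    the left; per row the end position is the last supra-threshold
    column.  The positions-vs-time slope (px/frame) is converted to
    subunits/s via ``pixel_nm`` and 2.7 nm/subunit.  The default
    threshold is midway between robust background and filament levels;
    ``robust=True`` uses a least-absolute-deviation fit instead of OLS.
    """
    kymo = np.asarray(kymo, dtype=float)
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if threshold is None:
        lo, hi = np.percentile(kymo, [10, 90])
        threshold = 0.5 * (lo + hi)
    T = kymo.shape[0]
    pos = np.full(T, np.nan)
    for t in range(T):
        above = np.nonzero(kymo[t] > threshold)[0]
        if above.size:
            pos[t] = above[-1]
    ok = np.isfinite(pos)
    if ok.sum() < (1.0 - max_missing_fraction) * T or ok.sum() < 3:
        raise ValueError("filament edge not found in enough kymograph rows")
    tt = np.arange(T)[ok] * frame_interval_s
    xx = pos[ok]
    if robust:
        from scipy.optimize import minimize

        def lad(b):
            return np.abs(xx - (b[0] * tt + b[1])).sum()

        b0 = np.polyfit(tt, xx, 1)
        slope_px = minimize(lad, b0, method="Nelder-Mead").x[0]
    else:
        slope_px = np.polyfit(tt, xx, 1)[0]
    rate = -slope_px * geometry.pixel_nm / geometry.subunit_nm
    return SlopeFit(float(rate), float("nan"), int(ok.sum()))


def segment_velocities(
    traj: FilamentTrajectory,
    dwells: DwellSet,
    min_points: int = 3,
) -> tuple[list[float], list[float], int]:
    """Per-interval depolymerization velocities split by occupancy.

    Fits a line to the observed length inside each dwell (bound) and
    each gap between dwells (unbound).  Intervals with fewer than
    ``min_points`` frames are skipped and counted.

    Returns ``(bound, unbound, n_skipped)``.
    """
    bound, unbound, skipped = [], [], 0
    intervals: list[tuple[float, float, bool]] = [(s, e, True) for s, e in dwells.dwells]
    for (s0, e0), (s1, _e1) in zip(dwells.dwells, dwells.dwells[1:]):
        intervals.append((e0, s1, False))
    for t0, t1, is_bound in intervals:
        sel = (traj.times >= t0) & (traj.times < t1)
        if sel.sum() < min_points:
            skipped += 1
            continue
        fit = fit_trajectory_velocity(traj.times[sel], traj.length_observed[sel])
        (bound if is_bound else unbound).append(fit.rate)
    return bound, unbound, skipped


def fit_mm(velocities, weighted: bool = False) -> MMFitResult:
    """Michaelis–Menten fit of velocity vs depolymerase concentration.

    ``velocities`` is a DataFrame with columns ``concentration_M`` and
    ``velocity_subunits_per_s`` (or a (c, v) pair of arrays).  Nonlinear
    least squares of v = k_cat*c/(K_M + c), initialized at
    K_M = median(c), k_cat = max(v); SEs from the fit covariance.
    """
    if isinstance(velocities, pd.DataFrame):
        c = velocities["concentration_M"].to_numpy(dtype=float)
        v = velocities["velocity_subunits_per_s"].to_numpy(dtype=float)
    else:
        c, v = (np.asarray(a, dtype=float) for a in velocities)
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")

    def mm(cc, km, kcat):
        return kcat * cc / (km + cc)

    p0 = (float(np.median(c)), float(np.max(v)))
    try:
        popt, pcov = curve_fit(mm, c, v, p0=p0, maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Michaelis–Menten fit failed to converge: {err}") from err
    se = np.sqrt(np.diag(pcov))
    return MMFitResult(
        K_M=float(popt[0]),
        k_cat=float(popt[1]),
        se_K_M=float(se[0]),
        se_k_cat=float(se[1]),
        n_points=int(c.size),
    )


def occupancy_velocity_table(
    params: KineticParams,
    fit: MMFitResult,
    concentrations: Sequence[float],
) -> pd.DataFrame:
    """Occupancy vs fractional-velocity comparison across concentrations.

    Per concentration: end occupancy c*K_A/(1 + c*K_A) from the
    single-molecule rate constants, and the fraction of saturating
    velocity c/(c + K_M) from the saturation fit.
    """
    rows = []
    for c in concentrations:
        occ = occupancy(c, params.k_on, params.k_off) if c > 0 else 0.0
        vf = c / (c + fit.K_M) if c > 0 else 0.0
        row = OccupancyVelocityRow(c=float(c), occupancy_fraction=occ, velocity_fraction=vf)
        rows.append(
            {
                "concentration_M": row.c,
                "occupancy_fraction": row.occupancy_fraction,
                "velocity_fraction": row.velocity_fraction,
            }
        )
    return pd.DataFrame(rows)
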