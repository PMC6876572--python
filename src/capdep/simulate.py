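"""Seeded stochastic generators for every input the analysis stages consume.

The generators emulate a microfluidics-assisted TIRF experiment on
Cofilin-decorated actin filaments held by their barbed ends:

* two-state pointed-end occupancy dynamics (exponential gaps and dwells)
  with Poisson subunit removal, discretized to the camera frame grid
  (0.065 s per frame by default);
* single-spot fluorescence traces of the end-bound hexamer, including
  Binomial(6, p) dye loading, photobleaching and camera noise;
* photobleaching staircases of surface-immobilized molecules;
* per-filament velocity datasets following a saturation curve;
* optional rendered two-channel image stacks (green actin / red hexamer).

Every generator takes an integer seed and is bit-reproducible for a
fixed seed.  Simulation is event-driven (exact exponential sampling of
transition times) and only afterwards discretized to frames; there is no
fixed-timestep approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams, LabelingModel, MMFitResult, mm_velocity

__all__ = [
    "BindingEvent",
    "FilamentTrajectory",
    "IntensityTrace",
    "ImagingGeometry",
    "simulate_end_dynamics",
    "render_intensity_trace",
    "simulate_photobleach_traces",
    "simulate_velocity_dataset",
    "simulate_shrinking_filaments",
    "render_movie",
]

DEFAULT_FRAME_INTERVAL = 0.065  # s, high-time-resolution acquisition


@dataclass(frozen=True)
class BindingEvent:
    """One hexamer binding event at the pointed end."""

    bind_time: float
    unbind_time: float
    productive: bool
    n_dyes: int

    @property
    def dwell(self) -> float:
        return self.unbind_time - self.bind_time


@dataclass
class FilamentTrajectory:
    """Length-vs-time record of one depolymerizing filament.

    ``length_true`` is the exact subunit count on the frame grid;
    ``length_observed`` adds the configured measurement noise (filament
    Brownian motion plus sparse 10% actin labeling make real length
    measurements noisy at the ~10 subunit level).
    """

    times: np.ndarray
    length_true: np.ndarray
    length_observed: np.ndarray
    bound_state: np.ndarray
    events: list[BindingEvent] = field(default_factory=list)
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) else 0.0

    def mean_velocity(self) -> float:
        """Empirical time-averaged depolymerization velocity (subunits/s)."""
        if self.duration <= 0:
            return 0.0
        return float(self.length_true[0] - self.length_true[-1]) / self.duration


@dataclass
class IntensityTrace:
    """Single-spot fluorescence intensity vs time."""

    times: np.ndarray
    intensity: np.ndarray
    frame_interval: float
    truth_occupied: np.ndarray | None = None


@dataclass(frozen=True)
class ImagingGeometry:
    """Pixel and length calibration of the rendered movies.

    130 nm pixels for the single-molecule microscope, 143 nm for the
    mf-TIRF instrument; 2.7 nm of filament length per actin subunit.
    """

    pixel_nm: float = 130.0
    subunit_nm: float = 2.7
    actin_label_fraction: float = 0.10
    psf_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pixel_nm, self.subunit_nm, self.psf_sigma_px) <= 0:
            raise ValueError("geometry lengths must be positive")
        if not 0 < self.actin_label_fraction <= 1:
            raise ValueError("actin_label_fraction must lie in (0, 1]")


def _truncated_binomial_counts(rng, n_draws, n_sites, p_site):
    """Draw dye counts from Binomial(n_sites, p) conditioned on >= 1."""
    pmf = np.array(
        [
            math.comb(n_sites, k) * p_site**k * (1 - p_site) ** (n_sites - k)
            for k in range(n_sites + 1)
        ]
    )
    pmf[0] = 0.0
    pmf /= pmf.sum()
    return rng.choice(np.arange(n_sites + 1), size=n_draws, p=pmf)


def simulate_end_dynamics(
    params: KineticParams,
    duration: float,
    seed: int,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    initial_length: int = 500_000,
    length_noise_sd: float = 10.0,
    labeling: LabelingModel | None = None,
) -> FilamentTrajectory:
    """Simulate two-state pointed-end dynamics of one filament.

    The end alternates between unbound intervals (exponential, rate
    ``k_on * c``) and bound intervals (exponential, rate ``k_off``).
    During bound-productive intervals subunits leave as a Poisson
    process at ``v_bound``; otherwise at ``v_unbound``.  Each binding
    event is tagged productive with probability ``productive_fraction``
    and carries ``n_dyes ~ Binomial(6, p_site)`` dyes.

    ``c = 0`` yields a permanently unbound trajectory.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    labeling = labeling or LabelingModel(p_site=0.2223)

    bind_rate = params.k_on * params.c
    events: list[BindingEvent] = []
    # exact alternating-renewal event times
    segments: list[tuple[float, float, float]] = []  # (t0, t1, removal rate)
    t = 0.0
    while t < duration:
        if bind_rate > 0:
            gap = rng.exponential(1.0 / bind_rate)
        else:
            gap = np.inf
        t_bind = min(t + gap, duration)
        if t_bind > t:
            segments.append((t, t_bind, params.v_unbound))
        if t_bind >= duration:
            break
        dwell = rng.exponential(1.0 / params.k_off) if params.k_off > 0 else np.inf
        t_unbind = min(t_bind + dwell, duration)
        productive = bool(rng.random() < params.productive_fraction)
        n_dyes = int(rng.binomial(labeling.n_sites, labeling.p_site))
        events.append(BindingEvent(t_bind, t_unbind, productive, n_dyes))
        rate = params.v_bound if productive else params.v_unbound
        segments.append((t_bind, t_unbind, rate))
        t = t_unbind

    # Poisson subunit removal within each constant-rate segment
    removal_times = []
    for t0, t1, rate in segments:
        if rate <= 0 or t1 <= t0:
            continue
        n = rng.poisson(rate * (t1 - t0))
        if n:
            removal_times.append(rng.uniform(t0, t1, size=n))
    if removal_times:
        removals = np.sort(np.concatenate(removal_times))
    else:
        removals = np.empty(0)

    times = np.arange(0.0, duration, frame_interval)
    n_removed = np.searchsorted(removals, times, side="right")
    length_true = initial_length - n_removed.astype(float)
    length_observed = length_true + rng.normal(0.0, length_noise_sd, size=times.size)

    bound = np.zeros(times.size, dtype=bool)
    for ev in events:
        bound |= (times >= ev.bind_time) & (times < ev.unbind_time)

    return FilamentTrajectory(
        times=times,
        length_true=length_true,
        length_observed=length_observed,
        bound_state=bound,
        events=events,
        frame_interval=frame_interval,
    )


def render_intensity_trace(
    traj: FilamentTrajectory,
    unit_intensity: float = 1.0,
    k_bleach: float = 0.05,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> IntensityTrace:
    """Render the pointed-end spot intensity implied by a trajectory.

    Each dye on the currently bound hexamer contributes
    ``unit_intensity`` and bleaches independently at ``k_bleach`` while
    the hexamer is at the end; hexamers with zero dyes contribute
    nothing (invisible events).  Gaussian camera noise is added per
    frame.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    times = traj.times
    intensity = np.zeros(times.size)
    for ev in traj.events:
        if ev.n_dyes == 0:
            continue
        sel = (times >= ev.bind_time) & (times < ev.unbind_time)
        if not sel.any():
            continue
        if k_bleach > 0:
            bleach_at = ev.bind_time + rng.exponential(1.0 / k_bleach, size=ev.n_dyes)
        else:
            bleach_at = np.full(ev.n_dyes, np.inf)
        surviving = (times[sel][:, None] < bleach_at[None, :]).sum(axis=1)
        intensity[sel] += surviving * unit_intensity
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=times.size)
    return IntensityTrace(
        times=times.copy(),
        intensity=intensity,
        frame_interval=traj.frame_interval,
        truth_occupied=traj.bound_state.copy(),
    )


def simulate_photobleach_traces(
    n: int,
    labeling: LabelingModel,
    unit_intensity: float = 1.0,
    k_bleach: float = 0.2,
    noise_sd: float = 0.2,
    seed: int = 0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> tuple[list[IntensityTrace], np.ndarray]:
    """Simulate photobleaching staircases of surface-immobilized molecules.

    Only visible molecules (>= 1 dye) are returned, so true step counts
    follow the zero-truncated Binomial(n_sites, p_site).  Each trace
    starts at (dyes) x ``unit_intensity``, drops one unit at each
    exponential bleach time, and ends at background.

    Returns the traces and the array of true step counts.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k_bleach <= 0:
        raise ValueError("k_bleach must be positive")
    rng = np.random.default_rng(seed)
    counts = _truncated_binomial_counts(rng, n, labeling.n_sites, labeling.p_site)
    traces = []
    for k in counts:
        bleach_times = np.sort(rng.exponential(1.0 / k_bleach, size=int(k)))
        t_end = bleach_times[-1] + 5.0 / k_bleach / int(k)  # tail of background
        times = np.arange(0.0, t_end, frame_interval)
        surviving = int(k) - np.searchsorted(bleach_times, times, side="right")
        intensity = surviving * unit_intensity
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, size=times.size)
        traces.append(IntensityTrace(times, intensity, frame_interval))
    return traces, counts.astype(int)


def simulate_velocity_dataset(
    concentrations,
    fit: MMFitResult,
    noise_cv: float = 0.15,
    n_per_c: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-filament depolymerization velocities along a saturation curve.

    Velocities are Normal(mm_velocity(c), noise_cv * mm_velocity(c)),
    truncated at zero — per-filament scatter in the concentration
    series experiments is roughly proportional to the mean rate.
    """
    concentrations = np.asarray(list(concentrations), dtype=float)
    if concentrations.size == 0:
        raise ValueError("concentration list must not be empty")
    if n_per_c < 1:
        raise ValueError("n_per_c must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        mu = mm_velocity(float(c), fit)
        v = rng.normal(mu, noise_cv * mu, size=n_per_c) if noise_cv > 0 else np.full(n_per_c, mu)
        v = np.clip(v, 0.0, None)
        for i, vi in enumerate(v):
            rows.append({"concentration_M": float(c), "filament": i, "velocity_subunits_per_s": float(vi)})
    return pd.DataFrame(rows)


def simulate_shrinking_filaments(
    n: int,
    rate: float,
    duration: float,
    frame_interval: float,
    noise_sd: float,
    seed: int = 0,
    initial_length: float = 5000.0,
) -> list[FilamentTrajectory]:
    """Deterministic constant-velocity length ramps with Gaussian noise.

    Emulates the bulk kymograph-velocimetry conditions: each filament
    shrinks at exactly ``rate`` subunits/s and its measured length
    carries i.i.d. Gaussian noise of sd ``noise_sd`` subunits.
    """
    if n < 1 or duration <= 0 or frame_interval <= 0:
        raise ValueError("n, duration and frame_interval must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, frame_interval)
    out = []
    for _ in range(n):
        true = initial_length - rate * times
        obs = true + rng.normal(0.0, noise_sd, size=times.size)
        out.append(
            FilamentTrajectory(
                times=times.copy(),
                length_true=true,
                length_observed=obs,
                bound_state=np.zeros(times.size, dtype=bool),
                events=[],
                frame_interval=frame_interval,
            )
        )
    return out


def render_movie(
    traj: FilamentTrajectory,
    geometry: ImagingGeometry,
    seed: int = 0,
    shape: tuple[int, int] = (24, 96),
    frame_stride: int = 1,
    background: float = 20.0,
    photons_per_subunit: float = 200.0,
    photons_per_dye: float = 400.0,
    shot_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a two-channel image stack from a filament trajectory.

    Channel 1 (actin): the filament is a horizontal line of Gaussian
    spots at the ~10% labeled subunits, anchored at its barbed end on
    the left and shrinking from the pointed end on the right.  Channel 2
    (hexamer): a spot at the pointed-end position whenever a dye-carrying
    hexamer is bound.  Poisson shot noise on both channels.

    Returns (actin_stack, hexamer_stack), each (T, H, W) float arrays.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    y0 = H // 2
    px_per_subunit = geometry.subunit_nm / geometry.pixel_nm
    x_anchor = 4.0  # barbed end, px

    L0 = int(np.ceil(np.max(traj.length_true))) if traj.times.size else 0
    labeled_idx = np.nonzero(rng.random(max(L0, 1)) < geometry.actin_label_fraction)[0]

    frames = traj.times[::frame_stride]
    lengths = traj.length_true[::frame_stride]
    bound = traj.bound_state[::frame_stride]

    max_x = x_anchor + (L0 * px_per_subunit if L0 else 0)
    if max_x > W - 4:
        import warnings

        warnings.warn("trajectory longer than field of view; filament truncated", stacklevel=2)

    sig = geometry.psf_sigma_px
    xgrid = np.arange(W)
    ygrid = np.arange(H)
    ypsf = np.exp(-0.5 * ((ygrid - y0) / sig) ** 2)
    ypsf /= ypsf.sum() if ypsf.sum() else 1.0

    # per-event visibility of the end-bound hexamer
    visible_at = np.zeros(frames.size, dtype=bool)
    for ev in traj.events:
        if ev.n_dyes > 0:
            visible_at |= (frames >= ev.bind_time) & (frames < ev.unbind_time)

    actin = np.empty((frames.size, H, W))
    hexch = np.empty((frames.size, H, W))
    for i in range(frames.size):
        present = labeled_idx[labeled_idx < lengths[i]]
        xs = x_anchor + present * px_per_subunit
        xs = xs[xs < W - 1]
        profile = np.zeros(W)
        if xs.size:
            d = xgrid[None, :] - xs[:, None]
            profile = (photons_per_subunit * np.exp(-0.5 * (d / sig) ** 2)).sum(axis=0)
        img = background + ypsf[:, None] * profile[None, :] * (sig * np.sqrt(2 * np.pi))
        actin[i] = img

        prof2 = np.zeros(W)
        if bound[i] and visible_at[i]:
            x_end = x_anchor + lengths[i] * px_per_subunit
            if x_end < W - 1:
                prof2 = photons_per_dye * np.exp(-0.5 * ((xgrid - x_end) / sig) ** 2)
        hexch[i] = background + ypsf[:, None] * prof2[None, :] * (sig * np.sqrt(2 * np.pi))

    if shot_noise:
        actin = rng.poisson(actin).astype(float)
        hexch = rng.poisson(hexch).astype(float)
    return actin, hexch
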