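"""Closed-form kinetic model of occupancy-gated pointed-end depolymerization.

A hexameric depolymerase (CAP/Srv2) binds the pointed end of a
Cofilin-decorated actin filament with second-order rate constant ``k_on``
and leaves with first-order rate constant ``k_off``.  While a productive
hexamer occupies the end, subunits dissociate fast (``v_bound``); while the
end is free they dissociate slowly (``v_unbound``).  Everything downstream
— the simulator, the trace pipeline, the saturation fit — is tested
against the closed forms collected here.

Units are strict: concentrations in molar, times in seconds, rates in
s^-1 or M^-1 s^-1, velocities in actin subunits per second.  Nanomolar
appears only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "KineticParams",
    "MMFitResult",
    "LabelingModel",
    "ValueWithError",
    "occupancy",
    "mm_velocity",
    "catalytic_efficiency",
    "subunits_per_event",
    "correct_interevent_time",
    "kon_from_mean_gap",
    "koff_from_mean_dwell",
    "predicted_mean_velocity",
    "SUBUNIT_NM",
]

#: Filament length contributed by one actin subunit (nm).
SUBUNIT_NM = 2.7


class ValueWithError(NamedTuple):
    """A scalar estimate with a first-order (delta-method) standard error."""

    value: float
    se: float


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth or estimated rate constants of the two-state end model.

    Parameters
    ----------
    k_on
        Second-order association rate constant of the hexamer for the
        pointed end (M^-1 s^-1).
    k_off
        Dissociation rate constant (s^-1); mean dwell time is ``1/k_off``.
    c
        Free hexamer concentration (molar).
    v_bound
        Depolymerization velocity while the end is occupied by a
        productive hexamer (subunits/s).
    v_unbound
        Velocity while the end is free (subunits/s).
    productive_fraction
        Probability that a binding event is depolymerization-competent.
        Defaults to 1; exposed because a subset of observed binding
        events is not accompanied by rapid depolymerization.
    """

    k_on: float
    k_off: float
    c: float
    v_bound: float = 53.0
    v_unbound: float = 0.43
    productive_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.c < 0:
            raise ValueError("rate constants and concentration must be nonnegative")
        if not 0.0 <= self.productive_fraction <= 1.0:
            raise ValueError("productive_fraction must lie in [0, 1]")

    @property
    def K_A(self) -> float:
        """Association equilibrium constant k_on/k_off (M^-1), computed on demand."""
        if self.k_off <= 0:
            raise ValueError("K_A undefined for k_off <= 0")
        return self.k_on / self.k_off


@dataclass(frozen=True)
class MMFitResult:
    """Saturation-kinetics (Michaelis–Menten) fit of velocity vs concentration."""

    K_M: float
    k_cat: float
    se_K_M: float = 0.0
    se_k_cat: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.K_M <= 0 or self.k_cat <= 0:
            raise ValueError("K_M and k_cat must be positive")
        if self.se_K_M < 0 or self.se_k_cat < 0:
            raise ValueError("standard errors must be nonnegative")


@dataclass(frozen=True)
class LabelingModel:
    """Binomial dye-labeling model of a multimeric molecule.

    Each of ``n_sites`` labeling sites (one cysteine per protomer, six
    protomers per hexamer) carries a dye independently with probability
    ``p_site``; a molecule is observable iff it carries at least one dye.
    """

    p_site: float
    n_sites: int = 6

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_site <= 1.0:
            raise ValueError("p_site must lie in [0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be a positive integer")

    @property
    def f(self) -> float:
        """Fraction of molecules carrying at least one dye."""
        return 1.0 - (1.0 - self.p_site) ** self.n_sites


def occupancy(c: float, k_on: float, k_off: float) -> float:
    """Equilibrium probability that the filament end is occupied.

    occ = c*K_A / (1 + c*K_A) with K_A = k_on/k_off.  Monotone
    nondecreasing in ``c``; 0 at c = 0; -> 1 as c -> infinity.
    """
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    if c < 0 or k_on < 0:
        raise ValueError("c and k_on must be nonnegative")
    cKA = c * k_on / k_off
    return cKA / (1.0 + cKA)


def mm_velocity(c: float, fit: MMFitResult) -> float:
    """Michaelis–Menten velocity k_cat*c/(K_M + c) at hexamer concentration c."""
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    return fit.k_cat * c / (fit.K_M + c)


def catalytic_efficiency(fit: MMFitResult) -> ValueWithError:
    """Catalytic efficiency k_cat/K_M (subunits s^-1 M^-1).

    The standard error is propagated to first order from the fit's
    standard errors, treating k_cat and K_M as uncorrelated:
    rel_err^2 = (se_kcat/kcat)^2 + (se_KM/KM)^2.
    """
    if fit.K_M <= 0:
        raise ValueError("K_M must be positive")
    eff = fit.k_cat / fit.K_M
    rel = math.hypot(fit.se_k_cat / fit.k_cat, fit.se_K_M / fit.K_M)
    return ValueWithError(eff, eff * rel)


def subunits_per_event(
    efficiency: float,
    k_on: float,
    se_efficiency: float = 0.0,
    se_k_on: float = 0.0,
) -> ValueWithError:
    """Mean number of subunits removed per binding event.

    The catalytic efficiency k_cat/K_M equals (subunits removed per
    event) x k_on, so the processivity per event is efficiency/k_on.
    """
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    if efficiency < 0:
        raise ValueError("efficiency must be nonnegative")
    n = efficiency / k_on
    rel = 0.0
    if efficiency > 0:
        rel = math.hypot(se_efficiency / efficiency, se_k_on / k_on)
    return ValueWithError(n, n * rel)


def correct_interevent_time(
    m_prime: float,
    f: float,
    k_off: float,
    min_dwell_s: float = 0.0,
    gap_floor_s: float = 0.0,
) -> float:
    """Correct the observed mean inter-event gap for invisible binding events.

    With incomplete labeling only a fraction ``f`` of hexamers carry a
    dye; dwells of dark hexamers are not seen, so consecutive visible
    dwells are separated by gaps that contain hidden dwells and merged
    true gaps.  For duration-independent thinning the exact inverse is

        m = f * m' - (1 - f) / k_off

    where ``m`` is the true mean gap and ``m'`` the observed one.

    When the dwell detector additionally discards dwells shorter than a
    floor ``min_dwell_s`` (t0), deletion becomes duration-dependent:
    a dwell is visible iff it is labeled AND longer than t0, so the
    visible fraction is f_vis = f * exp(-k_off * t0), and a deleted
    dwell is a mixture of unlabeled dwells (mean 1/k_off) and labeled
    short dwells (mean of the exponential truncated above at t0).  The
    generalized inverse, which reduces exactly to the formula above at
    t0 = 0, is

        m = f_vis * m' - (1 - f_vis) * tau_del

    with tau_del the mean duration of a deleted dwell.

    A finite gap resolution ``gap_floor_s`` (t_g) — two visible dwells
    separated by less than t_g are read as one — removes the shortest
    gaps from the observed sample, so m' additionally overestimates the
    mean resolved separation.  With exponential gaps the observed mean
    separation between visible events, as a function of the true
    binding rate lambda = 1/m, is

        m'(lambda) = [ f_vis e^{-lambda t_g} (t_g + 1/lambda)
                       + (1 - f_vis) * E[S | >=1 hidden event] ]
                     / [ f_vis e^{-lambda t_g} + (1 - f_vis) ]

    (separations containing a hidden dwell are effectively never below
    t_g).  The function inverts this relation for m; at t_g = 0 it
    reduces to the closed forms above, and at f = 1 it reduces to the
    memoryless shift m = m' - t_g.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("f must lie in (0, 1]")
    if m_prime <= 0:
        raise ValueError("m_prime must be positive")
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    if min_dwell_s < 0 or gap_floor_s < 0:
        raise ValueError("detection floors must be nonnegative")

    t0 = min_dwell_s
    surv = math.exp(-k_off * t0)
    f_vis = f * surv
    if t0 > 0.0 and surv < 1.0:
        # mean of Exp(k_off) truncated above at t0
        mean_short = 1.0 / k_off - t0 * surv / (1.0 - surv)
        p_short_given_deleted = f * (1.0 - surv) / (1.0 - f_vis) if f_vis < 1.0 else 0.0
    else:
        mean_short = 0.0
        p_short_given_deleted = 0.0
    if f_vis < 1.0:
        tau_del = (
            p_short_given_deleted * mean_short
            + (1.0 - p_short_given_deleted) / k_off
        )
    else:
        tau_del = 0.0

    tg = gap_floor_s
    if tg == 0.0:
        m = f_vis * m_prime - (1.0 - f_vis) * tau_del if f_vis < 1.0 else m_prime
    else:
        def observed_mean(lam: float) -> float:
            w_vis = f_vis * math.exp(-lam * tg)
            num = w_vis * (tg + 1.0 / lam)
            den = w_vis
            if f_vis < 1.0:
                # >=1 hidden dwell between visible events: E[#gaps]=1+1/f_vis,
                # E[#hidden dwells]=1/f_vis; such separations exceed tg w.p. ~1
                num += (1.0 - f_vis) * ((1.0 + 1.0 / f_vis) / lam + tau_del / f_vis)
                den += 1.0 - f_vis
            if den == 0.0:
                return tg
            return num / den

        # the solution satisfies 1/lam < m', so a bracket of [tiny, 100/m']
        # always contains it; avoid exp underflow at absurd rates
        lo, hi = 1e-12, 100.0 / m_prime
        if observed_mean(hi) > m_prime or observed_mean(lo) < m_prime:
            raise ValueError(
                "observed mean gap is inconsistent with the detection model"
            )
        from scipy.optimize import brentq

        lam = brentq(lambda L: observed_mean(L) - m_prime, lo, hi, xtol=1e-15, rtol=1e-13)
        m = 1.0 / lam
    if m <= 0:
        raise ValueError(
            "corrected mean gap is nonpositive: the labeling correction "
            "exceeds the observed gap (inconsistent inputs)"
        )
    return m


def kon_from_mean_gap(m: float, c: float) -> float:
    """Association rate constant from the true mean inter-event gap: 1/(m*c)."""
    if m <= 0 or c <= 0:
        raise ValueError("mean gap and concentration must be positive")
    return 1.0 / (m * c)


def koff_from_mean_dwell(mean_dwell: float) -> float:
    """Dissociation rate constant from the mean residence time: 1/mean."""
    if mean_dwell <= 0:
        raise ValueError("mean dwell must be positive")
    return 1.0 / mean_dwell


def predicted_mean_velocity(params: KineticParams) -> float:
    """Long-run mean depolymerization velocity of the two-state model.

    The end is occupied a fraction occ of the time and a fraction phi of
    binding events is productive, so the time-averaged velocity is

        occ*phi*v_bound + (1 - occ*phi)*v_unbound.
    """
    if params.c == 0:
        occ = 0.0
    else:
        occ = occupancy(params.c, params.k_on, params.k_off)
    w = occ * params.productive_fraction
    return w * params.v_bound + (1.0 - w) * params.v_unbound
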