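"""Closed-form observation model of the dwell detector.

The single-molecule trace pipeline does not see the true alternating
binding/unbinding process: a binding event is observed only if the
hexamer carries at least one dye (probability f), only while at least
one dye has not photobleached, and only if the visible portion exceeds
the detector's minimum-dwell floor t_d; two visible events closer than
the gap resolution t_g are read as one.  Each mechanism biases the
pooled mean dwell and mean gap.  This module computes the *predicted*
observed moments as functions of the true rates, and inverts them.

Model assumptions: exponential gaps (rate lambda = k_on c), exponential
dwells (rate k_off), dye counts from the zero-truncated
Binomial(n_sites, p_site), independent per-dye bleaching at k_bleach
while bound, sharp detection floors.  All expectations below are exact
under these assumptions except that (i) separations containing a
hidden event are taken to always exceed t_g and (ii) a bleach-ended
event's dark tail is assumed not to merge across t_g — both are
second-order at the study conditions.

With k_bleach = 0, t_g = 0 the gap equation reduces to the classical
labeling correction m = f_vis m' - (1 - f_vis) tau_del.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import LabelingModel

__all__ = ["DetectionModel", "invert_observed_moments"]


@dataclass(frozen=True)
class DetectionModel:
    """Predicted observed dwell/gap moments for given true rates."""

    f: float  # labeled fraction
    min_dwell_s: float  # t_d
    gap_floor_s: float  # t_g
    k_bleach: float = 0.0
    labeling: LabelingModel | None = None  # dye-count distribution given labeled

    def _dye_weights(self) -> tuple[np.ndarray, np.ndarray]:
        lab = self.labeling or LabelingModel(p_site=0.2223)
        n, p = lab.n_sites, lab.p_site
        ks = np.arange(1, n + 1)
        w = np.array([math.comb(n, int(k)) * p**k * (1 - p) ** (n - k) for k in ks])
        return ks, w / w.sum()

    def event_terms(self, k_off: float) -> dict:
        """Per-event expectations for a labeled molecule with d dyes.

        kept_d      P(visible duration > t_d)
        Evkept_d    E[visible duration; kept]
        Etail_d     P(bleach-ended and kept) = k_off * E[dark tail; kept]
        Edel_d      E[true bound time; deleted]
        """
        td, kb = self.min_dwell_s, self.k_bleach
        ks, w = self._dye_weights()
        kept = np.empty(ks.size)
        evk = np.empty(ks.size)
        etail = np.empty(ks.size)
        edel = np.empty(ks.size)
        for i, d in enumerate(ks):
            d = int(d)
            if kb == 0.0:
                sb_td = 1.0
                kept[i] = math.exp(-k_off * td)
                evk[i] = (td + 1.0 / k_off) * kept[i]
                etail[i] = 0.0
            else:
                sb_td = 1.0 - (1.0 - math.exp(-kb * td)) ** d
                kept[i] = math.exp(-k_off * td) * sb_td
                integral = sum(
                    math.comb(d, j)
                    * (-1) ** (j + 1)
                    * math.exp(-(k_off + j * kb) * td)
                    / (k_off + j * kb)
                    for j in range(1, d + 1)
                )
                evk[i] = td * kept[i] + integral
                etail[i] = (
                    d
                    * kb
                    * sum(
                        math.comb(d - 1, j)
                        * (-1) ** j
                        * math.exp(-(k_off + (j + 1) * kb) * td)
                        / (k_off + (j + 1) * kb)
                        for j in range(0, d)
                    )
                )
            # E[T; min(T, B) <= td] = E[T] - E[T; T > td] P(B > td)
            edel[i] = 1.0 / k_off - (td + 1.0 / k_off) * math.exp(-k_off * td) * sb_td
        return {
            "kept": float(np.dot(w, kept)),
            "Evkept": float(np.dot(w, evk)),
            "Etail": float(np.dot(w, etail)),
            "Edel_labeled": float(np.dot(w, edel)),
        }

    def predicted_moments(self, k_off: float, lam: float) -> tuple[float, float]:
        """Predicted (mean observed dwell, mean observed gap).

        lam is the binding rate k_on * c.
        """
        f, tg = self.f, self.gap_floor_s
        t = self.event_terms(k_off)
        q = f * t["kept"]  # P(event produces a kept dwell)
        if q <= 0:
            raise ValueError("no events are observable under this model")
        E_dwell_kept = f * t["Evkept"] / q
        E_tail_per_kept = (1.0 / k_off) * f * t["Etail"] / q
        w_unbind = (q - f * t["Etail"]) / q  # kept dwell ended by unbinding
        # deleted events: unlabeled (full bound time) or labeled-but-short
        E_deleted = (1.0 - f) / k_off + f * t["Edel_labeled"]  # per event, unnormalized

        E_S = E_tail_per_kept + (1.0 / q) / lam + E_deleted / q
        if tg > 0:
            p_merge = w_unbind * q * (1.0 - math.exp(-lam * tg))
            eg = math.exp(-lam * tg)
            E_G_short = 1.0 / lam - tg * eg / (1.0 - eg)
        else:
            p_merge, E_G_short = 0.0, 0.0
        mean_gap = (E_S - p_merge * E_G_short) / (1.0 - p_merge)
        EN = 1.0 / (1.0 - p_merge)
        mean_dwell = EN * E_dwell_kept + (EN - 1.0) * E_G_short
        return mean_dwell, mean_gap


def invert_observed_moments(
    model: DetectionModel,
    mean_dwell_obs: float,
    mean_gap_obs: float,
    k_off0: float | None = None,
    lam0: float | None = None,
) -> tuple[float, float]:
    """Solve the two moment equations for (k_off, lambda).

    Root finding on log-parameters keeps both rates positive; the
    starting point defaults to the floor-subtracted naive estimates.
    """
    td = model.min_dwell_s
    if k_off0 is None:
        k_off0 = 1.0 / max(mean_dwell_obs - td, 0.1 * mean_dwell_obs)
    if lam0 is None:
        lam0 = 1.0 / max(model.f * mean_gap_obs, 1e-6)

    def resid(logx):
        k_off, lam = np.exp(logx)
        d, g = model.predicted_moments(k_off, lam)
        return [math.log(d / mean_dwell_obs), math.log(g / mean_gap_obs)]

    sol = least_squares(resid, np.log([k_off0, lam0]), xtol=1e-14, ftol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError("observed moments are inconsistent with the detection model")
    k_off, lam = np.exp(sol.x)
    return float(k_off), float(lam)
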