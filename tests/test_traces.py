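"""Trace pipeline: extraction, smoothing, dwell calling, rate estimation."""

import math

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from capdep import (
    IntensityTrace,
    KineticParams,
    LabelingModel,
    detect_dwells,
    estimate_koff,
    estimate_kon,
    extract_spot_intensity,
    render_intensity_trace,
    simulate_end_dynamics,
    smooth_trace,
)
from capdep.traces import DwellSet, estimate_binding_kinetics

DT = 0.065


def make_trace(intensity, dt=DT):
    intensity = np.asarray(intensity, dtype=float)
    return IntensityTrace(np.arange(intensity.size) * dt, intensity, dt)


def staircase(runs, pad=40, level=1.0, noise=0.0, rng=None):
    """Trace with given supra-threshold run lengths separated by pads."""
    x = []
    for r in runs:
        x.extend([0.0] * pad)
        x.extend([level] * r)
    x.extend([0.0] * pad)
    x = np.asarray(x)
    if noise and rng is not None:
        x = x + rng.normal(0, noise, x.size)
    return make_trace(x)


class TestSpotExtraction:
    def test_uniform_image_gives_zero(self):
        stack = np.full((3, 40, 40), 11.0)
        tr = extract_spot_intensity(stack, [(20, 20)] * 3, DT)
        assert np.allclose(tr.intensity, 0.0)

    def test_recovers_known_integrated_signal(self):
        yy, xx = np.mgrid[0:40, 0:40]
        spot = 500 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * 1.0**2))
        stack = 30.0 + spot[None]
        tr = extract_spot_intensity(stack, [(20, 20)], DT)
        # a 5x5 box captures ~98.8% of a sigma=1 px Gaussian
        assert tr.intensity[0] == pytest.approx(spot.sum(), rel=0.02)

    def test_edge_position_yields_missing_value(self):
        stack = np.full((2, 40, 40), 5.0)
        with pytest.warns(UserWarning, match="out-of-bounds"):
            tr = extract_spot_intensity(stack, [(1, 1), (20, 20)], DT)
        assert np.isnan(tr.intensity[0]) and np.isfinite(tr.intensity[1])


class TestSmoothing:
    def test_constant_unchanged(self):
        tr = make_trace(np.full(100, 3.3))
        assert np.allclose(smooth_trace(tr).intensity, 3.3)

    def test_linear_ramp_unchanged_in_interior(self):
        tr = make_trace(np.linspace(0, 10, 200))
        sm = smooth_trace(tr)
        assert np.allclose(sm.intensity[6:-6], tr.intensity[6:-6], atol=1e-9)

    def test_window_is_eleven_frames_at_default_rate(self):
        # 0.71 s / 0.065 s = 10.9 -> nearest odd count 11
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(size=5000))
        sm = smooth_trace(tr)
        w = savgol_coeffs(11, 2)
        # white-noise variance is reduced by sum(w^2): direct convolution oracle
        expected = float(np.sum(w**2))
        assert sm.intensity[20:-20].var() == pytest.approx(expected, rel=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(make_trace(np.zeros(5)))


class TestDwellDetection:
    def test_single_plateau_detected_exactly(self):
        tr = staircase([50])
        ds = detect_dwells(tr)
        assert len(ds.dwells) == 1
        s, e = ds.dwells[0]
        assert (e - s) / DT == pytest.approx(50, abs=1)

    def test_min_frames_boundary_strictly_greater_than_four(self):
        # a 4-frame run is rejected; a 5-frame run is kept
        assert len(detect_dwells(staircase([4])).dwells) == 0
        assert len(detect_dwells(staircase([5])).dwells) == 1

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        tr = staircase([30, 12, 50], noise=0.1, rng=rng)
        shifted = make_trace(tr.intensity + 100.0)
        a = detect_dwells(smooth_trace(tr))
        b = detect_dwells(smooth_trace(shifted))
        assert a.dwells == b.dwells

    def test_constant_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ds = detect_dwells(make_trace(np.full(100, 2.0)))
        assert ds.dwells == [] and ds.gaps == []

    def test_noiseless_rendered_trace_matches_truth_within_one_frame(self, study_params):
        traj = simulate_end_dynamics(study_params, 400.0, seed=9)
        tr = render_intensity_trace(traj, k_bleach=0.0, noise_sd=0.0, seed=0)
        ds = detect_dwells(smooth_trace(tr), raw_trace=tr)
        # frame-level truth: occupied frames of dye-carrying events,
        # merged when fewer than two dark frames separate them
        visible = np.zeros(traj.times.size, dtype=bool)
        for ev in traj.events:
            if ev.n_dyes > 0:
                visible |= (traj.times >= ev.bind_time) & (traj.times < ev.unbind_time)
        truth = []
        i = 0
        while i < visible.size:
            if visible[i]:
                j = i
                while j + 1 < visible.size and visible[j + 1]:
                    j += 1
                if truth and i - truth[-1][1] - 1 < 2:
                    truth[-1] = (truth[-1][0], j)
                else:
                    truth.append((i, j))
                i = j + 1
            else:
                i += 1
        truth = [
            (i0, i1)
            for i0, i1 in truth
            if i1 - i0 + 1 > 4 and i0 > 0 and i1 < visible.size - 1
        ]
        assert len(ds.dwells) == len(truth)
        for (s, e), (i0, i1) in zip(ds.dwells, truth):
            assert abs(s - traj.times[i0]) <= DT + 1e-9
            assert abs(e - (traj.times[i1] + DT)) <= DT + 1e-9

    def test_dropout_frames_tolerated_within_dwell(self):
        x = np.zeros(120)
        x[40:70] = 1.0
        x[50:52] = np.nan  # two-frame tracking dropout
        ds = detect_dwells(make_trace(x))
        assert len(ds.dwells) == 1
        s, e = ds.dwells[0]
        assert (e - s) / DT == pytest.approx(30, abs=1)


class TestRateEstimators:
    def test_koff_from_pooled_mean(self):
        ds = DwellSet(dwells=[(0.0, 2.2), (5.0, 7.2)], gaps=[2.8], min_dwell_s=0.0)
        est = estimate_koff([ds], min_dwell_s=0.0)
        assert est.value == pytest.approx(1 / 2.2)
        assert est.se == 0.0  # equal dwells

    def test_koff_sampling_oracle(self):
        rng = np.random.default_rng(12)
        d = rng.exponential(1 / 0.45, 126)
        t = np.concatenate([[0], np.cumsum(d + 1.0)])
        ds = DwellSet(dwells=[(a, a + x) for a, x in zip(t[:-1], d)], gaps=[1.0] * 125)
        est = estimate_koff([ds], min_dwell_s=0.0)
        assert abs(est.value - 0.45) < 3 * 0.45 / math.sqrt(126)

    def test_kon_study_values(self):
        ds = DwellSet(dwells=[(0, 1), (3, 4)], gaps=[2.0365, 2.0365], min_dwell_s=0.0)
        est = estimate_kon([ds], f=0.779, k_off=0.45, c=83e-9, min_dwell_s=0.0, gap_floor_s=0.0)
        assert est.value == pytest.approx(1.1e7, rel=0.001)

    def test_kon_fully_labeled_reduces_to_reciprocal(self):
        ds = DwellSet(dwells=[(0, 1), (3, 4)], gaps=[2.0, 2.0], min_dwell_s=0.0)
        est = estimate_kon([ds], f=1.0, k_off=0.45, c=83e-9, min_dwell_s=0.0, gap_floor_s=0.0)
        assert est.value == pytest.approx(1 / (2.0 * 83e-9), rel=1e-9)

    def test_empty_pools_rejected(self):
        with pytest.raises(ValueError):
            estimate_koff([DwellSet()])
        with pytest.raises(ValueError):
            estimate_kon([DwellSet()], f=0.8, k_off=0.45, c=83e-9)


class TestEstimatorChain:
    """simulate -> render -> detect -> estimate, against generative truth."""

    def _chain(self, noise_sd, f, n_filaments=6, duration=300.0, k_bleach=0.0, seed0=400):
        p = KineticParams(k_on=1.1e7, k_off=0.45, c=83e-9)
        lab = LabelingModel(p_site=1.0 - (1.0 - f) ** (1.0 / 6.0))
        dss = []
        for i in range(n_filaments):
            traj = simulate_end_dynamics(p, duration, seed=seed0 + 2 * i, labeling=lab)
            tr = render_intensity_trace(
                traj, noise_sd=noise_sd, k_bleach=k_bleach, seed=seed0 + 2 * i + 1
            )
            dss.append(detect_dwells(smooth_trace(tr), raw_trace=tr))
        return estimate_binding_kinetics(dss, f=f, c=83e-9, k_bleach=k_bleach, labeling=lab)

    @pytest.mark.parametrize("noise_sd", [0.02, 0.08, 0.15])
    def test_consistency_across_noise_levels(self, noise_sd):
        koff, kon = self._chain(noise_sd, f=1.0)
        assert abs(koff.value - 0.45) < 3 * koff.se
        assert abs(kon.value - 1.1e7) < 3 * kon.se

    def test_partial_labeling_recovered_with_correction(self):
        koff, kon = self._chain(0.15, f=0.779, n_filaments=8, k_bleach=0.05)
        assert abs(kon.value - 1.1e7) < 3 * kon.se
        assert abs(koff.value - 0.45) < 3 * koff.se

    def test_uncorrected_estimate_is_biased_low(self):
        """Skipping the labeling correction underestimates k_on as predicted."""
        from conftest import thinned_gap_sample

        rng = np.random.default_rng(77)
        lam, k_off, f, c = 1.1e7 * 83e-9, 0.45, 0.779, 83e-9
        rel_err = []
        for _ in range(20):
            obs = thinned_gap_sample(rng, 2000, lam, k_off, f)
            naive = 1.0 / (obs.mean() * c)
            rel_err.append(naive / 1.1e7 - 1.0)
        # predicted factor: m/m' = m / (m/f + (1-f)/(f k_off))
        m = 1.0 / lam
        predicted = m / (m / f + (1 - f) / (f * k_off))
        assert np.mean(rel_err) == pytest.approx(predicted - 1.0, abs=0.02)

    def test_corrected_estimate_is_unbiased(self):
        from capdep import correct_interevent_time
        from conftest import thinned_gap_sample

        rng = np.random.default_rng(78)
        lam, k_off, f, c = 1.1e7 * 83e-9, 0.45, 0.779, 83e-9
        est = []
        for _ in range(20):
            obs = thinned_gap_sample(rng, 2000, lam, k_off, f)
            m = correct_interevent_time(float(obs.mean()), f, k_off)
            est.append(1.0 / (m * c))
        se_mean = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(np.mean(est) - 1.1e7) < 3 * se_mean
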