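"""Generative model: event statistics, ergodicity, reproducibility."""

import math

import numpy as np
import pytest

from capdep import (
    ImagingGeometry,
    KineticParams,
    LabelingModel,
    MMFitResult,
    mm_velocity,
    predicted_mean_velocity,
    render_intensity_trace,
    render_movie,
    simulate_end_dynamics,
    simulate_photobleach_traces,
    simulate_shrinking_filaments,
    simulate_velocity_dataset,
)


class TestEndDynamics:
    def test_fixed_seed_is_bit_identical(self, study_params):
        a = simulate_end_dynamics(study_params, 50.0, seed=11)
        b = simulate_end_dynamics(study_params, 50.0, seed=11)
        assert np.array_equal(a.length_true, b.length_true)
        assert np.array_equal(a.length_observed, b.length_observed)
        assert a.events == b.events

    def test_no_binder_control_velocity(self):
        # spontaneous pointed-end depolymerization control: 0.14 subunits/s
        p = KineticParams(k_on=1.1e7, k_off=0.45, c=0.0, v_unbound=0.14)
        traj = simulate_end_dynamics(p, 1e4, seed=5)
        assert len(traj.events) == 0
        n = traj.length_true[0] - traj.length_true[-1]
        se = math.sqrt(max(n, 1.0)) / traj.duration  # Poisson counting error
        assert abs(traj.mean_velocity() - 0.14) < 3 * se

    def test_dwell_and_gap_means(self, study_params):
        traj = simulate_end_dynamics(study_params, 18000.0, seed=6, frame_interval=0.5)
        events = traj.events[:-1]  # last may be truncated at the horizon
        assert len(events) >= 5000
        dwells = np.array([e.dwell for e in events])
        gaps = np.array(
            [b.bind_time - a.unbind_time for a, b in zip(events, events[1:])]
        )
        assert abs(dwells.mean() - 1 / 0.45) < 3 * dwells.std() / math.sqrt(dwells.size)
        true_gap = 1 / (1.1e7 * 83e-9)
        assert abs(gaps.mean() - true_gap) < 3 * gaps.std() / math.sqrt(gaps.size)
        # the pooled mean dwell reproduces the printed 2.2 s
        assert dwells.mean() == pytest.approx(2.2, abs=0.1)

    def test_ergodic_mean_velocity(self, study_params):
        vels = [
            simulate_end_dynamics(
                study_params, 1000.0, seed=20 + i, frame_interval=0.5
            ).mean_velocity()
            for i in range(12)
        ]
        se = np.std(vels, ddof=1) / math.sqrt(len(vels))
        assert abs(np.mean(vels) - predicted_mean_velocity(study_params)) < 3 * se

    def test_unproductive_events_slow_mean_velocity(self):
        half = KineticParams(
            k_on=1.1e7, k_off=0.45, c=83e-9, productive_fraction=0.5
        )
        vels = [
            simulate_end_dynamics(half, 1000.0, seed=50 + i, frame_interval=0.5).mean_velocity()
            for i in range(8)
        ]
        se = np.std(vels, ddof=1) / math.sqrt(len(vels))
        assert abs(np.mean(vels) - predicted_mean_velocity(half)) < 3 * se

    def test_zero_velocities_keep_length_constant(self):
        p = KineticParams(k_on=1.1e7, k_off=0.45, c=83e-9, v_bound=0.0, v_unbound=0.0)
        traj = simulate_end_dynamics(p, 100.0, seed=1)
        assert np.all(traj.length_true == traj.length_true[0])

    def test_length_noise_is_zero_mean_at_configured_sd(self, study_params):
        traj = simulate_end_dynamics(study_params, 500.0, seed=2, length_noise_sd=10.0)
        resid = traj.length_observed - traj.length_true
        n = resid.size
        assert abs(resid.mean()) < 3 * 10.0 / math.sqrt(n)
        assert resid.std() == pytest.approx(10.0, rel=0.05)

    def test_events_interleave_within_duration(self, study_params):
        traj = simulate_end_dynamics(study_params, 200.0, seed=3)
        t = 0.0
        for ev in traj.events:
            assert ev.bind_time >= t
            assert ev.unbind_time > ev.bind_time
            assert ev.unbind_time <= 200.0
            t = ev.unbind_time


class TestIntensityRendering:
    def test_visible_fraction_matches_labeling(self, study_params, labeling):
        n_events = 0
        n_visible = 0
        for i in range(8):
            traj = simulate_end_dynamics(
                study_params, 1000.0, seed=30 + i, frame_interval=0.5, labeling=labeling
            )
            n_events += len(traj.events)
            n_visible += sum(1 for e in traj.events if e.n_dyes > 0)
        assert n_events >= 2000
        f = labeling.f
        se = math.sqrt(f * (1 - f) / n_events)
        assert abs(n_visible / n_events - f) < 3 * se

    def test_noiseless_unbleached_trace_is_truth_staircase(self, study_params):
        traj = simulate_end_dynamics(study_params, 100.0, seed=4)
        tr = render_intensity_trace(traj, unit_intensity=1.0, k_bleach=0.0, noise_sd=0.0, seed=0)
        visible = np.zeros(traj.times.size, dtype=bool)
        for ev in traj.events:
            if ev.n_dyes > 0:
                visible |= (traj.times >= ev.bind_time) & (traj.times < ev.unbind_time)
        assert np.array_equal(tr.intensity > 0, visible)

    def test_zero_dye_events_render_pure_noise(self, study_params):
        lab = LabelingModel(p_site=0.0)
        traj = simulate_end_dynamics(study_params, 100.0, seed=5, labeling=lab)
        tr = render_intensity_trace(traj, noise_sd=0.1, seed=1)
        assert np.all(np.abs(tr.intensity) < 1.0)
        assert abs(tr.intensity.mean()) < 0.05


class TestPhotobleachStaircases:
    def test_full_labeling_gives_six_steps(self):
        lab = LabelingModel(p_site=1.0)
        _, counts = simulate_photobleach_traces(20, lab, seed=0)
        assert np.all(counts == 6)

    def test_dye_counts_follow_truncated_binomial(self, labeling):
        _, counts = simulate_photobleach_traces(6000, labeling, seed=1)
        # exact enumeration oracle over 0..6
        p = labeling.p_site
        pmf = np.array([math.comb(6, k) * p**k * (1 - p) ** (6 - k) for k in range(7)])
        pmf[0] = 0.0
        pmf /= pmf.sum()
        obs = np.bincount(counts, minlength=7) / counts.size
        for k in range(1, 7):
            se = math.sqrt(pmf[k] * (1 - pmf[k]) / counts.size)
            assert abs(obs[k] - pmf[k]) < 4 * se
        # modal dye count is 1 or 2, as for 77.9% labeling
        assert np.argmax(obs) in (1, 2)

    def test_traces_start_at_dye_level_and_end_at_background(self, labeling):
        traces, counts = simulate_photobleach_traces(
            10, labeling, unit_intensity=2.0, noise_sd=0.0, seed=2
        )
        for tr, k in zip(traces, counts):
            assert tr.intensity[0] == pytest.approx(2.0 * k)
            assert tr.intensity[-1] == pytest.approx(0.0)


class TestVelocityDataset:
    def test_noiseless_reproduces_curve_exactly(self, saturation_fit):
        df = simulate_velocity_dataset([50e-9, 150e-9], saturation_fit, noise_cv=0.0, n_per_c=3, seed=0)
        for c, sub in df.groupby("concentration_M"):
            assert sub["velocity_subunits_per_s"].unique() == pytest.approx(
                mm_velocity(c, saturation_fit)
            )

    def test_mean_at_150nM(self, saturation_fit):
        df = simulate_velocity_dataset([150e-9], saturation_fit, noise_cv=0.15, n_per_c=400, seed=3)
        v = df["velocity_subunits_per_s"]
        # closed form: 53*150/(50+150) = 39.75
        assert v.mean() == pytest.approx(39.75, abs=3 * v.std() / math.sqrt(v.size))

    def test_saturation_limit(self, saturation_fit):
        df = simulate_velocity_dataset([1e-4], saturation_fit, noise_cv=0.05, n_per_c=200, seed=4)
        assert df["velocity_subunits_per_s"].mean() == pytest.approx(53.0, rel=0.02)

    def test_empty_concentrations_rejected(self, saturation_fit):
        with pytest.raises(ValueError):
            simulate_velocity_dataset([], saturation_fit, seed=0)


class TestShrinkingFilaments:
    def test_deterministic_ramp(self):
        (traj,) = simulate_shrinking_filaments(1, 43.9, 10.0, 0.5, 0.0, seed=0)
        slopes = np.diff(traj.length_true) / np.diff(traj.times)
        assert np.allclose(slopes, -43.9)

    def test_noise_sd(self):
        trajs = simulate_shrinking_filaments(20, 43.9, 20.0, 0.5, 10.0, seed=1)
        resid = np.concatenate([t.length_observed - t.length_true for t in trajs])
        assert resid.std() == pytest.approx(10.0, rel=0.1)


class TestMovieRendering:
    def test_static_filament_without_noise_is_constant(self):
        (traj,) = simulate_shrinking_filaments(1, 0.0, 5.0, 0.5, 0.0, seed=0, initial_length=2000)
        geo = ImagingGeometry()
        act, hexch = render_movie(traj, geo, seed=1, shape=(16, 64), shot_noise=False)
        assert np.allclose(act, act[0])
        assert np.allclose(hexch, hexch[0])

    def test_empty_trajectory_renders_background_only(self):
        (traj,) = simulate_shrinking_filaments(1, 0.0, 5.0, 0.5, 0.0, seed=0, initial_length=0)
        traj.length_true[:] = 0
        act, _ = render_movie(traj, ImagingGeometry(), seed=1, shape=(16, 64), shot_noise=False, background=7.0)
        assert np.allclose(act, 7.0)

    def test_long_filament_warns_of_truncation(self):
        (traj,) = simulate_shrinking_filaments(1, 0.0, 2.0, 0.5, 0.0, seed=0, initial_length=50000)
        with pytest.warns(UserWarning, match="field of view"):
            render_movie(traj, ImagingGeometry(), seed=1, shape=(16, 64), shot_noise=False)

    def test_end_regression_rate_in_pixels(self):
        # 43.9 subunits/s * 2.7 nm / 130 nm/px = 0.912 px/s
        (traj,) = simulate_shrinking_filaments(1, 43.9, 18.0, 0.5, 0.0, seed=0, initial_length=4000)
        geo = ImagingGeometry(pixel_nm=130.0)
        act, _ = render_movie(traj, geo, seed=1, shape=(16, 120), shot_noise=False)
        row = act[:, 8, :]  # filament axis
        thr = 0.5 * (np.percentile(row, 95) + np.percentile(row, 5))
        ends = np.array([np.nonzero(r > thr)[0][-1] for r in row])
        slope_px_per_s = np.polyfit(traj.times, ends, 1)[0]
        assert -slope_px_per_s == pytest.approx(43.9 * 2.7 / 130.0, rel=0.1)
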