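"""Generator contracts: textures, rendered advection, and model traces.

Noiseless traces must satisfy their defining kinetic/relaxation models
pointwise; rendered sequences must advect only where and when the light
schedule says so.
"""

import numpy as np
import pytest

import optoflow as of
from optoflow.core import Episode, IlluminationSchedule, RectRegion


class TestGenTexture:
    def test_deterministic_for_fixed_seed(self):
        a = of.gen_texture(seed=7, shape=(96, 96))
        b = of.gen_texture(seed=7, shape=(96, 96))
        np.testing.assert_array_equal(a, b)

    def test_intensities_span_unit_interval(self, aligned_texture):
        assert aligned_texture.min() == pytest.approx(0.0)
        assert aligned_texture.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("orientation", [0.0, np.pi / 4, np.pi / 9, -np.pi / 6])
    def test_structure_tensor_recovers_programmed_orientation(self, orientation):
        tex = of.gen_texture(seed=1, shape=(256, 256), orientation=orientation)
        measured = of.orientation_field(tex).modal_angle()
        err = np.mod(measured - orientation + np.pi / 2, np.pi) - np.pi / 2
        assert abs(err) < 0.035  # within 2 degrees

    def test_too_small_correlation_length_rejected(self):
        with pytest.raises(ValueError):
            of.gen_texture(seed=0, correlation_length=1.0, px_size=1.0)


class TestRenderSequence:
    def test_zero_speed_flow_gives_static_frames(self, aligned_texture, always_on):
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=0.0),
                                 always_on, n_frames=4, dt=1.0, seed=0)
        for k in range(1, 4):
            np.testing.assert_array_equal(seq.frames[k], seq.frames[0])

    def test_dark_schedule_gates_advection(self, aligned_texture):
        dark = IlluminationSchedule([Episode(0, 1000, 0.0)])
        noise_sd = 0.01
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=2.0),
                                 dark, n_frames=5, dt=1.0, noise_sd=noise_sd, seed=2)
        diffs = np.abs(np.diff(seq.frames, axis=0)).mean()
        assert diffs <= 3 * noise_sd

    def test_uniform_flow_shifts_correlation_peak_one_pixel(self, aligned_texture, always_on):
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=1.0),
                                 always_on, n_frames=3, dt=1.0, px_size=1.0, seed=0)
        a = seq.frames[0] - seq.frames[0].mean()
        b = seq.frames[1] - seq.frames[1].mean()
        corr = np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b)).real
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        assert peak == (0, 1)  # lag +1 px along x

    def test_advection_confined_to_activated_region(self, aligned_texture):
        region = RectRegion(32, 32, 96, 96)
        sched = IlluminationSchedule([Episode(0, 1000, 1.0, region)])
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=2.0),
                                 sched, n_frames=5, dt=1.0, seed=0)
        delta = np.abs(seq.frames[-1] - seq.frames[0])
        outside = delta.copy()
        outside[32:128, 32:128] = 0
        # a one-pixel skirt at the region boundary is warped; beyond it,
        # frames must be untouched
        outside[31:129, 31:129] = 0
        assert outside.max() < 1e-9
        assert delta[40:120, 40:120].mean() > 0.01

    def test_region_outside_frame_rejected(self, aligned_texture):
        sched = IlluminationSchedule([Episode(0, 10, 1.0, RectRegion(500, 500, 50, 50))])
        with pytest.raises(ValueError):
            of.render_sequence(aligned_texture, of.FlowSpec(), sched, n_frames=3, dt=1.0)

    def test_turbulent_flow_is_divergence_free(self):
        from optoflow.synthgen import _velocity_field

        vx, vy = _velocity_field(of.FlowSpec(kind="turbulent", speed=1.0,
                                             correlation_length=10, seed=2), (96, 96), 1.0)
        div = np.gradient(vx, axis=1) + np.gradient(vy, axis=0)
        assert np.sqrt((div**2).mean()) < 1e-10 * np.sqrt((vx**2 + vy**2).mean())


class TestGenSpeedTrace:
    def test_noiseless_trace_matches_models_pointwise(self):
        sched = IlluminationSchedule([Episode(0, 100, 1.0), Episode(100, 200, 0.0)])
        tr = of.gen_speed_trace(1.2, 8.0, 13.0, sched, dt=1.0)
        t = tr.times
        on = t < 100
        v_on = 1.2 * (1 - np.exp(-t / 8.0))
        v_deact = 1.2 * (1 - np.exp(-100 / 8.0))
        v_off = v_deact * 2.0 / (1.0 + np.exp((t - 100) / 13.0))
        expected = np.where(on, v_on, v_off)
        np.testing.assert_allclose(tr.speed, expected, rtol=1e-10)

    def test_half_rise_at_tau_ln2(self):
        sched = IlluminationSchedule([Episode(0, 1000, 1.0)])
        tau = 20.0
        tr = of.gen_speed_trace(2.0, tau, 10.0, sched, dt=tau * np.log(2.0))
        assert tr.speed[1] == pytest.approx(1.0, rel=1e-12)

    def test_plateau_reaches_vmax(self):
        sched = IlluminationSchedule([Episode(0, 1000, 1.0)])
        tr = of.gen_speed_trace(1.2, 8.0, 13.0, sched, dt=2.0)
        assert tr.speed[-1] == pytest.approx(1.2, rel=1e-10)

    def test_noiseless_roundtrip_recovers_exact_parameters(self):
        sched = IlluminationSchedule([Episode(0, 120, 1.0)])
        tr = of.gen_speed_trace(1.2, 8.0, 13.0, sched, dt=2.0)
        fit = of.fit_activation(tr)
        assert fit.vmax == pytest.approx(1.2, rel=1e-6)
        assert fit.tau_on == pytest.approx(8.0, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        sched = IlluminationSchedule([Episode(0, 10, 1.0)])
        with pytest.raises(ValueError):
            of.gen_speed_trace(0.5, 8.0, 13.0, sched, dark_speed=1.0)
        with pytest.raises(ValueError):
            of.gen_speed_trace(1.0, -1.0, 13.0, sched)

    def test_seeded_noise_reproducible(self):
        sched = IlluminationSchedule([Episode(0, 100, 1.0)])
        a = of.gen_speed_trace(1.0, 8.0, 13.0, sched, noise_sd=0.1, seed=3)
        b = of.gen_speed_trace(1.0, 8.0, 13.0, sched, noise_sd=0.1, seed=3)
        np.testing.assert_array_equal(a.speed, b.speed)


class TestGenAngleTrace:
    def test_dark_trace_is_exact_relaxation_model(self):
        sched = IlluminationSchedule([Episode(0, 300, 0.0)])
        tr = of.gen_angle_trace(0.002, 17.0, 17.0, 0.2, sched, dt=2.0)
        t = tr.times
        expected = np.exp(-t / 17.0) * 0.002 * t + 0.2 * np.exp(-t / 17.0)
        np.testing.assert_allclose(tr.angle, expected, rtol=1e-10)

    def test_value_at_deactivation_is_C(self):
        sched = IlluminationSchedule([Episode(0, 300, 0.0)])
        tr = of.gen_angle_trace(0.002, 17.0, 17.0, 0.25, sched, dt=2.0)
        assert tr.angle[0] == pytest.approx(0.25)

    def test_long_time_decay_to_zero(self):
        sched = IlluminationSchedule([Episode(0, 2000, 0.0)])
        tr = of.gen_angle_trace(0.002, 17.0, 17.0, 0.2, sched, dt=50.0)
        assert tr.angle[-1] < 1e-6

    def test_linear_growth_during_activation(self):
        sched = IlluminationSchedule([Episode(0, 300, 1.0)])
        tr = of.gen_angle_trace(0.002, 17.0, 17.0, 0.0, sched, dt=10.0)
        assert tr.angle[-1] == pytest.approx(0.6, rel=1e-10)

    def test_continuity_across_deactivation(self):
        sched = IlluminationSchedule([Episode(0, 300, 1.0), Episode(300, 600, 0.0)])
        tr = of.gen_angle_trace(0.002, 17.0, 17.0, 0.0, sched, dt=1.0)
        i = np.searchsorted(tr.times, 300.0)
        assert abs(tr.angle[i] - tr.angle[i - 1]) < 0.005


class TestGenThresholdDataset:
    def test_noiseless_dataset_satisfies_scaling_exactly(self):
        geoms = [(L, L, 100.0) for L in (50, 100, 200, 400)]
        df = of.gen_threshold_dataset(1.17, geoms, rel_noise=0.0, seed=0)
        expected = 1.17 * of.alpha_eff(df["L_um"], df["W_um"], df["H_um"])
        np.testing.assert_allclose(df["I_threshold"], expected, rtol=1e-12)

    def test_long_region_thresholds_independent_of_L(self):
        # all geometries on the saturated branch: 1/L^2 < 1/W^2 + 1/H^2
        geoms = [(L, 100.0, 100.0) for L in (200, 300, 500, 800)]
        df = of.gen_threshold_dataset(2.0, geoms, rel_noise=0.0, seed=0)
        assert df["I_threshold"].nunique() == 1

    def test_cube_value_matches_hand_evaluation(self):
        df = of.gen_threshold_dataset(1.17, [(100.0, 100.0, 100.0)], rel_noise=0.0, seed=0)
        assert df["I_threshold"].iloc[0] == pytest.approx(1.17 * 4 * np.pi**2 * 2e-4)

    def test_roundtrip_recovers_coefficient(self):
        geoms = [(L, L, 100.0) for L in (50, 100, 150, 300)]
        df = of.gen_threshold_dataset(1.17, geoms, rel_noise=0.0, seed=0)
        assert of.fit_activity_coefficient(df).a == pytest.approx(1.17, rel=1e-6)

    def test_non_positive_dimension_rejected(self):
        with pytest.raises(ValueError):
            of.gen_threshold_dataset(1.0, [(50.0, -1.0, 100.0)])
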