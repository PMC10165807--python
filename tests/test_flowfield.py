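"""PIV correctness: constructed shifts, sub-pixel accuracy, outlier
replacement, speed statistics and field correlation."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift

import optoflow as of
from optoflow.core import Episode, IlluminationSchedule


def _shift(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Exact periodic sub-pixel shift via the Fourier shift theorem."""
    return np.fft.ifft2(fourier_shift(np.fft.fft2(frame), (dy, dx))).real


def _uniform_field(vx=0.0, vy=0.0, n=10, rng=None, noise=0.0):
    x = np.arange(n, dtype=float)
    vx_a = np.full((n, n), vx)
    vy_a = np.full((n, n), vy)
    if rng is not None:
        vx_a = vx_a + rng.normal(0, noise, (n, n))
        vy_a = vy_a + rng.normal(0, noise, (n, n))
    return of.VelocityField(x, x, vx_a, vy_a, np.ones((n, n), bool))


class TestPivPair:
    def test_identity_pair_gives_zero_vectors(self, aligned_texture):
        f = of.piv_pair(aligned_texture, aligned_texture, dt=1.0, px_size=1.0)
        assert np.all(f.valid)
        np.testing.assert_allclose(f.vx, 0.0, atol=1e-9)
        np.testing.assert_allclose(f.vy, 0.0, atol=1e-9)

    @pytest.mark.parametrize("dy,dx", [(0.0, 3.0), (3.0, 0.0), (0.0, 0.5), (0.5, 0.0)])
    def test_constructed_shift_recovered(self, aligned_texture, dy, dx):
        b = _shift(aligned_texture, dy, dx)
        f = of.filter_outliers(of.piv_pair(aligned_texture, b, dt=1.0, px_size=1.0))
        assert abs(f.vx[f.valid].mean() - dx) <= 0.1
        assert abs(f.vy[f.valid].mean() - dy) <= 0.1

    def test_units_scale_with_dt_and_px_size(self, aligned_texture):
        b = _shift(aligned_texture, 0.0, 2.0)
        f = of.piv_pair(aligned_texture, b, dt=4.0, px_size=0.5)
        assert f.vx[f.valid].mean() == pytest.approx(2.0 * 0.5 / 4.0, abs=0.02)

    def test_translation_equivariance(self, aligned_texture):
        """Adding a constant extra shift to frame_b adds it to every vector."""
        b1 = _shift(aligned_texture, 0.0, 1.0)
        b2 = _shift(aligned_texture, 0.0, 3.0)
        f1 = of.filter_outliers(of.piv_pair(aligned_texture, b1, dt=1.0, px_size=1.0))
        f2 = of.filter_outliers(of.piv_pair(aligned_texture, b2, dt=1.0, px_size=1.0))
        assert abs((f2.vx[f2.valid].mean() - f1.vx[f1.valid].mean()) - 2.0) <= 0.1

    def test_rotation_consistency(self, aligned_texture):
        """Rotating both frames 90 deg maps (vx, vy) -> (vy, -vx)."""
        b = np.roll(aligned_texture, 3, axis=1)
        f = of.piv_pair(aligned_texture, b, dt=1.0, px_size=1.0)
        fr = of.piv_pair(np.rot90(aligned_texture), np.rot90(b), dt=1.0, px_size=1.0)
        assert fr.vx[fr.valid].mean() == pytest.approx(f.vy[f.valid].mean(), abs=0.1)
        assert fr.vy[fr.valid].mean() == pytest.approx(-f.vx[f.valid].mean(), abs=0.1)

    def test_time_reversed_pair_negates_vectors(self, aligned_texture):
        b = _shift(aligned_texture, 0.0, 2.0)
        fwd = of.piv_pair(aligned_texture, b, dt=1.0, px_size=1.0)
        rev = of.piv_pair(b, aligned_texture, dt=1.0, px_size=1.0)
        assert rev.vx[rev.valid].mean() == pytest.approx(-fwd.vx[fwd.valid].mean(), abs=0.05)

    def test_frames_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            of.piv_pair(np.zeros((16, 16)), np.zeros((16, 16)), dt=1.0, px_size=1.0,
                        window_px=32)

    def test_flat_window_flagged_invalid(self, aligned_texture):
        a = aligned_texture.copy()
        a[:32, :32] = 0.5
        b = a.copy()
        f = of.piv_pair(a, b, dt=1.0, px_size=1.0)
        assert not f.valid[0, 0]
        assert f.valid_fraction < 1.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            of.piv_pair(np.zeros((64, 64)), np.zeros((64, 32)), dt=1.0, px_size=1.0)


class TestFilterOutliers:
    def test_single_spike_replaced_by_neighbour_median(self):
        f = _uniform_field(vx=1.0)
        f.vx[4, 4] = 10.0
        out = of.filter_outliers(f, threshold=2.0)
        assert out.vx[4, 4] == pytest.approx(1.0)
        assert out.replaced[4, 4]

    def test_uniform_field_unchanged(self):
        f = _uniform_field(vx=1.0, vy=-2.0)
        out = of.filter_outliers(f)
        np.testing.assert_array_equal(out.vx, f.vx)
        np.testing.assert_array_equal(out.vy, f.vy)
        assert not out.replaced.any()

    def test_iid_noise_replacement_rate_small(self):
        # noise at the ~0.1 um/s scale of PIV residuals, where the
        # epsilon-regularized median test is calibrated
        rng = np.random.default_rng(11)
        f = _uniform_field(vx=0.0, rng=rng, noise=0.1, n=20)
        out = of.filter_outliers(f, threshold=2.0)
        assert out.replaced.mean() <= 0.10

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            of.filter_outliers(_uniform_field(), threshold=0.0)


class TestMeanSpeed:
    def test_zero_field(self):
        assert of.mean_speed(_uniform_field()) == 0.0

    def test_three_four_five_triangle(self):
        assert of.mean_speed(_uniform_field(vx=3.0, vy=4.0)) == pytest.approx(5.0)

    def test_mixed_unit_vectors_average_magnitudes(self):
        f = _uniform_field()
        f.vx[: 5] = 1.0
        f.vy[5:] = 1.0
        assert of.mean_speed(f) == pytest.approx(1.0)

    def test_no_valid_nodes_errors(self):
        f = _uniform_field()
        f.valid[:] = False
        with pytest.raises(ValueError):
            of.mean_speed(f)

    def test_invalid_nodes_excluded_not_zero_filled(self):
        f = _uniform_field(vx=2.0)
        f.vx[0, 0] = 0.0
        f.valid[0, 0] = False
        assert of.mean_speed(f) == pytest.approx(2.0)


class TestSpeedTrace:
    def test_static_sequence_gives_zero_speeds(self, aligned_texture):
        seq = of.ImageSequence(np.stack([aligned_texture] * 3), 1.0, 1.0)
        tr = of.speed_trace(seq)
        np.testing.assert_allclose(tr.speed, 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.times, [0.5, 1.5])

    def test_programmed_uniform_speed_recovered_within_5_percent(
        self, aligned_texture, always_on
    ):
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=2.0),
                                 always_on, n_frames=12, dt=1.0, seed=1)
        tr = of.speed_trace(seq, always_on)
        assert tr.speed.mean() == pytest.approx(2.0, rel=0.05)

    def test_on_episodes_faster_than_off_episodes(self, aligned_texture):
        sched = IlluminationSchedule([Episode(0, 5, 1.0), Episode(5, 12, 0.0)])
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=1.5),
                                 sched, n_frames=12, dt=1.0, noise_sd=0.002, seed=4)
        tr = of.speed_trace(seq, sched)
        on = tr.intensity > 0
        assert tr.speed[on].mean() > 3 * tr.speed[~on].mean()

    def test_time_reversed_sequence_same_speeds(self, aligned_texture, always_on):
        seq = of.render_sequence(aligned_texture, of.FlowSpec(kind="uniform", speed=1.0),
                                 always_on, n_frames=6, dt=1.0, seed=1)
        rev = of.ImageSequence(seq.frames[::-1].copy(), 1.0, 1.0)
        tr = of.speed_trace(seq)
        tr_rev = of.speed_trace(rev)
        np.testing.assert_allclose(tr.speed, tr_rev.speed[::-1], rtol=0.05, atol=0.01)


class TestFieldCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        f = _uniform_field(rng=rng, noise=1.0)
        assert of.field_correlation(f, f) == pytest.approx(1.0)

    def test_negated_field_is_minus_one(self):
        rng = np.random.default_rng(0)
        f = _uniform_field(rng=rng, noise=1.0)
        g = of.VelocityField(f.x_um, f.y_um, -f.vx, -f.vy, f.valid)
        assert of.field_correlation(f, g) == pytest.approx(-1.0)

    def test_independent_fields_weakly_correlated(self):
        rng = np.random.default_rng(1)
        f = _uniform_field(rng=rng, noise=1.0, n=12)  # 144 nodes >= 100
        g = _uniform_field(rng=rng, noise=1.0, n=12)
        assert abs(of.field_correlation(f, g)) < 0.2

    def test_grid_mismatch_rejected(self):
        f = _uniform_field(n=10)
        g = _uniform_field(n=12)
        with pytest.raises(ValueError):
            of.field_correlation(f, g)
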