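import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stepgait.preprocessing import (
    lowpass_filter,
    magnitude_vector,
    preprocess_step,
    pseudo_gaussian_smooth,
    select_forward_direction,
)

from conftest import make_segment


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestLowpassFilter:
    def test_dc_passes_unchanged(self):
        out = lowpass_filter(np.full(100, 3.7), 100.0, 10.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-6)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(200) / 100.0
        x = np.sin(2 * np.pi * 20 * t)
        out = lowpass_filter(x, 100.0, 10.0)
        assert rms(out) < 0.10 * rms(x)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(200) / 100.0
        x = np.sin(2 * np.pi * 1 * t)
        out = lowpass_filter(x, 100.0, 10.0)
        assert abs(rms(out) - rms(x)) < 0.05 * rms(x)

    def test_zero_phase_keeps_peak_position(self):
        t = np.arange(100) / 100.0
        x = np.exp(-0.5 * ((t - 0.5) / 0.08) ** 2)
        out = lowpass_filter(x, 100.0, 10.0)
        assert abs(int(np.argmax(out)) - int(np.argmax(x))) <= 1

    @pytest.mark.parametrize("cutoff", [0.0, -1.0, 50.0, 60.0])
    def test_cutoff_out_of_range_rejected(self, cutoff):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter(np.zeros(50), 100.0, cutoff)


class TestPseudoGaussianSmooth:
    def test_constant_series_unchanged(self):
        out = pseudo_gaussian_smooth(np.full(30, 2.5), width=5)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_impulse_response_matches_explicit_kernel(self):
        # oracle: convolve the unit impulse with the explicit normalized kernel
        width = 5
        x = np.zeros(21)
        x[10] = 1.0
        out = pseudo_gaussian_smooth(x, width)
        offsets = np.arange(-2, 3)
        kernel = np.exp(-0.5 * (offsets / (width / 4.0)) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[8:13], kernel, atol=1e-12)
        assert np.argmax(out) == 10
        # symmetric bell shape around the impulse
        np.testing.assert_allclose(out[8:13], out[12:7:-1], atol=1e-12)

    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).standard_normal(20)
        np.testing.assert_array_equal(pseudo_gaussian_smooth(x, 1), x)

    def test_width_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="width"):
            pseudo_gaussian_smooth(np.zeros(4), 5)


class TestForwardDirectionSelection:
    def test_dominant_axis_wins(self):
        square = np.tile([1.0, -1.0], 10)
        triad = np.stack([np.zeros(20), square, np.zeros(20)])
        axis, series = select_forward_direction(triad)
        assert axis == 1
        np.testing.assert_array_equal(series, square)

    def test_tie_breaks_to_lowest_index(self):
        same = np.sin(np.linspace(0, 6, 30))
        axis, _ = select_forward_direction(np.stack([same, same, same]))
        assert axis == 0

    def test_amplitude_ordering_matches_power_oracle(self):
        t = np.linspace(0, 1, 50)
        triad = np.stack([0.5 * np.sin(7 * t), 1.0 * np.sin(7 * t), 2.0 * np.sin(7 * t)])
        powers = [np.mean((a - a.mean()) ** 2) for a in triad]
        axis, _ = select_forward_direction(triad)
        assert axis == int(np.argmax(powers)) == 2

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(3)
        triad = rng.standard_normal((3, 40))
        axis_before, _ = select_forward_direction(triad)
        shifted = triad.copy()
        shifted[0] += 100.0  # huge DC offset must not attract selection
        axis_after, _ = select_forward_direction(shifted)
        assert axis_before == axis_after


class TestMagnitudeVector:
    def test_three_four_five(self):
        triad = np.stack([np.full(10, 3.0), np.full(10, 4.0), np.zeros(10)])
        np.testing.assert_allclose(magnitude_vector(triad), 5.0)

    def test_zero_triad(self):
        np.testing.assert_array_equal(magnitude_vector(np.zeros((3, 8))), np.zeros(8))

    def test_matches_per_sample_norm_oracle(self):
        rng = np.random.default_rng(1)
        triad = rng.standard_normal((3, 25))
        expected = np.array([np.linalg.norm(triad[:, i]) for i in range(25)])
        np.testing.assert_allclose(magnitude_vector(triad), expected, atol=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        triad = rng.standard_normal((3, 30))
        for seed in range(3):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            np.testing.assert_allclose(
                magnitude_vector(rot @ triad), magnitude_vector(triad), atol=1e-9
            )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            magnitude_vector(np.zeros((2, 10)))


class TestPreprocessStep:
    def test_all_series_keep_source_length(self, segment):
        step = preprocess_step(segment)
        for name in ("acc_fd", "acc_xyz", "gyr_fd", "gyr_xyz"):
            assert len(getattr(step, name)) == len(segment)

    def test_magnitudes_non_negative(self, segment):
        step = preprocess_step(segment)
        assert (step.acc_xyz >= 0).all() and (step.gyr_xyz >= 0).all()

    def test_dominant_axis_selected(self):
        seg = make_segment(60)
        boosted = seg.with_series({"acc_y": seg.acc_y + 5 * np.sin(np.arange(60) / 3)})
        step = preprocess_step(boosted)
        assert step.fd_axis_acc == 1

    def test_constant_segment_magnitude(self):
        n = 30
        seg = make_segment(n).with_series(
            {"acc_x": np.full(n, 1.0), "acc_y": np.full(n, 2.0), "acc_z": np.full(n, 2.0)}
        )
        step = preprocess_step(seg)
        np.testing.assert_allclose(step.acc_xyz, 3.0, atol=1e-5)

    def test_high_frequency_noise_removed(self):
        n = 120
        seg = make_segment(n, seed=4)
        t = np.arange(n) / 100.0
        noisy = seg.acc_x + 0.8 * np.sin(2 * np.pi * 30 * t)
        seg = seg.with_series({"acc_x": noisy})

        def band_power_above(x, fs=100.0, f0=15.0):
            freqs = np.fft.rfftfreq(len(x), 1 / fs)
            spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
            return spec[freqs > f0].sum()

        step = preprocess_step(seg, cutoff=10.0)
        raw_power = band_power_above(noisy)
        for series in (step.acc_fd, step.acc_xyz):
            assert band_power_above(series) < 0.05 * raw_power
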