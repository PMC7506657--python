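import numpy as np
import pytest
from scipy import stats

from stepgait.augmentation import (
    ALL_TECHNIQUES,
    AugmentationConfig,
    AugmentationTechnique,
    DMF_TECHNIQUES,
    DMM_TECHNIQUES,
    Treatment,
    apply_treatment,
    augment_step,
    balance_by_augmentation,
    cut_signals,
    downsample_signals,
    draw_factor,
    hann_window_length,
    jitter_signal,
    scale_signal,
    smooth_signal,
    subsample_to_minority,
    synthetic_requirements,
)
from stepgait.signal_model import GaitActivity, SENSOR_COLUMNS, StepDataset, class_histogram

from conftest import make_segment

CONFIG = AugmentationConfig()


def six_series(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return {name: rng.standard_normal(n) for name in SENSOR_COLUMNS}


class TestFactorDrawing:
    def test_factors_match_gaussian_1_02(self):
        rng = np.random.default_rng(0)
        draws = np.array([draw_factor(rng, CONFIG) for _ in range(10_000)])
        assert abs(draws.mean() - 1.0) < 0.01
        assert abs(draws.std() - 0.2) < 0.01
        # distributional check against N(1, 0.2)
        _, p = stats.kstest(draws, "norm", args=(1.0, 0.2))
        assert p > 0.01


class TestScaling:
    def test_factor_one_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(scale_signal(x, 1.0), x)

    def test_elementwise_multiplication(self):
        np.testing.assert_array_equal(scale_signal(np.array([1.0, 2.0, 3.0]), 2.0),
                                      [2.0, 4.0, 6.0])


class TestJittering:
    def test_zero_sd_is_identity(self):
        x = np.linspace(-1, 1, 50)
        out = jitter_signal(x, np.random.default_rng(0), AugmentationConfig(factor_sd=0.0))
        np.testing.assert_array_equal(out, x)

    def test_elementwise_ratios_match_gaussian(self):
        x = np.full(10_000, 2.0)  # strictly positive so ratios are well defined
        out = jitter_signal(x, np.random.default_rng(1), CONFIG)
        ratios = out / x
        assert abs(ratios.mean() - 1.0) < 0.01
        assert abs(ratios.std() - 0.2) < 0.01

    def test_zero_series_stays_zero(self):
        out = jitter_signal(np.zeros(30), np.random.default_rng(2), CONFIG)
        np.testing.assert_array_equal(out, np.zeros(30))


class TestSmoothing:
    def test_window_length_rule(self):
        # a 100-sample step with unit factor gets a 10-sample Hann window
        assert hann_window_length(100, CONFIG, 1.0) == 10
        assert hann_window_length(100, CONFIG, 2.0) == 20
        assert hann_window_length(5, CONFIG, 1.0) == 1  # clipped below

    def test_constant_series_unchanged(self):
        x = np.full(100, 1.5)
        out = smooth_signal(x, np.random.default_rng(0), CONFIG)
        np.testing.assert_allclose(out, 1.5, atol=1e-12)

    def test_high_frequency_attenuated(self):
        t = np.arange(100) / 100.0
        x = np.sin(2 * np.pi * 25 * t)
        out = smooth_signal(x, np.random.default_rng(0), CONFIG, factor=1.0)
        assert np.sqrt(np.mean(out**2)) < np.sqrt(np.mean(x**2))

    def test_length_preserved(self):
        x = np.random.default_rng(3).standard_normal(73)
        out = smooth_signal(x, np.random.default_rng(0), CONFIG)
        assert len(out) == 73


class TestDownsampling:
    def test_outputs_are_subsequences(self):
        signals = six_series(100)
        out = downsample_signals(signals, np.random.default_rng(5), CONFIG)
        lengths = {len(v) for v in out.values()}
        assert len(lengths) == 1
        n_out = lengths.pop()
        assert 4 <= n_out < 100
        for name in SENSOR_COLUMNS:
            # every output value exists in the input, in order
            it = iter(signals[name])
            assert all(any(np.isclose(v, x) for x in it) for v in out[name])

    def test_same_indices_for_all_axes(self):
        signals = {name: np.arange(100, dtype=float) + i * 1000
                   for i, name in enumerate(SENSOR_COLUMNS)}
        out = downsample_signals(signals, np.random.default_rng(7), CONFIG)
        base = out["acc_x"]
        for i, name in enumerate(SENSOR_COLUMNS):
            np.testing.assert_array_equal(out[name] - i * 1000, base)

    def test_min_max_within_input_range(self):
        signals = six_series(80, seed=2)
        out = downsample_signals(signals, np.random.default_rng(9), CONFIG)
        for name in SENSOR_COLUMNS:
            assert out[name].min() >= signals[name].min()
            assert out[name].max() <= signals[name].max()


class TestCutting:
    def test_explicit_factor_removes_expected_frames(self):
        signals = {name: np.arange(100, dtype=float) for name in SENSOR_COLUMNS}
        out = cut_signals(signals, np.random.default_rng(0), CONFIG, factor=1.0)
        # n_remove = 10: 5 from the start, 5 from the end
        assert len(out["acc_x"]) == 90
        np.testing.assert_array_equal(out["acc_x"], np.arange(5.0, 95.0))

    def test_odd_removal_takes_extra_from_start(self):
        signals = {name: np.arange(90, dtype=float) for name in SENSOR_COLUMNS}
        out = cut_signals(signals, np.random.default_rng(0), CONFIG, factor=1.0)
        # n_remove = 9: 5 from the start, 4 from the end
        np.testing.assert_array_equal(out["acc_x"], np.arange(5.0, 86.0))

    def test_output_contiguous_and_shared(self):
        signals = six_series(64, seed=4)
        out = cut_signals(signals, np.random.default_rng(11), CONFIG)
        n_out = len(out["acc_x"])
        # locate the kept block on one axis, check the same block on all axes
        full = signals["acc_x"]
        starts = [s for s in range(64 - n_out + 1)
                  if np.array_equal(full[s : s + n_out], out["acc_x"])]
        assert starts
        s = starts[0]
        for name in SENSOR_COLUMNS:
            np.testing.assert_array_equal(out[name], signals[name][s : s + n_out])


class TestAugmentStep:
    @pytest.mark.parametrize("technique", ALL_TECHNIQUES)
    def test_label_preserved_and_provenance_synthetic(self, technique):
        seg = make_segment(60, GaitActivity.UP_STAIRS)
        out = augment_step(seg, technique, np.random.default_rng(0), CONFIG)
        assert out.label is GaitActivity.UP_STAIRS
        assert out.provenance == "synthetic"

    @pytest.mark.parametrize("technique", DMM_TECHNIQUES)
    def test_dmm_preserves_length(self, technique):
        seg = make_segment(57)
        out = augment_step(seg, technique, np.random.default_rng(1), CONFIG)
        assert len(out) == 57

    @pytest.mark.parametrize("technique", DMF_TECHNIQUES)
    def test_dmf_values_subset_of_input(self, technique):
        seg = make_segment(60)
        out = augment_step(seg, technique, np.random.default_rng(2), CONFIG)
        assert len(out) < 60
        for name in SENSOR_COLUMNS:
            in_values = set(np.round(getattr(seg, name), 12))
            assert all(round(v, 12) in in_values for v in getattr(out, name))

    def test_deterministic_under_seed(self):
        seg = make_segment(60)
        a = augment_step(seg, AugmentationTechnique.JITTERING, np.random.default_rng(5), CONFIG)
        b = augment_step(seg, AugmentationTechnique.JITTERING, np.random.default_rng(5), CONFIG)
        np.testing.assert_array_equal(a.acc_x, b.acc_x)


def dataset_with_counts(counts):
    segs = []
    for activity, count in counts.items():
        for i in range(count):
            segs.append(make_segment(40 + (i % 5), activity, seed=i, provenance="real"))
    return StepDataset(segs)


class TestBalancer:
    def test_two_class_balancing(self):
        ds = dataset_with_counts({GaitActivity.LEVEL: 5, GaitActivity.UP_STAIRS: 3})
        out = balance_by_augmentation(ds, np.random.default_rng(0))
        hist = class_histogram(out)
        assert hist[GaitActivity.LEVEL] == 5
        assert hist[GaitActivity.UP_STAIRS] == 5
        synthetic = [s for s in out if s.provenance == "synthetic"]
        assert len(synthetic) == 2

    def test_originals_retained_unmodified(self):
        ds = dataset_with_counts({GaitActivity.LEVEL: 4, GaitActivity.DOWN_STAIRS: 2})
        out = balance_by_augmentation(ds, np.random.default_rng(1))
        assert out.segments[: len(ds)] == ds.segments

    def test_balanced_input_unchanged(self):
        ds = dataset_with_counts({a: 3 for a in GaitActivity})
        out = balance_by_augmentation(ds, np.random.default_rng(2))
        assert len(out) == len(ds)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            balance_by_augmentation(StepDataset([]), np.random.default_rng(0))

    def test_synthetic_requirements_arithmetic(self):
        ds = dataset_with_counts(
            {GaitActivity.DOWN_INCLINE: 21, GaitActivity.UP_INCLINE: 19,
             GaitActivity.LEVEL: 99, GaitActivity.DOWN_STAIRS: 9, GaitActivity.UP_STAIRS: 10}
        )
        req = synthetic_requirements(ds)
        assert [req[a] for a in GaitActivity] == [78, 80, 0, 90, 89]


class TestSubsampleAndTreatments:
    def test_subsample_to_minority_counts(self):
        ds = dataset_with_counts(
            {GaitActivity.LEVEL: 12, GaitActivity.UP_STAIRS: 5, GaitActivity.DOWN_STAIRS: 7}
        )
        out = subsample_to_minority(ds, np.random.default_rng(0))
        hist = class_histogram(out)
        assert hist[GaitActivity.LEVEL] == 5
        assert hist[GaitActivity.UP_STAIRS] == 5
        assert hist[GaitActivity.DOWN_STAIRS] == 5

    def test_subsample_without_replacement(self):
        ds = dataset_with_counts({GaitActivity.LEVEL: 10, GaitActivity.UP_STAIRS: 6})
        out = subsample_to_minority(ds, np.random.default_rng(1))
        ids = [id(s) for s in out]
        assert len(ids) == len(set(ids))

    def test_subsample_deterministic(self):
        ds = dataset_with_counts({GaitActivity.LEVEL: 10, GaitActivity.UP_STAIRS: 6})
        a = subsample_to_minority(ds, np.random.default_rng(7))
        b = subsample_to_minority(ds, np.random.default_rng(7))
        assert [id(x) for x in a] == [id(x) for x in b]

    def test_unbalanced_treatment_is_identity(self):
        ds = dataset_with_counts({GaitActivity.LEVEL: 6, GaitActivity.UP_STAIRS: 5})
        out = apply_treatment(ds, Treatment.UNBALANCED, np.random.default_rng(0))
        assert out is ds
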