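"""Unit and property tests for the time-series feature catalog."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import synaptodyn as sd
from synaptodyn._stats import DegenerateSeriesError, robust_sigmoid_columns
from synaptodyn.features import (
    OutlierTimingParams,
    compute_feature_matrix,
    default_catalog,
    dfa_scaling,
    group_average,
    local_global_std,
    loglog_fit,
    normalize_features,
    outlier_timing_mrmd,
    statav,
    zscore,
)

from conftest import make_feature_matrix

series_strategy = hnp.arrays(
    float,
    st.integers(30, 120),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
).filter(lambda x: np.std(x, ddof=1) > 1e-3)


class TestZscore:
    def test_symmetric_example(self):
        assert np.allclose(zscore(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_constant_raises(self):
        with pytest.raises(DegenerateSeriesError):
            zscore(np.array([5.0, 5.0, 5.0]))

    @settings(max_examples=40, derandomize=True)
    @given(series_strategy)
    def test_idempotent(self, x):
        z = zscore(x)
        assert np.allclose(zscore(z), z, atol=1e-10)


class TestStatAv:
    def test_equal_segment_means_give_zero(self):
        x = np.array([1.0, -1.0] * 5)
        assert statav(x, 5) == 0.0

    def test_hand_computed_value(self):
        # segment means of [1..10] at n=2 are 3 and 8
        assert statav(np.arange(1.0, 11.0), 2) == pytest.approx(
            1.1677484162422844, abs=1e-12
        )

    @settings(max_examples=40, derandomize=True)
    @given(series_strategy, st.floats(0.1, 10), st.floats(-5, 5))
    def test_positive_affine_invariance(self, x, a, b):
        assert statav(a * x + b, 3) == pytest.approx(statav(x, 3), abs=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            statav(np.arange(5.0), 3)


class TestOutlierTiming:
    def test_single_deep_negative_point_is_late(self):
        assert outlier_timing_mrmd(np.array([0.0, 0, 0, 0, -10.0])) == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True)
    @given(series_strategy)
    def test_time_reversal_antisymmetry(self, x):
        forward = outlier_timing_mrmd(x)
        backward = outlier_timing_mrmd(x[::-1])
        assert backward == pytest.approx(-forward, abs=1e-10)

    def test_positive_variant_mirrors_negation(self, rng):
        x = rng.normal(size=200)
        pos = outlier_timing_mrmd(x, OutlierTimingParams(sign="positive"))
        neg = outlier_timing_mrmd(-x, OutlierTimingParams(sign="negative"))
        assert pos == pytest.approx(neg, abs=1e-12)

    def test_increasing_ramp_defined(self):
        # after z-scoring, the smallest point always sits below zero,
        # so the shallowest threshold selects at least one point
        assert np.isfinite(outlier_timing_mrmd(np.array([10.0, 11.0, 12.0, 13.0])))


class TestLocalGlobalStd:
    def test_constant_head_gives_zero(self):
        x = np.concatenate([np.zeros(2), np.random.default_rng(0).normal(size=198)])
        assert local_global_std(x, 0.01) == 0.0

    def test_hand_computed_alternating(self):
        x = np.tile([1.0, -1.0], 100)
        assert local_global_std(x, 0.01) == pytest.approx(
            1.4106735979665885, abs=1e-12
        )

    @settings(max_examples=30, derandomize=True)
    @given(series_strategy, st.floats(0.5, 20))
    def test_scale_invariance(self, x, a):
        assert local_global_std(a * x, 0.1) == pytest.approx(
            local_global_std(x, 0.1), abs=1e-10
        )

    def test_short_head_raises(self):
        with pytest.raises(ValueError):
            local_global_std(np.random.default_rng(1).normal(size=50), 0.01)


class TestDFA:
    def test_white_noise_alpha_half(self):
        alphas = [
            dfa_scaling(np.random.default_rng(s).normal(size=5000))[0]
            for s in range(20)
        ]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_alpha_three_halves(self):
        alphas = [
            dfa_scaling(np.cumsum(np.random.default_rng(s).normal(size=5000)))[0]
            for s in range(20)
        ]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.1)

    def test_exact_power_law_fit_has_zero_residual(self):
        scales = np.array([50, 80, 128, 205, 328])
        alpha, ssr = loglog_fit(scales, 0.37 * scales**0.8)
        assert alpha == pytest.approx(0.8, abs=1e-12)
        assert ssr <= 1e-10

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dfa_scaling(np.random.default_rng(0).normal(size=100), min_window=50)


class TestFeatureMatrix:
    def test_shape_and_zero_variance_drop(self, small_stack):
        stack, _ = small_stack
        mats = compute_feature_matrix(stack)
        assert len(mats) == stack.values.shape[0]
        for m in mats:
            assert m.values.shape[0] == len(stack.region_ids)
            # mean and std are constant after z-scoring, hence dropped
            assert "mean" not in m.values.columns
            assert "std" not in m.values.columns

    def test_identical_subjects_identical_matrices(self, rng):
        one = rng.normal(size=(1, 10, 200))
        stack = sd.TimeSeriesStack(
            values=np.repeat(one, 3, axis=0),
            region_ids=[f"R{i}" for i in range(10)],
            subject_ids=["a", "b", "c"],
            state=["awake"] * 3,
        )
        mats = compute_feature_matrix(stack)
        assert mats[0].values.equals(mats[1].values)
        assert mats[1].values.equals(mats[2].values)

    def test_cells_match_direct_single_series_calls(self, small_stack):
        stack, _ = small_stack
        mats = compute_feature_matrix(stack)
        x = stack.values[0, 5]
        assert mats[0].values.iloc[5]["statav_10"] == pytest.approx(statav(x, 10))
        assert mats[0].values.iloc[5]["outlier_timing_neg_mrmd"] == pytest.approx(
            outlier_timing_mrmd(x)
        )
        assert mats[0].values.iloc[5]["dfa_alpha"] == pytest.approx(dfa_scaling(x)[0])


class TestNormalization:
    def test_median_maps_to_half_before_rescale(self):
        col = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        pre, _ = robust_sigmoid_columns(col, rescale=False)
        assert pre[2, 0] == pytest.approx(0.5)

    def test_hand_computed_prerescale_value(self):
        # type-7 quartiles of [0..4]: Q1=1, Q3=3, IQR=2
        col = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        pre, _ = robust_sigmoid_columns(col, rescale=False)
        assert pre[4, 0] == pytest.approx(0.7939660923501268, abs=1e-12)

    def test_rescale_bounds_and_order(self, rng):
        mat = make_feature_matrix(rng.normal(size=(20, 4)))
        norm = normalize_features(mat)
        v = norm.values.values
        assert v.min() == pytest.approx(0.0) and v.max() == pytest.approx(1.0)
        for j in range(4):
            assert (
                np.argsort(v[:, j]) == np.argsort(mat.values.values[:, j])
            ).all()

    def test_iqr_zero_falls_back_to_sd(self):
        col = np.array([[0.0]] * 8 + [[1.0]] * 2)  # IQR = 0, SD > 0
        pre, dropped = robust_sigmoid_columns(col, rescale=False)
        assert not dropped[0]
        assert np.isfinite(pre).all()

    def test_constant_feature_dropped(self, rng):
        arr = rng.normal(size=(10, 2))
        arr[:, 1] = 3.0
        norm = normalize_features(make_feature_matrix(arr))
        assert list(norm.values.columns) == ["f0"]


class TestGroupAverage:
    def test_single_subject_identity(self, rng):
        m = make_feature_matrix(rng.normal(size=(8, 3)))
        assert group_average([m]).values.equals(m.values)

    def test_opposite_values_cancel(self, rng):
        a = rng.normal(size=(8, 3))
        avg = group_average([make_feature_matrix(a), make_feature_matrix(-a)])
        assert np.allclose(avg.values.values, 0.0)

    def test_matches_stacked_mean_oracle(self, rng):
        mats = [make_feature_matrix(rng.normal(size=(8, 3))) for _ in range(10)]
        avg = group_average(mats)
        oracle = np.mean([m.values.values for m in mats], axis=0)
        assert np.allclose(avg.values.values, oracle, atol=1e-12)

    def test_missing_cells_ignored_not_zeroed(self):
        a = make_feature_matrix(np.array([[1.0, np.nan], [2.0, 4.0]]))
        b = make_feature_matrix(np.array([[3.0, np.nan], [4.0, 8.0]]))
        avg = group_average([a, b])
        assert avg.values.iloc[0, 0] == 2.0
        assert np.isnan(avg.values.iloc[0, 1])  # missing in all subjects

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            group_average([])
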