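"""Tests for mass-univariate mapping, feature clustering and confound checks."""

import numpy as np
import pandas as pd
import pytest

import synaptodyn as sd
from synaptodyn.association import (
    apply_gsr,
    associate,
    celltype_specificity,
    cluster_significant_features,
    motion_amplitude_check,
    residualize_confound,
)

from conftest import make_feature_matrix


def _map_over(features, values):
    return pd.Series(values, index=features.values.index)


class TestAssociate:
    def test_feature_identical_to_map_is_significant(self, rng):
        arr = rng.normal(size=(20, 3))
        feats = make_feature_matrix(arr)
        table = associate(_map_over(feats, arr[:, 0]), feats)
        assert table.loc["f0", "r"] == pytest.approx(1.0)
        assert table.loc["f0", "significant"]

    def test_bonferroni_arithmetic(self, rng):
        arr = rng.normal(size=(30, 10))
        feats = make_feature_matrix(arr)
        table = associate(_map_over(feats, rng.normal(size=30)), feats)
        assert np.allclose(
            table["p_bonf"].values, np.minimum(table["p_raw"].values * 10, 1.0)
        )

    def test_monotone_transform_invariance(self, rng):
        arr = rng.uniform(1, 2, size=(25, 4))
        feats = make_feature_matrix(arr)
        m = pd.Series(rng.uniform(0, 1, size=25), index=feats.values.index)
        t1 = associate(m, feats)
        t2 = associate(np.exp(3 * m), feats)
        assert np.allclose(t1["r"].values, t2["r"].values, atol=1e-12)

    def test_r_min_filter(self, rng):
        arr = rng.normal(size=(40, 2))
        m = _map_over(make_feature_matrix(arr), arr[:, 0])
        arr[:, 1] = arr[:, 0] + 2.5 * rng.normal(size=40)  # significant but modest r
        feats = make_feature_matrix(arr)
        t = associate(m, feats, r_min=0.99)
        assert not t.loc["f1", "significant"]

    def test_too_few_regions_raises(self, rng):
        feats = make_feature_matrix(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            associate(_map_over(feats, rng.normal(size=4)), feats)


class TestFeatureClustering:
    def test_two_exact_blocks(self, rng):
        base1 = rng.normal(size=30)
        base2 = rng.normal(size=30)
        cols = [base1 + 0.01 * rng.normal(size=30) for _ in range(6)]
        cols += [base2 + 0.01 * rng.normal(size=30) for _ in range(6)]
        feats = make_feature_matrix(np.column_stack(cols))
        rvec = pd.Series(rng.uniform(0.5, 0.9, 12), index=feats.values.columns)
        res = cluster_significant_features(feats, rvec)
        assert res.chosen_k == 2
        labels = res.labels
        assert labels.iloc[:6].nunique() == 1 and labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[6]

    def test_singleton_input_returns_itself(self, rng):
        feats = make_feature_matrix(rng.normal(size=(20, 1)))
        rvec = pd.Series([0.7], index=feats.values.columns)
        res = cluster_significant_features(feats, rvec)
        assert res.representative == "f0"

    def test_representative_is_max_abs_r_in_largest_cluster(self, rng):
        base = rng.normal(size=30)
        cols = [base + 0.05 * rng.normal(size=30) for _ in range(5)]
        cols += [rng.normal(size=30) for _ in range(2)]
        feats = make_feature_matrix(np.column_stack(cols))
        rvec = pd.Series([0.5, 0.9, 0.6, 0.55, 0.52, 0.3, 0.2],
                         index=feats.values.columns)
        res = cluster_significant_features(feats, rvec)
        assert res.representative == "f1"

    def test_explicit_override(self, rng):
        feats = make_feature_matrix(rng.normal(size=(25, 4)))
        rvec = pd.Series([0.9, 0.5, 0.4, 0.3], index=feats.values.columns)
        res = cluster_significant_features(feats, rvec, representative="f3")
        assert res.representative == "f3"


class TestResidualizeConfound:
    def test_orthogonal_confound_leaves_features(self, rng):
        arr = rng.normal(size=(40, 3))
        feats = make_feature_matrix(arr)
        confound = pd.Series(rng.normal(size=40), index=feats.values.index)
        out, n = residualize_confound(feats, confound)
        assert n == 0
        assert np.allclose(out.values.values, arr)

    def test_proportional_feature_zeroed(self, rng):
        c = rng.normal(size=40)
        arr = np.column_stack([2.0 * c, rng.normal(size=40)])
        feats = make_feature_matrix(arr)
        confound = pd.Series(c, index=feats.values.index)
        out, n = residualize_confound(feats, confound)
        assert n >= 1
        assert np.allclose(out.values["f0"].values, 0.0, atol=1e-10)

    def test_constant_confound_noop(self, rng):
        arr = rng.normal(size=(30, 2))
        feats = make_feature_matrix(arr)
        confound = pd.Series(np.ones(30), index=feats.values.index)
        out, n = residualize_confound(feats, confound)
        assert n == 0 and np.allclose(out.values.values, arr)


class TestMotionCheck:
    def _stack(self, values, motion):
        n_s, n_r, T = values.shape
        return sd.TimeSeriesStack(
            values=values,
            region_ids=[f"R{i}" for i in range(n_r)],
            subject_ids=[f"s{i}" for i in range(n_s)],
            state=["awake"] * n_s,
            motion=motion,
        )

    def test_fd_equal_to_signal_gives_unit_r(self, rng):
        sig = rng.normal(size=(1, 2, 100))
        motion = sig[:, 0, 1:].copy()
        res = motion_amplitude_check(self._stack(sig, motion))
        assert res["per_subject_region"].iloc[0, 0] == pytest.approx(1.0)

    def test_independent_motion_near_zero_median(self):
        meds = []
        for s in range(5):
            cfg = sd.SynthConfig(seed=400 + s, n_subjects=3, n_timepoints=300)
            d, _ = sd.synthetic.gen_density(cfg)
            stack, _ = sd.synthetic.gen_timeseries(cfg, d)
            meds.append(motion_amplitude_check(stack)["median"])
        assert abs(np.median(meds)) < 0.05

    def test_contamination_dial_is_monotone(self):
        meds = []
        for dial in (0.0, 0.4, 0.8):
            cfg = sd.SynthConfig(
                seed=41, n_subjects=3, n_timepoints=300, motion_coupling=dial
            )
            d, _ = sd.synthetic.gen_density(cfg)
            stack, _ = sd.synthetic.gen_timeseries(cfg, d)
            meds.append(motion_amplitude_check(stack)["median"])
        assert meds[0] < meds[1] < meds[2]

    def test_missing_motion_raises(self, rng):
        stack = self._stack(rng.normal(size=(1, 2, 50)), rng.normal(size=(1, 49)))
        stack.motion = None
        with pytest.raises(ValueError):
            motion_amplitude_check(stack)


class TestGSR:
    def test_identical_regions_become_degenerate(self):
        base = np.random.default_rng(0).normal(size=120)
        values = np.tile(base, (1, 4, 1))
        stack = sd.TimeSeriesStack(
            values=values, region_ids=list("abcd"), subject_ids=["s"], state=["awake"]
        )
        out = apply_gsr(stack)
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_orthogonal_region_only_rescaled(self, rng):
        t = np.arange(200)
        g = np.sin(2 * np.pi * t / 50)
        y = np.cos(2 * np.pi * t / 50)
        # global mean is (g + g + y - y)/4 = g/2, exactly orthogonal to y
        values = np.stack([np.stack([g, g, y, -y])])
        stack = sd.TimeSeriesStack(
            values=values, region_ids=list("abyz"), subject_ids=["s"], state=["awake"]
        )
        out = apply_gsr(stack)
        r = np.corrcoef(out.values[0, 2], y)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_feature_maps_stable_under_gsr_when_global_weak(self, small_stack):
        stack, _ = small_stack
        mats = sd.features.compute_feature_matrix(stack)
        mats_g = sd.features.compute_feature_matrix(apply_gsr(stack))
        a = sd.features.group_average(mats).values
        b = sd.features.group_average(mats_g).values
        common = a.columns.intersection(b.columns)
        rs = [
            pd.Series(a[c]).corr(pd.Series(b[c]), method="spearman") for c in common
        ]
        assert np.nanmean(rs) > 0.6


class TestCellTypes:
    def test_identical_map_and_bonferroni_arithmetic(self, rng):
        maps = pd.DataFrame(
            rng.uniform(1, 2, size=(2, 44)),
            index=["psd95_long", "sap102"],
            columns=[f"R{i}" for i in range(44)],
        )
        cells = pd.DataFrame(
            rng.uniform(0, 1, size=(9, 44)),
            index=[f"cell{i}" for i in range(9)],
            columns=maps.columns,
        )
        cells.iloc[0] = maps.iloc[0]
        res = celltype_specificity(maps, cells)["table"]
        row = res[(res.synapse_type == "psd95_long") & (res.cell_type == "cell0")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert np.allclose(
            res["p_bonf"].values, np.minimum(res["p_raw"].values * 9, 1.0)
        )
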