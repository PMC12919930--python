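"""Tests for connectome construction and degree-density associations."""

import numpy as np
import pandas as pd
import pytest

import synaptodyn as sd
from synaptodyn.network import (
    build_functional_connectome,
    build_structural_connectome,
    degrees,
    layer_degree_association,
    lifetime_degree_relation,
)


def _edges(rows):
    return pd.DataFrame(rows, columns=["source", "target", "weight", "p"])


class TestStructural:
    def test_p_filter_keeps_significant(self):
        e = _edges([
            ("a", "b", 1.0, 0.01),
            ("b", "c", 2.0, 0.01),
            ("c", "a", 3.0, 0.5),
            ("a", "c", 4.0, 0.5),
        ])
        sc = build_structural_connectome(e, region_ids=list("abc"))
        assert (sc.weights != 0).sum() == 2

    def test_polarity_flag(self):
        e = _edges([("a", "b", 1.0, 0.01), ("b", "a", 2.0, 0.5)])
        sc = build_structural_connectome(e, region_ids=list("ab"),
                                         keep_significant=False)
        assert sc.weights[1, 0] == 2.0 and sc.weights[0, 1] == 0.0

    def test_duplicates_and_self_loops_raise(self):
        with pytest.raises(ValueError):
            build_structural_connectome(
                _edges([("a", "b", 1.0, 0.01), ("a", "b", 2.0, 0.02)])
            )
        with pytest.raises(ValueError):
            build_structural_connectome(_edges([("a", "a", 1.0, 0.01)]))

    def test_generator_hits_requested_density(self):
        cfg = sd.SynthConfig(seed=9, n_regions=137)
        d, _ = sd.synthetic.gen_density(cfg)
        edges = sd.synthetic.gen_edge_candidates(cfg, d)
        sc = build_structural_connectome(edges, region_ids=list(d.values.columns))
        assert sc.density == pytest.approx(0.07, abs=0.01)


class TestDegrees:
    def test_hand_example(self):
        sc = sd.StructuralConnectome(
            weights=np.array([[0.0, 2.0], [3.0, 0.0]]),
            pvalues=np.full((2, 2), np.nan),
            region_ids=["a", "b"],
        )
        t = degrees(sc)
        assert list(t["in_strength"]) == [3.0, 2.0]
        assert list(t["out_strength"]) == [2.0, 3.0]

    def test_symmetric_in_equals_out_and_oracle(self, rng):
        W = rng.uniform(0, 1, size=(10, 10))
        np.fill_diagonal(W, 0.0)
        sym = (W + W.T) / 2
        sc = sd.StructuralConnectome(
            weights=sym, pvalues=np.full((10, 10), np.nan),
            region_ids=[f"R{i}" for i in range(10)],
        )
        t = degrees(sc)
        assert np.allclose(t["in_strength"], t["out_strength"])
        assert np.allclose(t["in_strength"].values, sym.sum(axis=0))

    def test_region_permutation_equivariance(self, rng):
        W = rng.uniform(0, 1, size=(6, 6))
        np.fill_diagonal(W, 0)
        ids = [f"R{i}" for i in range(6)]
        perm = rng.permutation(6)
        sc1 = sd.StructuralConnectome(W, np.full((6, 6), np.nan), ids)
        sc2 = sd.StructuralConnectome(
            W[np.ix_(perm, perm)], np.full((6, 6), np.nan), [ids[i] for i in perm]
        )
        t1, t2 = degrees(sc1), degrees(sc2)
        assert np.allclose(t1.loc[t2.index, "in_strength"], t2["in_strength"])


class TestFunctional:
    def _stack(self, values):
        n_s, n_r, _ = values.shape
        return sd.TimeSeriesStack(
            values=values,
            region_ids=[f"R{i}" for i in range(n_r)],
            subject_ids=[f"s{i}" for i in range(n_s)],
            state=["awake"] * n_s,
        )

    def test_identical_regions_give_unit_fc(self, rng):
        base = rng.normal(size=100)
        v = np.stack([np.stack([base, base, rng.normal(size=100)])])
        fc = build_functional_connectome(self._stack(v))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(fc.values) == 0)

    def test_single_subject_equals_pearson(self, rng):
        v = rng.normal(size=(1, 5, 80))
        fc = build_functional_connectome(self._stack(v))
        oracle = np.corrcoef(v[0])
        np.fill_diagonal(oracle, 0)
        assert np.allclose(fc.values, oracle, atol=1e-12)

    def test_mean_across_subjects_matches_oracle(self, rng):
        v = rng.normal(size=(10, 5, 80))
        fc = build_functional_connectome(self._stack(v))
        oracle = np.mean([np.corrcoef(v[s]) for s in range(10)], axis=0)
        np.fill_diagonal(oracle, 0)
        assert np.allclose(fc.values, oracle, atol=1e-12)

    def test_mean_of_subject_fc_differs_from_concatenated_fc(self, rng):
        # subject means differ, so concatenating time-series is NOT the
        # same as averaging per-subject correlation matrices
        v = rng.normal(size=(2, 4, 60))
        v[1] += 5.0
        fc = build_functional_connectome(self._stack(v))
        concat = np.corrcoef(np.concatenate([v[0], v[1]], axis=1))
        np.fill_diagonal(concat, 0)
        assert not np.allclose(fc.values, concat, atol=1e-3)

    def test_constant_region_raises_with_name(self, rng):
        v = rng.normal(size=(1, 3, 50))
        v[0, 1] = 2.0
        with pytest.raises(ValueError, match="R1"):
            build_functional_connectome(self._stack(v))


class TestLayerAssociation:
    def test_layer_equal_to_strength_and_pairwise_complete(self, rng):
        deg = pd.DataFrame(
            {
                "in_strength": rng.uniform(0, 5, 31),
                "out_strength": rng.uniform(0, 5, 31),
            },
            index=[f"R{i}" for i in range(31)],
        )
        layers = pd.DataFrame(
            np.full((2, 31), np.nan), index=["I", "IV"], columns=deg.index
        )
        layers.loc["I"] = deg["in_strength"].values
        layers.loc["IV", deg.index[:15]] = rng.uniform(0, 1, 15)  # 15-region layer
        table = layer_degree_association(layers, deg)
        row = table[(table.layer == "I") & (table.degree == "in_strength")]
        assert row["r"].iloc[0] == pytest.approx(1.0)
        assert table[table.layer == "IV"]["n"].iloc[0] == 15

    def test_sparse_layer_flagged_missing(self, rng):
        deg = pd.DataFrame(
            {"in_strength": rng.uniform(0, 5, 10), "out_strength": rng.uniform(0, 5, 10)},
            index=[f"R{i}" for i in range(10)],
        )
        layers = pd.DataFrame(np.full((1, 10), np.nan), index=["IV"], columns=deg.index)
        layers.iloc[0, :3] = 1.0
        table = layer_degree_association(layers, deg)
        assert table["r"].isna().all()


class TestLifetimeRelation:
    def _density(self, maps, lifetimes):
        idx = pd.Index([f"S{i}" for i in range(maps.shape[0])], name="subtype")
        meta = pd.DataFrame(
            {"protein_class": ["PSD95"] * maps.shape[0], "lifetime": lifetimes},
            index=idx,
        )
        vals = pd.DataFrame(maps, index=idx,
                            columns=[f"R{i}" for i in range(maps.shape[1])])
        return sd.DensityMatrix(values=vals, subtype_meta=meta)

    def test_monotone_lifetime_gives_unit_step2(self, rng):
        deg_vals = rng.uniform(0, 5, 20)
        deg = pd.DataFrame(
            {"in_strength": deg_vals, "out_strength": deg_vals},
            index=[f"R{i}" for i in range(20)],
        )
        # subtype k's map = degree + noise growing with k: step-1 r decreasing
        maps = np.stack([deg_vals + k * rng.normal(size=20) for k in range(4)])
        maps = maps - maps.min(axis=1, keepdims=True)  # shift keeps ranks, nonneg
        d = self._density(maps, [90, 70, 50, 30])  # lifetime decreasing with k
        res = lifetime_degree_relation(d, deg)
        step1 = res["step1"].sort_values("lifetime")
        if step1["r_in"].is_monotonic_increasing:
            assert res["r_in"] == pytest.approx(1.0)

    def test_identical_lifetimes_degenerate(self, rng):
        maps = rng.uniform(0, 1, size=(3, 15))
        deg = pd.DataFrame(
            {"in_strength": rng.uniform(0, 5, 15), "out_strength": rng.uniform(0, 5, 15)},
            index=[f"R{i}" for i in range(15)],
        )
        res = lifetime_degree_relation(self._density(maps, [50, 50, 50]), deg)
        assert res["degenerate"] and np.isnan(res["r_in"])

    def test_log_transform_leaves_spearman(self, rng):
        # rank invariance: correlating density with degree or log(degree)
        # is identical for positive degrees
        from synaptodyn._stats import spearman

        dmap = rng.uniform(0.5, 2.0, 30)
        deg = rng.uniform(0.1, 9.0, 30)
        assert spearman(dmap, deg)[0] == pytest.approx(
            spearman(dmap, np.log(deg))[0], abs=1e-12
        )
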