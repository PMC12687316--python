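"""Feature matrices, complete-linkage clustering, exclusive intersections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from venomglyco.clustering import (
    FeatureMatrix,
    build_matrix,
    cluster,
    intersections,
    mass_bin,
)
from venomglyco.simulate import planted_feature_matrix


def df(rows, samples=None, features=None):
    rows = np.asarray(rows)
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    features = features or [f"f{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=samples, columns=features)


class TestBuildMatrix:
    def test_mass_binning_merges_within_tolerance(self):
        assert mass_bin([1000.000, 1000.010], bin_da=0.02) == [[1000.000, 1000.010]]
        assert mass_bin([1000.000, 1000.010], bin_da=0.005) == [[1000.000], [1000.010]]

    def test_mass_binning_is_single_linkage(self):
        # chain 0.015 apart merges under 0.02 even though ends differ by 0.03
        assert len(mass_bin([1000.0, 1000.015, 1000.03], bin_da=0.02)) == 1

    def test_identical_samples_identical_rows(self, zero_noise_bundle):
        from venomglyco.assembly import assemble

        b = zero_noise_bundle
        recs = assemble(b.intact_table, b.proteins, b.glycan_db).records
        for kind in ("glycopeptide", "neutral_mass", "backbone"):
            m = build_matrix(recs, kind)
            assert set(np.unique(m.values.to_numpy())) <= {0, 1}
            assert (m.values.sum(axis=0) > 0).all()

    def test_all_zero_feature_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(df([[1, 0], [1, 0]]), "glycopeptide")


class TestCluster:
    def test_identical_rows_merge_first_at_zero(self):
        d = cluster(FeatureMatrix(df([[1, 0, 1], [1, 0, 1], [1, 1, 0]]), "glycopeptide"))
        first = d.merges[0]
        assert first[2] == 0.0
        assert set(first[0] + first[1]) == {"S0", "S1"}

    def test_binary_distance_is_sqrt_k(self):
        # rows differing in k positions are sqrt(k) apart (first merge height)
        rows = [[1, 1, 1, 1, 0, 0], [1, 1, 0, 0, 1, 1], [0, 0, 0, 0, 0, 1]]
        d = cluster(FeatureMatrix(df(rows), "glycopeptide"))
        heights = sorted(m[2] for m in d.merges)
        assert heights[0] == pytest.approx(np.sqrt(3))  # S1 vs S2 differ in 3

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            cluster(df([[1, 0]], samples=["only"]))

    def test_heights_nondecreasing_and_n_minus_1_merges(self, rng):
        mat, _ = planted_feature_matrix(rng)
        d = cluster(FeatureMatrix(mat, "glycopeptide"))
        heights = [m[2] for m in d.merges]
        assert heights == sorted(heights)
        assert len(d.merges) == mat.shape[0] - 1

    def test_merge_heights_agree_with_scipy(self, rng):
        """Cross-check the hand-rolled agglomeration against scipy linkage."""
        for _ in range(5):
            X = rng.random((8, 12))
            m = pd.DataFrame((X > 0.5).astype(int),
                             index=[f"S{i}" for i in range(8)],
                             columns=[f"f{j}" for j in range(12)])
            ours = sorted(mg[2] for mg in cluster(m).merges)
            scipys = sorted(linkage(pdist(m.to_numpy(dtype=float)), "complete")[:, 2])
            np.testing.assert_allclose(ours, scipys, atol=1e-9)

    def test_feature_permutation_invariant(self, rng):
        mat, _ = planted_feature_matrix(rng, n_features_per_group=30)
        d1 = cluster(FeatureMatrix(mat, "glycopeptide"))
        perm = rng.permutation(mat.shape[1])
        d2 = cluster(FeatureMatrix(mat.iloc[:, perm], "glycopeptide"))
        assert d1.merges == d2.merges

    def test_planted_partition_recovered(self, rng):
        mat, labels = planted_feature_matrix(
            rng, group_sizes=(3, 2, 2), within_overlap=0.9, between_overlap=0.2
        )
        got = cluster(FeatureMatrix(mat, "glycopeptide")).cut(3)
        # same partition up to label renaming
        by_got = {}
        for s, g in got.items():
            by_got.setdefault(g, set()).add(s)
        by_true = {}
        for s, g in labels.items():
            by_true.setdefault(g, set()).add(s)
        assert sorted(map(sorted, by_got.values())) == sorted(map(sorted, by_true.values()))

    def test_newick_export_parses(self, rng):
        import dendropy

        mat, _ = planted_feature_matrix(rng, n_features_per_group=20)
        nwk = cluster(FeatureMatrix(mat, "glycopeptide")).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == mat.shape[0]


def brute_force_intersections(sets):
    """Oracle: per-feature membership pattern enumeration."""
    union = set().union(*sets.values())
    out = {}
    for f in union:
        pat = tuple(sorted(s for s in sets if f in sets[s]))
        out[pat] = out.get(pat, 0) + 1
    return out


class TestIntersections:
    def test_disjoint_sets_only_singletons(self):
        out = intersections({"a": {1, 2}, "b": {3}, "c": {4, 5, 6}})
        assert (out["degree"] == 1).all()
        assert out["count"].sum() == 6

    def test_identical_sets_full_subset_only(self):
        out = intersections({"a": {1, 2, 3}, "b": {1, 2, 3}, "c": {1, 2, 3}})
        assert len(out) == 1
        assert out.iloc[0]["members"] == "a&b&c"
        assert out.iloc[0]["count"] == 3

    def test_counts_sum_to_union(self, rng):
        sets = {f"s{i}": set(rng.choice(100, size=30, replace=False)) for i in range(4)}
        out = intersections(sets)
        assert out["count"].sum() == len(set().union(*sets.values()))

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.sets(st.integers(0, 99), max_size=40),
            min_size=1, max_size=4,
        )
    )
    def test_matches_brute_force(self, sets):
        if not any(sets.values()):
            return
        out = intersections(sets)
        want = brute_force_intersections(sets)
        got = {tuple(m.split("&")): c for m, c in zip(out["members"], out["count"])}
        assert got == want

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            intersections({})
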