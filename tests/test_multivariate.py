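import numpy as np
import pandas as pd
import pytest

from knotpop import (band_similarity, cophenetic_matrix, hierarchical_cluster,
                     kruskal_wallis, mca_binary, pca)
from knotpop.io import BandMatrix, TraitTable

from conftest import random_band_matrix


def profile_bm(rows, index=None):
    index = index or [f"s{i}" for i in range(len(rows))]
    values = pd.DataFrame(np.asarray(rows, float), index=index,
                          columns=[f"P1::b{j}" for j in range(len(rows[0]))])
    return BandMatrix(values, pd.Series("X", index=values.index))


class TestBandSimilarity:
    def test_identical_profiles(self):
        bm = profile_bm([[1, 1, 0], [1, 1, 0]])
        for method in ("dice_paper", "jaccard_true"):
            assert band_similarity(bm, method).values.iloc[0, 1] == 1.0

    def test_worked_example(self):
        bm = profile_bm([[1, 1, 0], [1, 0, 1]])
        assert band_similarity(bm, "dice_paper").values.iloc[0, 1] == 0.5
        assert band_similarity(bm, "jaccard_true").values.iloc[0, 1] == \
            pytest.approx(1 / 3)

    def test_disjoint_profiles(self):
        bm = profile_bm([[1, 1, 0], [0, 0, 1]])
        for method in ("dice_paper", "jaccard_true"):
            assert band_similarity(bm, method).values.iloc[0, 1] == 0.0

    def test_all_zero_pair_warns_similarity_one(self):
        bm = profile_bm([[0, 0, 0], [0, 0, 0], [1, 1, 1]])
        with pytest.warns(UserWarning, match="all-zero"):
            sim = band_similarity(bm)
        assert sim.values.iloc[0, 1] == 1.0

    def test_dice_dominates_jaccard(self, preset_bm):
        bm, _ = preset_bm
        dice = band_similarity(bm, "dice_paper").values.to_numpy()
        jac = band_similarity(bm, "jaccard_true").values.to_numpy()
        assert (dice >= jac - 1e-12).all()
        # equality only where profiles identical or disjoint
        off = ~np.eye(len(dice), dtype=bool)
        eq = np.isclose(dice, jac) & off
        assert np.all((dice[eq] == 1.0) | (dice[eq] == 0.0))


def brute_force_linkage(d0: np.ndarray, method: str) -> np.ndarray:
    """Naive O(N^3) agglomeration with Lance-Williams updates, merging the
    lowest-distance pair (lowest indices on ties)."""
    n = d0.shape[0]
    d = d0.astype(float).copy()
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    slots = list(range(n))
    Z = []
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(slots)):
            for bi in range(ai + 1, len(slots)):
                key = d[slots[ai], slots[bi]]
                if best is None or key < best[0] - 1e-12:
                    best = (key, ai, bi)
        dist, ai, bi = best
        sa, sb = slots[ai], slots[bi]
        ida, na = active[sa]
        idb, nb = active[sb]
        Z.append([min(ida, idb), max(ida, idb), dist, na + nb])
        for sc in slots:
            if sc in (sa, sb):
                continue
            nc = active[sc][1]
            if method == "upgma":
                new = (na * d[sa, sc] + nb * d[sb, sc]) / (na + nb)
            else:  # ward.d2 on the given dissimilarities
                tot = na + nb + nc
                new = np.sqrt(((na + nc) * d[sa, sc] ** 2
                               + (nb + nc) * d[sb, sc] ** 2
                               - nc * dist ** 2) / tot)
            d[sa, sc] = d[sc, sa] = new
        active[sa] = (next_id, na + nb)
        next_id += 1
        slots.remove(sb)
    return np.array(Z)


class TestHierarchicalCluster:
    def test_obvious_first_merge(self):
        D = pd.DataFrame([[0, 1, 10], [1, 0, 10], [10, 10, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        for method in ("ward", "upgma"):
            dend = hierarchical_cluster(D, method)
            assert sorted(dend.linkage[0, :2]) == [0, 1]

    def test_upgma_exact_on_ultrametric(self):
        # perfect ultrametric: d(a,b)=2, d(.,c)=6, d(.,d)=10
        D = pd.DataFrame([[0, 2, 6, 10], [2, 0, 6, 10],
                          [6, 6, 0, 10], [10, 10, 10, 0]],
                         index=list("abcd"), columns=list("abcd"), dtype=float)
        dend = hierarchical_cluster(D, "upgma")
        pd.testing.assert_frame_equal(dend.cophenetic_heights(), D,
                                      check_names=False)

    def test_order_invariance(self, preset_bm):
        bm, _ = preset_bm
        D = band_similarity(bm).to_distance()
        perm = list(np.random.default_rng(0).permutation(D.index))
        dend1 = hierarchical_cluster(D, "ward")
        dend2 = hierarchical_cluster(D.loc[perm, perm], "ward")
        h1 = dend1.cophenetic_heights().loc[D.index, D.index]
        h2 = dend2.cophenetic_heights().loc[D.index, D.index]
        assert np.allclose(h1, h2)

    @pytest.mark.parametrize("method", ["ward", "upgma"])
    def test_matches_brute_force_small_n(self, method):
        rng = np.random.default_rng(3)
        for n in (3, 4, 5):
            for _ in range(5):
                x = rng.random((n, 4))
                from scipy.spatial.distance import pdist, squareform
                d = squareform(pdist(x))
                D = pd.DataFrame(d, index=[f"s{i}" for i in range(n)],
                                 columns=[f"s{i}" for i in range(n)])
                dend = hierarchical_cluster(D, method)
                Z_bf = brute_force_linkage(d, method)
                assert np.allclose(dend.linkage[:, 2], Z_bf[:, 2]), method
                sets_scipy = _merge_sets(dend.linkage, n)
                sets_bf = _merge_sets(Z_bf, n)
                assert sets_scipy == sets_bf

    def test_newick_export_round_trip(self, tmp_path, tiny_bm):
        import skbio
        D = band_similarity(tiny_bm).to_distance()
        dend = hierarchical_cluster(D, "upgma")
        p = tmp_path / "tree.nwk"
        dend.to_newick(p)
        tree = skbio.TreeNode.read(str(p))
        assert {t.name for t in tree.tips()} == set(tiny_bm.sample_ids)


def _merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = set()
    for m, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + m] = merged
        out.add(merged)
    return out


class TestCopheneticRanks:
    def test_first_merge_lowest_rank(self):
        D = pd.DataFrame([[0, 1, 10], [1, 0, 10], [10, 10, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        _, ranks = cophenetic_matrix(hierarchical_cluster(D, "upgma"))
        assert ranks.loc["a", "b"] == 1
        assert ranks.loc["a", "c"] == 2

    def test_caterpillar_hand_enumeration(self):
        # merges: (a,b) then (+c) then (+d)
        D = pd.DataFrame([[0, 1, 4, 9], [1, 0, 4, 9],
                          [4, 4, 0, 9], [9, 9, 9, 0]],
                         index=list("abcd"), columns=list("abcd"), dtype=float)
        _, ranks = cophenetic_matrix(hierarchical_cluster(D, "upgma"))
        assert ranks.loc["a", "b"] == 1
        assert ranks.loc["a", "c"] == ranks.loc["b", "c"] == 2
        assert ranks.loc["a", "d"] == ranks.loc["c", "d"] == 3

    def test_star_tree_all_pairs_tie(self):
        bm = profile_bm([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0],
                         [0, 0, 0, 1]])
        from knotpop import squared_euclidean_binary
        D = squared_euclidean_binary(bm)  # all off-diagonal distances equal
        heights, _ = cophenetic_matrix(hierarchical_cluster(D, "upgma"))
        off = heights.to_numpy()[np.triu_indices(4, 1)]
        assert np.allclose(off, off[0])


class TestPca:
    def test_collinear_data_single_component(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        res = pca(X, center=True)
        assert res.explained[0] == pytest.approx(1.0)

    def test_explained_sums_to_one(self, preset):
        from knotpop import simulate_feature_table
        feats = simulate_feature_table(preset)
        res = pca(feats.data, center=True, scale=True)
        assert res.explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        r1 = pca(X, center=True, scale=True)
        r2 = pca(X[["c", "a", "d", "b"]], center=True, scale=True)
        assert np.allclose(r1.scores, r2.scores)
        assert np.allclose(r1.explained, r2.explained)

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((8, 3)))
        res = pca(X, center=True)
        for k in res.loadings.columns:
            col = res.loadings[k]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_zero_variance_column_dropped_under_scaling(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca(X, center=True, scale=True)
        assert list(res.loadings.index) == ["a"]


class TestMca:
    def test_identical_samples_identical_coordinates(self):
        bm = profile_bm([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 1]])
        res = mca_binary(bm)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_total_inertia_closed_form(self, preset_bm):
        """Indicator-matrix MCA total inertia equals J/Q - 1 = 1 exactly."""
        bm, _ = preset_bm
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mca_binary(bm)
        assert res.total_inertia == pytest.approx(1.0, abs=1e-10)

    def test_three_population_separation(self):
        from sklearn.metrics import silhouette_score

        from knotpop.simulate import (PopulationSpec, SyntheticConfig,
                                      simulate_band_matrix)
        f_a = np.array([0.95] * 20 + [0.05] * 20 + [0.5] * 10)
        f_b = np.array([0.05] * 20 + [0.95] * 20 + [0.5] * 10)
        cfg = SyntheticConfig(
            parent_a=PopulationSpec("A", 10, band_freqs=f_a),
            parent_b=PopulationSpec("B", 10, band_freqs=f_b),
            n_hybrids=10, seed=4)
        bm, _ = simulate_band_matrix(cfg)
        res = mca_binary(bm, n_axes=2)
        score = silhouette_score(res.scores, bm.populations)
        assert score > 0.5

    def test_constant_band_dropped(self):
        bm = profile_bm([[1, 1, 0], [1, 0, 1], [1, 0, 0]])
        with pytest.warns(UserWarning, match="constant"):
            res = mca_binary(bm)
        assert not any("b0" in c for c in res.loadings.index)


class TestKruskalWallis:
    @staticmethod
    def traits(groups):
        vals, labels, idx = [], [], []
        for g, (name, xs) in enumerate(groups.items()):
            for i, x in enumerate(xs):
                vals.append(x)
                labels.append(name)
                idx.append(f"{name}{i}")
        data = pd.DataFrame({"t": vals}, index=idx, dtype=float)
        return TraitTable(data, pd.Series(labels, index=idx))

    def test_identical_groups_zero(self):
        tt = self.traits({"A": [1, 2, 3], "B": [1, 2, 3]})
        res = kruskal_wallis(tt)
        assert res.loc["t", "H"] == pytest.approx(0.0)

    def test_hand_computed_h(self):
        tt = self.traits({"A": [1, 2, 3], "B": [10, 11, 12],
                          "C": [20, 21, 22]})
        res = kruskal_wallis(tt)
        assert res.loc["t", "H"] == pytest.approx(7.2)
        assert res.loc["t", "df"] == 2

    def test_monotone_transform_invariance(self):
        tt1 = self.traits({"A": [1, 5, 2], "B": [9, 7, 12]})
        tt2 = self.traits({"A": [np.exp(1), np.exp(5), np.exp(2)],
                           "B": [np.exp(9), np.exp(7), np.exp(12)]})
        assert kruskal_wallis(tt1).loc["t", "H"] == pytest.approx(
            kruskal_wallis(tt2).loc["t", "H"])

    def test_all_identical_values(self):
        tt = self.traits({"A": [3, 3], "B": [3, 3]})
        res = kruskal_wallis(tt)
        assert res.loc["t", "H"] == 0.0 and res.loc["t", "p_value"] == 1.0

    def test_apex_traits_nonsignificant_in_preset(self, preset):
        """The preset's apex characters are built near-identical across
        taxa; blade dimensions differ strongly."""
        from knotpop import simulate_morphology
        traits = simulate_morphology(preset)
        res = kruskal_wallis(traits)
        assert res.loc["blade_length", "p_value"] < 0.01
        assert res.loc["apex_width", "p_value"] > 0.05
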