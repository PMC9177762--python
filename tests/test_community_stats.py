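"""Distance, ordination, permutation-test and ANCOM behaviour."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from magforge import community_stats as cs
from magforge.errors import MagforgeError


def _euclid_dm(points, labels=None):
    labels = labels or [f"s{i}" for i in range(len(points))]
    return cs.DistanceMatrix(labels=labels,
                             data=squareform(pdist(points)),
                             method="euclidean")


class TestQuantifyBins:
    @pytest.mark.parametrize("lengths, depths, expected", [
        ([2000, 2000], [10.0, 20.0], 15.0),
        ([1500], [7.5], 7.5),
        ([1000, 3000], [10.0, 30.0], 25.0),
    ])
    def test_length_weighted_mean(self, lengths, depths, expected):
        contigs = [f"c{i}" for i in range(len(lengths))]
        table = pd.DataFrame({"s1": depths}, index=contigs)
        out = cs.quantify_bins(table, pd.Series(lengths, index=contigs),
                               pd.Series("A", index=contigs))
        assert out.loc["A", "s1"] == pytest.approx(expected)

    def test_zero_length_genome_rejected(self):
        table = pd.DataFrame({"s1": [1.0]}, index=["c0"])
        with pytest.raises(MagforgeError):
            cs.quantify_bins(table, pd.Series({"c0": 0}),
                             pd.Series({"c0": "A"}))


class TestBetaDiversity:
    def test_identical_samples_distance_zero(self):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):0.5,C:2);"))
        table = pd.DataFrame({"s1": [1, 2, 3], "s2": [1, 2, 3]},
                             index=["A", "B", "C"]).astype(float)
        for method in ("bray_curtis", "weighted_unifrac",
                       "unweighted_unifrac"):
            dm = cs.beta_diversity(table, method, tree=tree)
            assert dm.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_taxa_on_disjoint_clades_distance_one(self):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):0.5,(C:1,D:1):0.5);"))
        table = pd.DataFrame({"s1": [1, 1, 0, 0], "s2": [0, 0, 1, 1]},
                             index=list("ABCD")).astype(float)
        for method in ("bray_curtis", "weighted_unifrac"):
            dm = cs.beta_diversity(table, method, tree=tree)
            assert dm.data[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_example(self):
        table = pd.DataFrame({"x": [1, 1, 0], "y": [0, 1, 1]}).astype(float)
        dm = cs.beta_diversity(table, "bray_curtis")
        assert dm.data[0, 1] == pytest.approx(0.5)

    def test_star_tree_closed_form(self):
        """On a star tree with equal branch lengths, weighted UniFrac
        reduces to sum|x-y| / sum(x+y) of relative abundances."""
        tree = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))
        rng = np.random.default_rng(0)
        x, y = rng.random(4), rng.random(4)
        table = pd.DataFrame({"s1": x, "s2": y}, index=list("ABCD"))
        dm = cs.beta_diversity(table, "weighted_unifrac", tree=tree)
        rx, ry = x / x.sum(), y / y.sum()
        expected = np.abs(rx - ry).sum() / (rx + ry).sum()
        assert dm.data[0, 1] == pytest.approx(expected)

    def test_missing_leaf_names_taxon(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1);"))
        table = pd.DataFrame({"s1": [1, 1], "s2": [1, 2]},
                             index=["A", "ZZZ"]).astype(float)
        with pytest.raises(MagforgeError, match="ZZZ"):
            cs.beta_diversity(table, "weighted_unifrac", tree=tree)

    def test_all_zero_sample_rejected(self):
        table = pd.DataFrame({"s1": [1.0, 1.0], "s2": [0.0, 0.0]})
        with pytest.raises(MagforgeError, match="s2"):
            cs.beta_diversity(table, "bray_curtis")

    def test_matches_skbio_on_random_data(self, degraded_community):
        from skbio.diversity import beta_diversity as sk_beta

        _, bundle, _ = degraded_community
        # skbio's UniFrac treats abundances as integer counts
        table = (bundle.abundance.iloc[:, :12] * 100).round()
        table = table.loc[:, table.sum() > 0]
        dm = cs.beta_diversity(table, "weighted_unifrac", tree=bundle.tree)
        sk = sk_beta("weighted_unifrac", table.T.to_numpy(),
                     ids=list(table.columns), taxa=list(table.index),
                     tree=bundle.tree.copy(), normalized=True)
        assert np.abs(dm.data - sk.data).max() < 1e-12


class TestPCoA:
    def test_planar_points_reembedded(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 2))
        res = cs.pcoa(_euclid_dm(pts))
        coords = res.coordinates.to_numpy()
        assert np.abs(squareform(pdist(coords)) -
                      squareform(pdist(pts))).max() < 1e-8

    def test_zero_distances_zero_coordinates(self):
        dm = cs.DistanceMatrix(labels=["a", "b", "c"],
                               data=np.zeros((3, 3)), method="null")
        res = cs.pcoa(dm)
        assert res.coordinates.to_numpy().size == 0 or \
            np.abs(res.coordinates.to_numpy()).max() < 1e-12

    def test_eigenvalues_nonincreasing(self):
        rng = np.random.default_rng(2)
        res = cs.pcoa(_euclid_dm(rng.normal(size=(8, 3))))
        assert (np.diff(res.eigenvalues) <= 1e-9).all()


class TestPermanova:
    def test_observed_f_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        labels = pd.Series(["a"] * 6 + ["b"] * 6,
                           index=[f"s{i}" for i in range(12)])
        dm = _euclid_dm(pts)
        base = cs.permanova(dm, labels, n_perm=9, seed=0).statistic
        perm = rng.permutation(12)
        dm2 = cs.DistanceMatrix(labels=[dm.labels[i] for i in perm],
                                data=dm.data[np.ix_(perm, perm)],
                                method="euclidean")
        assert cs.permanova(dm2, labels, n_perm=9, seed=0).statistic == \
            pytest.approx(base)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 3))
        pts[8:] += 1.5
        labels = ["a"] * 8 + ["b"] * 7
        dm = _euclid_dm(pts)
        mine = cs.permanova(dm, pd.Series(labels, index=dm.labels),
                            n_perm=99, seed=1)
        theirs = sk_permanova(dm.to_skbio(), grouping=labels, permutations=0)
        assert mine.statistic == pytest.approx(theirs["test statistic"])

    def test_separated_clusters_reach_minimum_p(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(20, 3))
        pts[10:] += 5.0
        labels = pd.Series(["a"] * 10 + ["b"] * 10,
                           index=[f"s{i}" for i in range(20)])
        res = cs.permanova(_euclid_dm(pts), labels, n_perm=199, seed=2)
        assert res.p_value == pytest.approx(1 / 200)

    def test_single_group_rejected(self):
        dm = _euclid_dm(np.zeros((4, 2)))
        with pytest.raises(MagforgeError):
            cs.permanova(dm, pd.Series(["a"] * 4, index=dm.labels))


class TestPermdisp:
    def test_equal_dispersion_duplicated_groups(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 2))
        pts2 = np.vstack([pts, pts])
        labels = pd.Series(["a"] * 8 + ["b"] * 8,
                           index=[f"s{i}" for i in range(16)])
        res = cs.permdisp(_euclid_dm(pts2), labels, n_perm=199, seed=3)
        assert np.isfinite(res.statistic)
        assert res.p_value > 0.5

    def test_tripled_dispersion_detected(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(scale=1.0, size=(15, 3)),
                         rng.normal(scale=3.0, size=(15, 3))])
        labels = pd.Series(["a"] * 15 + ["b"] * 15,
                           index=[f"s{i}" for i in range(30)])
        res = cs.permdisp(_euclid_dm(pts), labels, n_perm=199, seed=4)
        assert res.p_value < 0.05


class TestRDA:
    def test_orthogonal_constraint_explains_nothing(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=20)
        scores -= scores.mean()  # response variation lives on centered scores
        response = pd.DataFrame(np.outer(scores, rng.normal(size=5)))
        constraint = np.ones(20).cumsum()
        constraint -= constraint.mean()
        constraint -= (constraint @ scores) / (scores @ scores) * scores
        res = cs.rda(response, pd.DataFrame({"c": constraint}))
        assert res.total_variance_explained < 1e-10

    def test_pc1_constraint_recovers_pc1_variance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(25, 6))
        y = y - y.mean(axis=0)
        u, s, vt = np.linalg.svd(y, full_matrices=False)
        pc1_scores = u[:, 0] * s[0]
        pc1_var = s[0] ** 2 / (y ** 2).sum()
        res = cs.rda(pd.DataFrame(y), pd.DataFrame({"c": pc1_scores}))
        assert res.axis_variance[0] == pytest.approx(pc1_var, abs=1e-8)

    def test_variance_fractions_bounded(self, degraded_community):
        _, bundle, _ = degraded_community
        chem = cs.chemistry_by_sample(bundle.sample_meta, bundle.chemistry)
        response = bundle.abundance.T
        res = cs.rda(response, chem)
        assert ((res.axis_variance >= 0) & (res.axis_variance <= 1)).all()
        assert res.total_variance_explained <= 1 + 1e-12

    def test_collinear_constraints_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        with pytest.raises(MagforgeError, match="collinear"):
            cs.rda(pd.DataFrame(rng.normal(size=(20, 3))),
                   pd.DataFrame({"a": x, "b": 2 * x + 1e-13}))


class TestCorrelationScreen:
    def test_significance_gates(self):
        rng = np.random.default_rng(11)
        ndf = rng.normal(size=30)
        abundance = pd.DataFrame({
            "pos": 2 * ndf + rng.normal(scale=0.5, size=30),
            "neg": -2 * ndf + rng.normal(scale=0.5, size=30),
            "null": rng.normal(size=30),
        }).T
        abundance.columns = [f"s{i}" for i in range(30)]
        chem = pd.DataFrame({"ndf": ndf, "adf": ndf * 0.7,
                             "adl": ndf * 0.3},
                            index=abundance.columns)
        hits = cs.correlation_screen(abundance, chem).set_index(
            ["taxon", "variable"])
        assert hits.loc[("pos", "NDF"), "significant"]
        assert hits.loc[("neg", "NDF"), "significant"]
        assert hits.loc[("neg", "NDF"), "r"] < -0.38
        assert not hits.loc[("null", "NDF"), "significant"]

    def test_strong_r_weak_p_not_significant(self):
        # tiny n: |r| can exceed the gate while p stays above 0.01
        abundance = pd.DataFrame([[1.0, 2.0, 2.5, 3.1]], index=["t"],
                                 columns=list("abcd"))
        chem = pd.DataFrame({"ndf": [1.0, 1.8, 2.9, 3.0],
                             "adf": [1, 1, 2, 2.0],
                             "adl": [0.5, 0.4, 0.8, 1.0]},
                            index=list("abcd"))
        hits = cs.correlation_screen(abundance, chem).set_index(
            ["taxon", "variable"])
        row = hits.loc[("t", "NDF")]
        assert abs(row["r"]) > 0.38 and row["p"] > 0.01
        assert not row["significant"]

    def test_too_few_samples_rejected(self):
        abundance = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        chem = pd.DataFrame({"ndf": [1, 2], "adf": [1, 2], "adl": [1, 2]},
                            index=["a", "b"])
        with pytest.raises(MagforgeError):
            cs.correlation_screen(abundance, chem)


class TestAncom:
    def test_w_range_with_three_taxa(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(rng.lognormal(0, 1, size=(3, 12)),
                              columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
        res = cs.ancom(counts, groups)
        assert res.w.isin([0, 1, 2]).all()

    def test_planted_taxon_attains_max_w(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.lognormal(0, 1, size=(20, 20)),
                              index=[f"t{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(20)])
        counts.iloc[0, 10:] *= 10
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
        res = cs.ancom(counts, groups)
        assert res.detected["t0"]
        assert res.w["t0"] == res.w.max()

    def test_null_data_yields_no_detection(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(rng.lognormal(0, 1, size=(20, 20)),
                              columns=[f"s{i}" for i in range(20)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
        assert not cs.ancom(counts, groups).detected.any()

    def test_too_few_taxa_rejected(self):
        counts = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=counts.columns)
        with pytest.raises(MagforgeError):
            cs.ancom(counts, groups)


class TestHeatmapOrder:
    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame({"s1": [1, 1, 5], "s2": [2, 2, 1],
                            "s3": [3, 3, 4]},
                           index=["r1", "r2", "r3"]).astype(float)
        order = cs.heatmap_order(mat, cluster_columns=False)
        merged_first = order.row_linkage[0]
        assert {int(merged_first[0]), int(merged_first[1])} == {0, 1}
        assert merged_first[2] == pytest.approx(0.0)

    def test_anticorrelated_rows_distance_two(self):
        mat = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        d = cs._spearman_distance(mat, ["a", "b"])
        assert d[0, 1] == pytest.approx(2.0)

    def test_three_row_brute_force_agglomeration(self):
        """Average-linkage merge order matches exhaustive agglomeration."""
        mat = pd.DataFrame({
            "s1": [1.0, 1.1, 9.0], "s2": [2.0, 2.2, 5.0],
            "s3": [3.0, 3.1, 1.0], "s4": [4.0, 4.4, 2.0]},
            index=["a", "b", "c"])
        from scipy.stats import spearmanr
        rows = mat.to_numpy()
        d = {}
        for i in range(3):
            for j in range(i + 1, 3):
                d[(i, j)] = 1 - spearmanr(rows[i], rows[j]).statistic
        first = min(d, key=d.get)  # brute-force: closest pair merges first
        order = cs.heatmap_order(mat, cluster_columns=False)
        assert {int(order.row_linkage[0][0]),
                int(order.row_linkage[0][1])} == set(first)
        # the final merge distance is the average of the remaining pairs
        rest = [v for k, v in d.items() if k != first]
        assert order.row_linkage[1][2] == pytest.approx(np.mean(rest))

    def test_constant_row_gets_unit_distance_with_warning(self):
        mat = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 2.0],
                            "s3": [1.0, 7.0]}, index=["flat", "var"])
        with pytest.warns(UserWarning, match="constant"):
            d = cs._spearman_distance(mat.to_numpy(), list(mat.index))
        assert d[0, 1] == pytest.approx(1.0)
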