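"""Ward clustering, cut selection diagnostics and Dunn's test."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy.stats import norm, rankdata
from skbio import DistanceMatrix

from soilbiome import clustering
from soilbiome.clustering import ClusterSolution
from tests.conftest import random_distance_matrix


# ---------------------------------------------------------------------------
# independent oracles


def ward_oracle(d):
    """Greedy Ward (D2) agglomeration recomputing merge costs from scratch.

    The Ward.D2 cluster distance has the closed form
    h(A, B)^2 = 2 |A||B| / (|A| + |B|) * c2(A, B) with the pseudo-centroid
    gap c2 computed directly from the original squared dissimilarities, so
    this oracle shares no code path with the Lance-Williams recursion.
    """
    d2 = np.asarray(d, dtype=float) ** 2
    clusters = [[i] for i in range(d2.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A, B = clusters[a], clusters[b]
            na, nb = len(A), len(B)
            cross = sum(d2[i, j] for i in A for j in B) / (na * nb)
            within_a = sum(d2[i, j] for i in A for j in A) / (2 * na * na)
            within_b = sum(d2[i, j] for i in B for j in B) / (2 * nb * nb)
            c2 = cross - within_a - within_b
            h = np.sqrt(max(2.0 * na * nb / (na + nb) * c2, 0.0))
            if best is None or h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        merges.append((sorted(clusters[a]), sorted(clusters[b]), h))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (a, b)]
            + [clusters[a] + clusters[b]]
        )
    return merges


def partitions_from_oracle(merges, n, k):
    clusters = [{i} for i in range(n)]
    for left, right, _ in merges[: n - k]:
        merged = set(left) | set(right)
        clusters = [c for c in clusters if not c <= merged] + [merged]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        for i in members:
            labels[i] = lab
    return labels


def same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


def dunn_oracle(values, groups):
    """Rank-sum z statistics recomputed from first principles."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = rankdata(values)
    ties = pd.Series(values).value_counts().to_numpy()
    tie_term = float((ties**3 - ties).sum())
    sigma2 = n * (n + 1) / 12 - tie_term / (12 * (n - 1))
    out = {}
    for g1, g2 in itertools.combinations(sorted(set(groups)), 2):
        r1 = ranks[groups == g1].mean()
        r2 = ranks[groups == g2].mean()
        n1 = (groups == g1).sum()
        n2 = (groups == g2).sum()
        z = (r1 - r2) / np.sqrt(sigma2 * (1 / n1 + 1 / n2))
        out[(g1, g2)] = z
    return out


# ---------------------------------------------------------------------------
# ward_cluster / cut_tree


class TestWard:
    def test_two_sites_single_merge(self):
        dm = DistanceMatrix(np.array([[0.0, 0.7], [0.7, 0.0]]), ids=["a", "b"])
        tree = clustering.ward_cluster(dm)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(0.7)

    def test_nearest_pair_merges_first(self):
        # collinear points 0, 1, 10 -> first merge is {0, 1}
        pts = np.array([0.0, 1.0, 10.0])
        d = np.abs(pts[:, None] - pts[None, :])
        tree = clustering.ward_cluster(DistanceMatrix(d, ids=["p0", "p1", "p2"]))
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_merge_sequence_matches_closed_form_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            dm = random_distance_matrix(rng, 6)
            tree = clustering.ward_cluster(dm)
            oracle = ward_oracle(dm.data)
            np.testing.assert_allclose(
                tree.linkage[:, 2], [m[2] for m in oracle], rtol=1e-9, atol=1e-12
            )
            for k in range(2, 6):
                sol = clustering.cut_tree(tree, k)
                ref = partitions_from_oracle(oracle, 6, k)
                assert same_partition(sol.labels.to_numpy(), ref)

    def test_heights_match_scipy_linkage(self):
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        for _ in range(10):
            dm = random_distance_matrix(rng, 9)
            tree = clustering.ward_cluster(dm)
            Z = sch.linkage(squareform(dm.data, checks=False), method="ward")
            np.testing.assert_allclose(np.sort(tree.linkage[:, 2]), np.sort(Z[:, 2]),
                                       rtol=1e-9)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        dm = random_distance_matrix(rng, 15)
        tree = clustering.ward_cluster(dm)
        assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()

    def test_asymmetric_input_errors(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            clustering.ward_cluster(d)


class TestCutTree:
    @pytest.fixture
    def tree(self):
        rng = np.random.default_rng(5)
        return clustering.ward_cluster(random_distance_matrix(rng, 8))

    def test_k1_single_cluster(self, tree):
        sol = clustering.cut_tree(tree, 1)
        assert sol.labels.nunique() == 1

    def test_kn_singletons(self, tree):
        sol = clustering.cut_tree(tree, 8)
        assert sol.labels.nunique() == 8

    def test_labels_first_appearance_order(self, tree):
        sol = clustering.cut_tree(tree, 3)
        seen = []
        for lab in sol.labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == [1, 2, 3]

    def test_partitions_nest(self, tree):
        for k in range(2, 8):
            fine = clustering.cut_tree(tree, k).labels
            coarse = clustering.cut_tree(tree, k - 1).labels
            # each fine cluster maps into exactly one coarse cluster
            mapping = pd.DataFrame({"fine": fine, "coarse": coarse})
            assert (mapping.groupby("fine")["coarse"].nunique() == 1).all()

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            clustering.cut_tree(tree, 0)
        with pytest.raises(ValueError):
            clustering.cut_tree(tree, 9)


# ---------------------------------------------------------------------------
# silhouette / matrix correlation / fidelity


class TestSilhouette:
    def test_tight_pairs_near_one(self, tight_pairs_dist, tight_pairs_solution):
        widths, mean = clustering.silhouette(tight_pairs_dist, tight_pairs_solution)
        assert mean > 0.9
        # exact: a = 0.01, b = 0.99 for every site
        np.testing.assert_allclose(widths, (0.99 - 0.01) / 0.99)

    def test_equidistant_site_zero(self):
        # site a: own-cluster mean distance equals nearest-other mean
        d = np.array(
            [
                [0.0, 0.5, 0.5, 0.5],
                [0.5, 0.0, 0.2, 0.2],
                [0.5, 0.2, 0.0, 0.1],
                [0.5, 0.2, 0.1, 0.0],
            ]
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        sol = ClusterSolution(k=2, labels=pd.Series([1, 1, 2, 2], index=list("abcd")))
        widths, _ = clustering.silhouette(dm, sol)
        assert widths["a"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_convention(self, tight_pairs_dist):
        sol = ClusterSolution(
            k=3, labels=pd.Series([1, 1, 2, 3], index=["a", "b", "c", "d"])
        )
        widths, _ = clustering.silhouette(tight_pairs_dist, sol)
        assert widths["c"] == 0.0
        assert widths["d"] == 0.0

    def test_single_cluster_errors(self, tight_pairs_dist):
        sol = ClusterSolution(k=1, labels=pd.Series(1, index=["a", "b", "c", "d"]))
        with pytest.raises(ValueError):
            clustering.silhouette(tight_pairs_dist, sol)


class TestMatrixCorrelation:
    def test_perfect_structure_near_one(self, tight_pairs_dist, tight_pairs_solution):
        assert clustering.matrix_correlation(tight_pairs_dist, tight_pairs_solution) > 0.9

    def test_random_labels_mean_near_zero(self):
        rng = np.random.default_rng(77)
        dm = random_distance_matrix(rng, 12)
        vals = []
        for _ in range(200):
            labels = pd.Series(
                rng.permutation([1] * 6 + [2] * 6), index=list(dm.ids)
            )
            sol = ClusterSolution(k=2, labels=labels)
            vals.append(clustering.matrix_correlation(dm, sol))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_reduces_to_point_biserial_for_single_pair(self):
        rng = np.random.default_rng(8)
        dm = random_distance_matrix(rng, 5)
        labels = pd.Series([1, 1, 2, 3, 4], index=list(dm.ids))
        sol = ClusterSolution(k=4, labels=labels)
        iu = np.triu_indices(5, k=1)
        dvec = dm.data[iu]
        bvec = np.ones(len(dvec))
        bvec[0] = 0.0  # the single within-pair (0, 1)
        expected = np.corrcoef(dvec, bvec)[0, 1]
        assert clustering.matrix_correlation(dm, sol) == pytest.approx(expected)


class TestFidelityProfile:
    def make_table(self, rows, sites):
        return pd.DataFrame(rows, index=sites, columns=["otu1", "otu2"])

    def test_perfect_indicator_counts_at_any_threshold(self):
        sites = list("abcd")
        sol = ClusterSolution(k=2, labels=pd.Series([1, 1, 2, 2], index=sites))
        t = self.make_table([[5, 1], [7, 1], [0, 1], [0, 1]], sites)
        count, total = clustering.fidelity_profile(t, sol, indval_threshold=1.0)
        assert count >= 1  # otu1: A=1, B=1 in cluster 1
        count0, _ = clustering.fidelity_profile(t, sol, indval_threshold=0.0)
        assert count0 == 2

    def test_uniform_otu_indval_half(self):
        sites = list("abcd")
        sol = ClusterSolution(k=2, labels=pd.Series([1, 1, 2, 2], index=sites))
        t = pd.DataFrame({"otu1": [3, 3, 3, 3]}, index=sites)
        count, total = clustering.fidelity_profile(t, sol, indval_threshold=0.5)
        assert count == 1 and total == pytest.approx(0.5)
        count_hi, _ = clustering.fidelity_profile(t, sol, indval_threshold=1.0)
        assert count_hi == 0

    def test_threshold_range_validated(self, tight_pairs_solution):
        t = pd.DataFrame({"o": [1, 1, 1, 1]}, index=list("abcd"))
        with pytest.raises(ValueError):
            clustering.fidelity_profile(t, tight_pairs_solution, indval_threshold=1.5)


# ---------------------------------------------------------------------------
# select_cut_level


def planted_chemistry(rng, n_per_group, n_groups=3, sep=6.0):
    centers = sep * np.eye(n_groups, 4)
    rows = []
    labels = []
    for g in range(n_groups):
        rows.append(centers[g] + rng.normal(size=(n_per_group, 4)))
        labels += [g] * n_per_group
    X = np.vstack(rows)
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist((X - X.mean(0)) / X.std(0)))
    ids = [f"s{i}" for i in range(len(labels))]
    return DistanceMatrix(d, ids=ids), np.array(labels)


class TestSelectCutLevel:
    def test_recovers_three_planted_groups(self):
        rng = np.random.default_rng(42)
        dm, labels = planted_chemistry(rng, 15)
        tree = clustering.ward_cluster(dm)
        k, diag = clustering.select_cut_level(
            tree, dm, None, k_range=range(2, 9), min_cluster_size=5
        )
        assert k == 3
        sol = clustering.cut_tree(tree, k)
        assert same_partition(sol.labels.to_numpy(), labels)

    def test_infeasible_min_cluster_size(self):
        rng = np.random.default_rng(1)
        dm = random_distance_matrix(rng, 10)
        tree = clustering.ward_cluster(dm)
        with pytest.raises(ValueError, match="min_cluster_size"):
            clustering.select_cut_level(
                tree, dm, None, k_range=range(2, 5), min_cluster_size=10
            )

    def test_singleton_k_range(self):
        rng = np.random.default_rng(2)
        dm = random_distance_matrix(rng, 10)
        tree = clustering.ward_cluster(dm)
        k, diag = clustering.select_cut_level(
            tree, dm, None, k_range=[2], min_cluster_size=1
        )
        assert k == 2
        assert diag["k"].tolist() == [2]


# ---------------------------------------------------------------------------
# dunn_test


class TestDunn:
    def test_matches_rank_sum_oracle_disjoint_groups(self):
        values = np.concatenate([np.arange(10), np.arange(100, 110)])
        groups = np.array(["lo"] * 10 + ["hi"] * 10)
        out = clustering.dunn_test(values, groups)
        ref = dunn_oracle(values, groups)
        row = out.iloc[0]
        assert row["z"] == pytest.approx(ref[(row["group1"], row["group2"])], abs=1e-10)
        # two-sided normal p, Bonferroni with a single pair
        assert row["p_adjusted"] == pytest.approx(2 * norm.sf(abs(row["z"])), abs=1e-12)

    def test_matches_oracle_with_ties_three_groups(self):
        rng = np.random.default_rng(6)
        values = rng.integers(0, 6, size=24).astype(float)  # heavy ties
        groups = np.repeat(["a", "b", "c"], 8)
        out = clustering.dunn_test(values, groups)
        ref = dunn_oracle(values, groups)
        for _, row in out.iterrows():
            assert row["z"] == pytest.approx(
                ref[(row["group1"], row["group2"])], abs=1e-10
            )

    def test_z_negates_under_group_swap(self):
        values = np.array([1.0, 2, 3, 10, 11, 12])
        g1 = ["a", "a", "a", "b", "b", "b"]
        g2 = ["b", "b", "b", "a", "a", "a"]
        out1 = clustering.dunn_test(values, g1)
        out2 = clustering.dunn_test(values, g2)
        assert out1["z"].iloc[0] == pytest.approx(-out2["z"].iloc[0])
        assert out1["p_adjusted"].iloc[0] == pytest.approx(out2["p_adjusted"].iloc[0])

    def test_tie_correction_engaged(self):
        # all observations tied except one: the tie term must reduce the
        # rank variance below the no-tie value
        values = np.array([5.0, 5, 5, 5, 5, 9])
        groups = ["a", "a", "a", "b", "b", "b"]
        out = clustering.dunn_test(values, groups)
        n = len(values)
        no_tie_var = n * (n + 1) / 12 * (2 / 3)
        se_observed = abs(
            (rankdata(values)[:3].mean() - rankdata(values)[3:].mean())
            / out["z"].iloc[0]
        )
        assert se_observed < np.sqrt(no_tie_var)

    def test_null_familywise_rejection_controlled(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 500
        base = rng.normal(size=24)
        for _ in range(n_rep):
            values = rng.permutation(base)
            groups = np.repeat(["a", "b", "c"], 8)
            out = clustering.dunn_test(values, groups)
            rejections += (out["p_adjusted"] < 0.05).any()
        rate = rejections / n_rep
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            clustering.dunn_test([1.0] * 6, ["a"] * 3 + ["b"] * 3)
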