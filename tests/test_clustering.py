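"""Dimension reduction, distances, hierarchical clustering and iteration."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import itersig as ig
from itersig.clustering import prefilter_genes, relabel_by_size

from conftest import make_matrix


def log_matrix(values, **kw):
    return make_matrix(values, scale=ig.Scale.LOG2_TPM_PLUS1, **kw)


def blobs(rng, sizes, n_features=20, sep=8.0):
    """Well-separated Gaussian blobs; returns (cells x features, labels)."""
    centers = rng.normal(0, 1, size=(len(sizes), n_features))
    centers *= sep / np.linalg.norm(centers, axis=1, keepdims=True)
    xs, labels = [], []
    for i, n in enumerate(sizes):
        xs.append(centers[i] + rng.normal(0, 0.3, size=(n, n_features)))
        labels += [i] * n
    return np.vstack(xs), np.array(labels)


class TestPcaReduce:
    def test_rank_one_data_gives_single_component(self):
        t = np.linspace(0, 1, 10)
        # 10 cells on a line in 3-gene space
        m = log_matrix(np.outer([1.0, 2.0, 3.0], t))
        coords = ig.pca_reduce(m, 0.8)
        assert coords.shape == (10, 1)

    def test_full_variance_gives_cells_minus_one(self, rng):
        m = log_matrix(rng.normal(5, 1, size=(50, 8)))
        coords = ig.pca_reduce(m, 1.0)
        assert coords.shape == (8, 7)

    def test_cumulative_variance_threshold_is_tight(self, rng):
        m = log_matrix(rng.normal(5, 1, size=(30, 50)))
        coords = ig.pca_reduce(m, 0.8)
        x = m.values.T - m.values.T.mean(axis=0)
        eig = np.sort(np.linalg.svd(x, compute_uv=False) ** 2)[::-1]
        cum = np.cumsum(eig) / eig.sum()
        k = coords.shape[1]
        assert cum[k - 1] >= 0.8 - 1e-9
        assert k == 1 or cum[k - 2] < 0.8

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            ig.pca_reduce(log_matrix([[1.0]]), 0.8)


class TestPearsonDistance:
    def test_identical_profiles_distance_zero(self):
        d = ig.pearson_distance(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_distance_two(self):
        d = ig.pearson_distance(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_value(self):
        # r((1,2,3),(1,2,4)) = sqrt(27/28); d = 1 - r ~ 0.0180197
        d = ig.pearson_distance(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]))
        assert d[0, 1] == pytest.approx(1.0 - np.sqrt(27.0 / 28.0), abs=1e-12)

    def test_zero_variance_profile_named(self):
        with pytest.raises(ValueError, match="flatcell"):
            ig.pearson_distance(
                np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), ids=["flatcell", "ok"]
            )

    def test_metric_properties_on_random_input(self, rng):
        x = rng.normal(0, 1, size=(15, 6))
        d = ig.pearson_distance(x)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_matches_brute_force_formula(self, rng):
        x = rng.normal(0, 1, size=(8, 5))
        d = ig.pearson_distance(x)
        for i, j in itertools.combinations(range(8), 2):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert d[i, j] == pytest.approx(1.0 - r, abs=1e-12)


def average_linkage_two_partition_oracle(dist):
    """Brute-force best 2-partition by minimum average between-cluster
    distance is not what UPGMA optimises; instead enumerate the UPGMA
    merge process directly on <= 8 points as an independent oracle."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > 2:
        best, pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if d < best - 1e-12:
                best, pair = d, (a, b)
        a, b = pair
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
            clusters[a] + clusters[b]
        ]
    labels = np.empty(n, dtype=int)
    for k, c in enumerate(clusters):
        labels[c] = k
    return labels


class TestHcluster:
    def test_two_blobs_recovered(self, rng):
        x, truth = blobs(rng, [10, 12])
        d = ig.pearson_distance(x)
        labels = ig.hcluster(d, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        x, _ = blobs(rng, [3, 3])
        labels = ig.hcluster(ig.pearson_distance(x), 6)
        assert len(set(labels)) == 6

    def test_forced_three_point_split(self):
        d = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        labels = ig.hcluster(d, 2)
        assert labels[0] == labels[1] != labels[2]
        # larger cluster gets label 1
        assert labels[0] == 1 and labels[2] == 2

    def test_matches_stepwise_upgma_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, size=(8, 5))
            d = ig.pearson_distance(x)
            mine = ig.hcluster(d, 2)
            oracle = average_linkage_two_partition_oracle(d)
            assert adjusted_rand_score(mine, oracle) == 1.0

    def test_k_out_of_range(self, rng):
        x, _ = blobs(rng, [3, 3])
        with pytest.raises(ValueError):
            ig.hcluster(ig.pearson_distance(x), 1)


def silhouette_oracle(dist, labels):
    """Mean silhouette width computed from first principles."""
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in same])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestChooseK:
    @pytest.mark.parametrize("sizes", [[8, 9], [7, 8, 9]])
    def test_recovers_blob_count(self, rng, sizes):
        x, _ = blobs(rng, sizes)
        d = ig.pearson_distance(x)
        k = ig.choose_k(d, (2, 6))
        assert k == len(sizes)
        # chosen k maximises the from-scratch silhouette over candidates
        from itersig.clustering import _linkage_from_dist
        from scipy.cluster import hierarchy

        link = _linkage_from_dist(d)
        scores = {
            kk: silhouette_oracle(d, hierarchy.fcluster(link, kk, "maxclust"))
            for kk in range(2, 7)
        }
        assert k == max(scores, key=lambda kk: (scores[kk], -kk))

    def test_all_equal_distances_fall_back_to_smallest_k(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.warns(UserWarning):
            k = ig.choose_k(d, (2, 3))
        assert k == 2


class TestIterate:
    def test_single_tight_class_converges(self, rng):
        # one class of cells with identical profiles: every pairwise
        # correlation distance is 0, so no split is meaningful
        profile = rng.gamma(2.0, 2.0, size=40)
        vals = np.tile(profile[:, None], (1, 20))
        m = log_matrix(vals)
        with pytest.warns(UserWarning):
            res = ig.iterate(m, ig.ClusteringConfig(k_range=(2, 4), subcluster=False))
        assert res.converged
        assert len(set(res.final_labels)) <= 2

    def test_default_simulation_recovered(self, default_sim, default_clustering):
        _, truth = default_sim
        res = default_clustering
        ari = adjusted_rand_score(truth.labels_for(res.column_ids), res.final_labels)
        assert ari >= 0.9
        assert res.converged

    def test_permutation_equivariance(self, rng):
        m, _ = ig.simulate_single_cell_matrix(
            ig.SimulationSpec(
                n_genes=200,
                classes=(
                    ig.ClassSpec("A", {"G1": 15}, 15),
                    ig.ClassSpec("B", {"G1": 20}, 15),
                    ig.ClassSpec("C", {"G1": 10}, 15),
                ),
                seed=3,
            )
        )
        perm = rng.permutation(m.n_columns)
        shuffled = m.subset_columns([m.column_ids[i] for i in perm])
        res = ig.iterate(m)
        res_shuffled = ig.iterate(shuffled)
        lookup = dict(zip(res_shuffled.column_ids, res_shuffled.final_labels))
        realigned = np.array([lookup[c] for c in res.column_ids])
        assert adjusted_rand_score(res.final_labels, realigned) == 1.0

    def test_sublabels_refine_clusters(self, default_clustering):
        res = default_clustering
        for lab, sub in zip(res.final_labels, res.final_sublabels):
            assert str(sub).split(".")[0] == str(lab)

    def test_prefilter_drops_rarely_expressed_genes(self):
        m = make_matrix([[0, 0, 0], [1, 0, 0], [2, 3, 0]])
        out = prefilter_genes(m, 2)
        assert out.gene_ids == ("g3",)


class TestFilterMinorClasses:
    def test_threshold_bookkeeping(self):
        labels = np.array([1] * 10 + [2] * 4 + [3] * 6)
        major, excluded = ig.filter_minor_classes(labels, 5)
        assert excluded == [2]
        assert set(major) == {0, 1, 2}
        assert (major == 0).sum() == 4

    def test_all_sizes_large_is_identity_up_to_renumbering(self):
        labels = np.array([2] * 6 + [1] * 5)
        major, excluded = ig.filter_minor_classes(labels, 5)
        assert excluded == []
        assert adjusted_rand_score(labels, major) == 1.0

    def test_retained_cells_keep_co_membership(self, rng):
        labels = rng.integers(1, 6, size=60)
        major, _ = ig.filter_minor_classes(labels, 5)
        kept = major != 0
        assert adjusted_rand_score(labels[kept], major[kept]) == 1.0

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError):
            ig.filter_minor_classes(np.array([1, 1, 2, 2]), 5)


class TestClassFrequencyTable:
    def _design(self, cells, group="G1"):
        return ig.GroupDesign((group,), {group: tuple(cells)})

    def test_single_class_is_hundred_percent(self):
        cells = [f"c{i}" for i in range(8)]
        table = ig.class_frequency_table(
            np.ones(8, dtype=int), self._design(cells), cells
        )
        assert table.loc["G1", "1"] == 100 and table.loc["G1", "Total %"] == 100

    def test_excluded_cells_stay_in_denominator(self):
        cells = [f"c{i}" for i in range(50)]
        labels = np.array([1] * 38 + [0] * 12)
        table = ig.class_frequency_table(labels, self._design(cells), cells)
        assert table.loc["G1", "1"] == 76
        assert table.loc["G1", "Total %"] == 76

    def test_study_truth_reproduces_published_frequencies(self, study_sim):
        # ground-truth labels of the study-shaped design reproduce the
        # published per-group major-class percentage table exactly
        m, truth = study_sim
        labels = truth.labels_for(m.column_ids)
        order = ["ProB", "gdT", "cILC2", "BIM", "BD-ILC1", "L-ILC2"]
        as_int = np.zeros(len(labels), dtype=int)
        for i, cls in enumerate(order, start=1):
            as_int[labels == cls] = i  # minors stay 0 = excluded
        table = ig.class_frequency_table(
            as_int, m.group_design(), m.column_ids, class_names=order
        )
        expected = ig.simulate.table1_expected()
        assert table.loc[list(expected.index), list(expected.columns)].equals(expected)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            ig.class_frequency_table(
                np.array([1]), ig.GroupDesign(("G1",), {"G1": ()}), ["c1"]
            )


class TestTsne:
    def test_deterministic_given_seed(self, rng):
        m = make_matrix(rng.gamma(1, 20, size=(30, 25)))
        genes = list(m.gene_ids[:10])
        a = ig.tsne_embed(m, genes, seed=5)
        b = ig.tsne_embed(m, genes, seed=5)
        assert a.equals(b)

    def test_two_cells_no_crash(self):
        m = make_matrix([[1.0, 5.0], [2.0, 0.0], [4.0, 1.0]])
        out = ig.tsne_embed(m, ["g1", "g2", "g3"], seed=0)
        assert out.shape == (2, 3)

    def test_classes_separate_in_embedding(self, default_sim, default_clustering):
        from sklearn.metrics import silhouette_score

        m, truth = default_sim
        res = default_clustering
        sigs = ig.signatures_for_all_classes(m, res.final_labels, None, 50)
        pooled = ig.pool_training_set(sigs)
        emb = ig.tsne_embed(m, pooled, seed=1)
        coords = emb[["x", "y"]].to_numpy()
        assert silhouette_score(coords, truth.labels_for(m.column_ids)) > 0

    def test_too_few_features_rejected(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            ig.tsne_embed(m, ["g1"], seed=0)


def test_relabel_by_size_orders_descending():
    raw = np.array([7, 7, 3, 3, 3, 9])
    out = relabel_by_size(raw)
    np.testing.assert_array_equal(out, [2, 2, 1, 1, 1, 3])
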