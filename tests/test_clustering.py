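"""Distances, PAM, k-selection indices, ARI and LOO stability."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from nasepi.clustering import (
    adjusted_rand_index,
    calinski_harabasz,
    loo_stability,
    mean_silhouette,
    pairwise_distance,
    pam_cluster,
    pam_exhaustive,
    pcoa_embedding,
    rename_by_size,
    select_k,
)
from nasepi.containers import DistanceMatrix


def ra_frame(cols):
    arr = np.asarray(cols, dtype=float).T
    return pd.DataFrame(arr, columns=[f"S{i}" for i in range(arr.shape[1])])


def dmat(points, metric="euclidean"):
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(np.asarray(points, dtype=float)))
    return DistanceMatrix(d, metric, pd.Index([f"S{i}" for i in range(len(points))]))


class TestDistances:
    def test_identical_profiles_are_zero(self):
        ra = ra_frame([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]])
        for metric in ("jsd", "jsd_sqrt", "bray_curtis", "jaccard"):
            d = pairwise_distance(ra, metric)
            assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support(self):
        ra = ra_frame([[1.0, 0.0], [0.0, 1.0]])
        assert pairwise_distance(ra, "jsd").values[0, 1] == pytest.approx(np.log(2))
        assert pairwise_distance(ra, "bray_curtis").values[0, 1] == pytest.approx(1.0)
        assert pairwise_distance(ra, "jaccard").values[0, 1] == pytest.approx(1.0)

    def test_jsd_hand_value(self):
        ra = ra_frame([[0.5, 0.5], [0.25, 0.75]])
        assert pairwise_distance(ra, "jsd").values[0, 1] == pytest.approx(
            0.03382, abs=1e-4
        )

    def test_jsd_matches_scipy(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(8), size=6).T
        ra = pd.DataFrame(X, columns=[f"S{i}" for i in range(6)])
        ours = pairwise_distance(ra, "jsd").values
        for i in range(6):
            for j in range(i + 1, 6):
                ref = jensenshannon(X[:, i], X[:, j]) ** 2
                assert ours[i, j] == pytest.approx(ref, abs=1e-10)

    def test_jsd_sqrt_triangle_inequality(self):
        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.full(10, 0.5), size=60).T
        ra = pd.DataFrame(X, columns=[f"S{i}" for i in range(60)])
        d = pairwise_distance(ra, "jsd_sqrt").values
        idx = rng.integers(0, 60, size=(10_000, 3))
        i, j, k = idx.T
        assert np.all(d[i, j] <= d[i, k] + d[k, j] + 1e-12)

    def test_unnormalised_columns_rejected(self):
        ra = ra_frame([[0.5, 0.7]])
        with pytest.raises(ValueError, match="sum to one"):
            pairwise_distance(ra, "jsd")


class TestPam:
    def test_two_tight_pairs(self):
        d = dmat([[0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        sol = pam_cluster(d, 2)
        assert sol.labels[0] == sol.labels[1] != sol.labels[2]
        med, cost = pam_exhaustive(d, 2)
        assert sol.total_cost == pytest.approx(cost)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_search_on_clustered_data(self, k):
        # greedy BUILD+SWAP is a local search; on separated clusters it
        # reaches the global optimum (on unstructured points it can stop
        # at the same local optima as the reference R implementation)
        rng = np.random.default_rng(10 + k)
        for _ in range(8):
            centers = rng.normal(size=(k, 2)) * 20
            pts = np.vstack([c + rng.normal(0, 0.5, (8 // k, 2)) for c in centers])
            d = dmat(pts)
            sol = pam_cluster(d, k)
            _, cost = pam_exhaustive(d, k)
            assert sol.total_cost == pytest.approx(cost, abs=1e-10)

    def test_k_equals_n(self):
        d = dmat([[0, 0], [1, 0], [2, 0]])
        sol = pam_cluster(d, 3)
        assert sol.total_cost == 0.0
        assert len(np.unique(sol.labels)) == 3

    def test_duplicate_points_take_lowest_index_medoid(self):
        d = dmat([[0, 0], [0, 0], [5, 0], [5, 0]])
        sol = pam_cluster(d, 2)
        assert set(sol.medoid_indices.tolist()) == {0, 2}

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        d = dmat(rng.normal(size=(30, 3)))
        a = pam_cluster(d, 4)
        b = pam_cluster(d, 4)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoid_indices, b.medoid_indices)

    def test_k_out_of_range(self):
        d = dmat([[0, 0], [1, 0]])
        with pytest.raises(ValueError):
            pam_cluster(d, 1)

    def test_matches_reference_r_implementation(self, tmp_path):
        # cluster::pam runs the same BUILD+SWAP local search; total costs
        # must agree even on instances where the search is suboptimal
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable")
        rng = np.random.default_rng(99)
        costs_py = []
        mats = []
        for i in range(6):
            pts = rng.normal(size=(12, 2))
            d = dmat(pts)
            sol = pam_cluster(d, 3)
            costs_py.append(sol.total_cost)
            np.savetxt(tmp_path / f"D{i}.txt", d.values)
            mats.append(tmp_path / f"D{i}.txt")
        script = tmp_path / "pam.R"
        script.write_text(
            "library(cluster)\n"
            "for (f in commandArgs(trailingOnly=TRUE)) {\n"
            "  D <- as.matrix(read.table(f))\n"
            "  p <- pam(as.dist(D), 3, diss=TRUE)\n"
            "  cat(sprintf('%.12f\\n', p$objective['swap'] * nrow(D)))\n"
            "}\n"
        )
        res = subprocess.run(
            ["Rscript", str(script)] + [str(m) for m in mats],
            capture_output=True, text=True,
        )
        costs_r = [float(v) for v in res.stdout.split()]
        assert np.allclose(costs_py, costs_r, atol=1e-6)


class TestSilhouette:
    def test_duplicate_clusters_score_one(self):
        d = dmat([[0, 0], [0, 0], [9, 0], [9, 0]])
        assert mean_silhouette(d, np.array([1, 1, 2, 2])) == 1.0

    def test_degenerate_identical_points(self):
        d = dmat([[0, 0]] * 4)
        assert mean_silhouette(d, np.array([1, 1, 2, 2])) == 0.0

    def test_hand_computed_configuration(self):
        # points on a line: 0, 1, 10, 12 with labels (1,1,2,2)
        d = dmat([[0, 0], [1, 0], [10, 0], [12, 0]])
        labels = np.array([1, 1, 2, 2])
        # sample 0: a=1, b=(10+12)/2=11 -> 10/11;  sample 1: a=1, b=(9+11)/2=10 -> 9/10
        # sample 2: a=2, b=(10+9)/2=9.5 -> 7.5/9.5; sample 3: a=2, b=(12+11)/2=11.5 -> 9.5/11.5
        expected = np.mean([10 / 11, 9 / 10, 7.5 / 9.5, 9.5 / 11.5])
        assert mean_silhouette(d, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(25, 3))
        d = dmat(pts)
        labels = rng.integers(1, 4, size=25)
        ref = silhouette_score(d.values, labels, metric="precomputed")
        assert mean_silhouette(d, labels) == pytest.approx(ref, abs=1e-10)

    def test_single_cluster_rejected(self):
        d = dmat([[0, 0], [1, 0]])
        with pytest.raises(ValueError):
            mean_silhouette(d, np.array([1, 1]))


class TestCalinskiHarabasz:
    def test_euclidean_embedding_consistency(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(30, 4))
        d = dmat(pts)
        labels = rng.integers(1, 4, size=30)
        ref = calinski_harabasz_score(pts, labels)
        assert calinski_harabasz(d, labels) == pytest.approx(ref, rel=1e-8)

    def test_monotone_in_separation(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        base = [[0, 0], [0.1, 0], [0, 0.1]]
        chis = []
        for sep in (2.0, 20.0):
            pts = base + [[sep, 0], [sep + 0.1, 0], [sep, 0.1]]
            chis.append(calinski_harabasz(dmat(pts), labels))
        assert chis[1] > chis[0] > 1

    def test_random_labels_on_noise_center_near_one(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(30):
            pts = rng.normal(size=(40, 5))
            labels = rng.integers(1, 4, size=40)
            vals.append(calinski_harabasz(dmat(pts), labels))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_all_singletons_rejected(self):
        d = dmat([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            calinski_harabasz(d, np.array([1, 2, 3]))

    def test_pcoa_recovers_euclidean_geometry(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(15, 3))
        d = dmat(pts)
        emb = pcoa_embedding(d)
        ref = dmat(emb).values
        assert np.allclose(ref, d.values, atol=1e-8)


class TestSelectK:
    def test_two_duplicate_clusters(self):
        d = dmat([[0, 0]] * 3 + [[9, 0]] * 3)
        rep = select_k(d, range(2, 5))
        assert rep.chosen_k == 2

    def test_report_covers_requested_range(self):
        rng = np.random.default_rng(11)
        d = dmat(rng.normal(size=(20, 2)))
        rep = select_k(d, range(2, 7))
        assert rep.k_values.tolist() == [2, 3, 4, 5, 6]


class TestARI:
    def test_identical_and_relabelled(self):
        a = np.array([1, 1, 2, 2, 3])
        assert adjusted_rand_index(a, a) == 1.0
        assert adjusted_rand_index(a, np.array([7, 7, 5, 5, 9])) == 1.0

    def test_hand_example(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_random_labelings_center_at_zero(self):
        rng = np.random.default_rng(12)
        vals = [
            adjusted_rand_index(rng.integers(0, 3, 60), rng.integers(0, 3, 60))
            for _ in range(1000)
        ]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestLooStability:
    def test_duplicate_pairs_fully_stable(self):
        d = dmat([[0, 0], [0, 0], [9, 0], [9, 0]])
        full = pam_cluster(d, 2)
        rep = loo_stability(d, full, range(2, 3))
        assert np.all(rep.ari == 1.0)
        assert np.all(rep.selected_k == 2)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal(0, 0.2, (6, 2)), rng.normal(5, 0.2, (6, 2))])
        d = dmat(pts)
        full = pam_cluster(d, 2)
        a = loo_stability(d, full, range(2, 4))
        b = loo_stability(d, full, range(2, 4))
        assert np.array_equal(a.ari, b.ari)
        assert np.array_equal(a.heldout_label, b.heldout_label)


class TestRenameBySize:
    def test_largest_becomes_cluster_one(self):
        d = dmat([[0, 0]] * 5 + [[9, 0]] * 2)
        sol = pam_cluster(d, 2)
        renamed = rename_by_size(sol)
        sizes = renamed.sizes()
        assert sizes[0] == 5 and sizes[1] == 2
        assert np.all(np.diff(renamed.sizes()) <= 0)

    def test_idempotent(self):
        d = dmat([[0, 0]] * 4 + [[9, 0]] * 3)
        sol = rename_by_size(pam_cluster(d, 2))
        again = rename_by_size(sol)
        assert np.array_equal(sol.labels, again.labels)

    def test_equal_sizes_ordered_by_medoid_index(self):
        d = dmat([[0, 0], [0, 0], [9, 0], [9, 0]])
        renamed = rename_by_size(pam_cluster(d, 2))
        assert renamed.medoid_indices.tolist() == [0, 2]
        assert renamed.labels[0] == 1
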