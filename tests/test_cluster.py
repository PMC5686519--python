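"""DBSCAN, silhouette and sweep behavior on precomputed distances."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import silhouette_samples

from bgclust import NOISE, SweepDBSCAN, SweepGrid, dbscan, find_singletons, silhouette, sweep
from bgclust.cluster import ClusterAssignment, default_eps_values, default_minpts_values

from ._utils import canonical_labels, dbscan_oracle, random_distance_matrix, silhouette_oracle


def block_matrix(sizes, within=0.05, between=0.9):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for size in sizes:
        d[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(d, 0.0)
    return d


def test_all_points_far_apart_become_noise():
    d = block_matrix([3], within=0.9)
    asg = dbscan(d, eps=0.1, min_pts=2)
    assert list(asg.labels) == [NOISE, NOISE, NOISE]


def test_two_dense_blocks_form_two_clusters():
    d = block_matrix([4, 4])
    asg = dbscan(d, eps=0.1, min_pts=3)
    assert asg.n_clusters == 2 and asg.n_noise == 0
    assert list(asg.labels) == [0, 0, 0, 0, 1, 1, 1, 1]


def test_parameter_domain_is_validated():
    d = block_matrix([4])
    with pytest.raises(ValueError, match="eps"):
        dbscan(d, eps=1.5, min_pts=2)
    with pytest.raises(ValueError, match="min_pts"):
        dbscan(d, eps=0.5, min_pts=1)


def test_border_point_joins_lowest_index_core_cluster():
    # two triangles {0,1,2} and {3,4,5}; point 6 is within eps of cores 0
    # and 3 only, so it is a border point reachable from both clusters
    d = np.full((7, 7), 0.9)
    for block in ([0, 1, 2], [3, 4, 5]):
        for x in block:
            for y in block:
                d[x, y] = 0.05
    d[6, 0] = d[0, 6] = 0.10
    d[6, 3] = d[3, 6] = 0.10
    np.fill_diagonal(d, 0.0)
    asg = dbscan(d, eps=0.11, min_pts=4)
    assert asg.n_clusters == 2
    assert asg.labels[6] == asg.labels[0] != asg.labels[3]


def test_labels_invariant_under_permutation():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(5, 25))
        d = random_distance_matrix(rng, n)
        perm = rng.permutation(n)
        base = dbscan(d, eps=0.3, min_pts=3).labels
        permuted = dbscan(d[np.ix_(perm, perm)], eps=0.3, min_pts=3).labels
        assert canonical_labels(permuted) == canonical_labels(base[perm])


def test_dbscan_agrees_with_bruteforce_on_blocks():
    d = block_matrix([4, 3, 2], within=0.04, between=0.8)
    for eps, min_pts in [(0.1, 2), (0.1, 3), (0.1, 4), (0.85, 2)]:
        asg = dbscan(d, eps, min_pts)
        assert canonical_labels(asg.labels) == dbscan_oracle(d, eps, min_pts)


def test_silhouette_two_pair_hand_case():
    d = block_matrix([2, 2], within=0.1, between=0.9)
    rep = silhouette(d, [0, 0, 1, 1])
    expected = (0.9 - 0.1) / 0.9
    np.testing.assert_allclose(rep.values, expected)
    assert rep.mean == pytest.approx(expected)


def test_silhouette_perfect_sample_scores_one():
    # two coincident points (a = 0) far from the other cluster (b = 0.9)
    d = block_matrix([2, 2], within=0.0, between=0.9)
    rep = silhouette(d, [0, 0, 1, 1])
    assert list(rep.values) == [1.0, 1.0, 1.0, 1.0]


def test_silhouette_single_cluster_is_undefined_sentinel():
    d = block_matrix([4], within=0.05)
    rep = silhouette(d, [0, 0, 0, 0])
    assert not rep.defined
    assert np.isnan(rep.mean)


def test_silhouette_size1_cluster_scores_zero():
    d = block_matrix([2, 1, 2], within=0.05, between=0.9)
    rep = silhouette(d, [0, 0, 1, 2, 2])
    assert rep.values[2] == 0.0


def test_silhouette_excludes_noise():
    d = block_matrix([2, 2, 1], within=0.05, between=0.9)
    rep = silhouette(d, [0, 0, 1, 1, NOISE])
    assert len(rep.values) == 4 and rep.n_excluded == 1


def test_silhouette_matches_sklearn_without_noise():
    rng = np.random.default_rng(1)
    for _ in range(10):
        n = int(rng.integers(6, 30))
        d = random_distance_matrix(rng, n)
        labels = rng.integers(0, 3, size=n)
        # ensure every cluster has >= 2 members so conventions coincide
        labels[:6] = [0, 0, 1, 1, 2, 2]
        rep = silhouette(d, labels)
        ref = silhouette_samples(d, labels, metric="precomputed")
        np.testing.assert_allclose(rep.values, ref, atol=1e-9)


def test_silhouette_matches_bruteforce_with_noise_and_singletons():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(5, 30))
        d = random_distance_matrix(rng, n)
        labels = rng.integers(-1, 4, size=n)
        rep = silhouette(d, labels)
        oracle = silhouette_oracle(d, labels)
        got = dict(zip((int(i) for i in rep.ids), rep.values))
        assert set(got) == set(oracle)
        for i in oracle:
            assert got[i] == pytest.approx(oracle[i], abs=1e-12)


def test_default_grid_dimensions():
    grid = SweepGrid()
    assert len(grid.eps_values) == 98
    assert grid.eps_values[0] == 0.01 and grid.eps_values[-1] == 0.98
    assert list(grid.minpts_values) == list(range(2, 16))
    assert grid.size == 1372


def test_sweep_recovers_planted_blocks_and_breaks_ties_low():
    d = block_matrix([4, 4], within=0.0, between=1.0)
    best, table = sweep(d, SweepGrid(np.array([0.05, 0.2, 0.5]), np.array([2, 3])))
    assert best.n_clusters == 2 and best.n_noise == 0
    # several parameterizations achieve the same score; ties break to the
    # smallest eps then the smallest min_pts
    assert best.eps == 0.05 and best.min_pts == 2
    assert len(table) == 6
    assert set(table.columns) == {"class", "eps", "minpts", "n_clusters", "n_noise", "mean_silhouette"}


def test_sweep_with_no_clusterable_structure_warns_all_noise():
    d = block_matrix([3], within=0.9)
    with pytest.warns(UserWarning, match="all-noise"):
        best, _ = sweep(d, SweepGrid(np.array([0.1, 0.5]), np.array([2])))
    assert list(best.labels) == [NOISE] * 3


def test_find_singletons_counts_noise_and_size1():
    asg = ClusterAssignment(
        ["a", "b", "c", "d", "e", "f"], [0, 0, 0, 1, 1, NOISE], eps=0.1, min_pts=2
    )
    assert find_singletons([asg]) == {"f"}
    one_cluster = ClusterAssignment(["a", "b", "c"], [0, 0, 0], eps=0.1, min_pts=2)
    assert find_singletons([one_cluster]) == set()
    with_size1 = ClusterAssignment(["a", "b", "c"], [0, 0, 1], eps=0.1, min_pts=2)
    assert find_singletons([with_size1]) == {"c"}


def test_truth_singletons_recovered_at_zero_divergence(zerodiv_collection, zerodiv_clustered):
    _, _, assignments = zerodiv_clustered
    truth = zerodiv_collection.truth
    expected = set(truth.loc[truth["family_id"] == "SINGLETON", "bgc_id"])
    found = find_singletons(assignments)
    # reference records cluster with their family; truth singletons are noise
    assert expected == {s for s in found if not s.startswith("REF_")}


def test_sweep_dbscan_estimator(benchmark_distance):
    est = SweepDBSCAN(
        eps_values=list(default_eps_values()), minpts_values=list(default_minpts_values())
    )
    assert clone(est).get_params() == est.get_params()
    sub = benchmark_distance.iloc[:20, :20]
    labels = est.fit_predict(sub.to_numpy())
    assert labels.shape == (20,)
    assert len(est.sweep_table_) == 1372
    assert 0.0 < est.best_eps_ < 1.0 and est.best_min_pts_ >= 2
    np.testing.assert_array_equal(labels, est.labels_)
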