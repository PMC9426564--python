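import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from coamag.coassembly_clustering import (CoassemblyPlan, cut_dendrogram,
                                          find_optimal_clustering,
                                          find_suboptimal_clustering,
                                          mean_silhouette, plan_from_labels,
                                          ward_cluster)
from coamag.kmer_distance import DistanceMatrix


def planted_matrix(rng, sizes, within=(0.05, 0.15), between=(0.7, 0.9)):
    """Random symmetric matrix with block structure; returns (matrix, labels)."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = within if labels[i] == labels[j] else between
            values[i, j] = values[j, i] = rng.uniform(lo, hi)
    ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(ids, values), labels


def silhouette_two_loop(values: np.ndarray, labels: np.ndarray) -> float:
    """Independent direct-formula oracle (explicit per-sample loops)."""
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([values[i, j] for j in own])
        b = min(
            np.mean([values[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


class TestWardCluster:
    def test_two_leaves_single_merge(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]], dtype=float))
        dendro = ward_cluster(m)
        assert dendro.n_leaves == 2
        assert len(dendro.merge_steps) == 1

    def test_first_merge_is_closest_pair(self):
        values = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dendro = ward_cluster(DistanceMatrix(["a", "b", "c"], values))
        left, right, height, size = dendro.merge_steps[0]
        assert {left, right} == {0, 1}
        assert height == pytest.approx(0.1)
        assert size == 2

    def test_heights_non_decreasing(self, rng):
        m, _ = planted_matrix(rng, [4, 4, 4])
        heights = [h for _, _, h, _ in ward_cluster(m).merge_steps]
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_permutation_invariance_up_to_relabelling(self, rng):
        m, labels = planted_matrix(rng, [3, 4, 5])
        perm = rng.permutation(len(labels))
        m2 = DistanceMatrix([m.sample_ids[i] for i in perm], m.values[np.ix_(perm, perm)])
        labs1 = cut_dendrogram(ward_cluster(m), 3)
        labs2 = cut_dendrogram(ward_cluster(m2), 3)
        # same partition after mapping back through the permutation
        assert adjusted_rand_score(labs1[perm], labs2) == 1.0

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            ward_cluster(DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.2, 0]])))


class TestCutDendrogram:
    def test_extreme_cuts(self, rng):
        m, _ = planted_matrix(rng, [3, 3])
        dendro = ward_cluster(m)
        assert len(set(cut_dendrogram(dendro, 1))) == 1
        assert len(set(cut_dendrogram(dendro, 6))) == 6

    def test_three_point_example(self):
        values = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dendro = ward_cluster(DistanceMatrix(["a", "b", "c"], values))
        labels = cut_dendrogram(dendro, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_out_of_range_k(self, rng):
        m, _ = planted_matrix(rng, [2, 2])
        dendro = ward_cluster(m)
        with pytest.raises(ValueError):
            cut_dendrogram(dendro, 5)

    def test_adjacent_cuts_differ_by_one_split(self, rng):
        m, _ = planted_matrix(rng, [5, 5, 5])
        dendro = ward_cluster(m)
        for k in range(2, 14):
            a = cut_dendrogram(dendro, k)
            b = cut_dendrogram(dendro, k + 1)
            # every cluster at k+1 is contained in one cluster at k,
            # and exactly one cluster at k is split in two
            mapping = {}
            for lab_a, lab_b in zip(a, b):
                mapping.setdefault(lab_b, set()).add(lab_a)
            assert all(len(v) == 1 for v in mapping.values())
            assert len(set(b)) == len(set(a)) + 1


class TestMeanSilhouette:
    def test_two_tight_pairs_worked_example(self):
        values = np.full((4, 4), 0.9)
        np.fill_diagonal(values, 0.0)
        values[0, 1] = values[1, 0] = 0.1
        values[2, 3] = values[3, 2] = 0.1
        m = DistanceMatrix(list("abcd"), values)
        s = mean_silhouette(m, [0, 0, 1, 1])
        assert s == pytest.approx((0.9 - 0.1) / 0.9)

    def test_equidistant_points_score_zero(self):
        values = np.full((4, 4), 0.5)
        np.fill_diagonal(values, 0.0)
        m = DistanceMatrix(list("abcd"), values)
        assert mean_silhouette(m, [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_singleton_convention(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.7], [0.7, 0]], dtype=float))
        assert mean_silhouette(m, [0, 1]) == 0.0

    def test_single_cluster_rejected(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.7], [0.7, 0]], dtype=float))
        with pytest.raises(ValueError):
            mean_silhouette(m, [0, 0])

    def test_matches_two_loop_oracle_and_sklearn(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 41))
            values = rng.random((n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 0.0)
            m = DistanceMatrix([f"s{i}" for i in range(n)], values)
            k = int(rng.integers(2, min(n, 6)))
            labels = rng.integers(0, k, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            ours = mean_silhouette(m, labels)
            assert ours == pytest.approx(silhouette_two_loop(values, labels), abs=1e-12)
            if np.all(np.bincount(labels) > 1):  # sklearn has no singleton rule to disagree on
                assert ours == pytest.approx(
                    silhouette_score(values, labels, metric="precomputed"), abs=1e-9)


class TestFindOptimalClustering:
    def test_recovers_planted_partition(self, rng):
        m, labels = planted_matrix(rng, [4, 4, 4])
        result = find_optimal_clustering(m)
        assert result.optimal_k == 3
        assert adjusted_rand_score(labels, result.labels_by_k[3]) == 1.0
        assert set(result.silhouette_by_k) == set(range(2, 12))

    def test_n3_degenerate_sweep(self):
        values = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        result = find_optimal_clustering(DistanceMatrix(list("abc"), values))
        assert list(result.silhouette_by_k) == [2]
        assert result.optimal_k == 2

    def test_too_few_samples_rejected(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]], dtype=float))
        with pytest.raises(ValueError):
            find_optimal_clustering(m)

    def test_planted_beats_random_partitions(self, rng):
        m, labels = planted_matrix(rng, [5, 5, 5])
        planted_score = mean_silhouette(m, labels)
        for _ in range(50):
            random_labels = rng.integers(0, 3, size=15)
            if len(set(random_labels.tolist())) < 2:
                continue
            assert planted_score >= mean_silhouette(m, random_labels)


class TestFindSuboptimalClustering:
    @staticmethod
    def _result_with_curve(curve: dict[int, float]):
        from coamag.coassembly_clustering import ClusteringResult

        ks = sorted(curve)
        return ClusteringResult(
            sample_ids=[], labels_by_k={k: np.zeros(1) for k in ks},
            silhouette_by_k=curve,
            optimal_k=max(ks, key=lambda k: (curve[k], -k)),
        )

    def test_local_maximum_nearest_target(self):
        # global max at 24, local max at 11, valley between: target 12 -> 11
        curve = {k: 0.1 for k in range(2, 31)}
        curve[11] = 0.5
        curve[24] = 0.8
        result = self._result_with_curve(curve)
        assert find_suboptimal_clustering(result, target_k=12) == 11
        assert result.suboptimal_k == 11

    def test_monotone_decreasing_returns_first_k(self):
        curve = {k: 1.0 / k for k in range(2, 12)}
        result = self._result_with_curve(curve)
        assert find_suboptimal_clustering(result, target_k=9) == 2

    def test_target_at_optimum_returns_optimum(self):
        curve = {2: 0.1, 3: 0.2, 4: 0.9, 5: 0.3}
        result = self._result_with_curve(curve)
        assert find_suboptimal_clustering(result, target_k=4) == 4


class TestPlanFromLabels:
    def test_groups_numbered_by_first_appearance(self):
        plan = plan_from_labels(["s1", "s2", "s3"], [0, 0, 1])
        assert plan.groups == {1: ["s1", "s2"], 2: ["s3"]}

    def test_single_group(self):
        plan = plan_from_labels(["a", "b"], [7, 7])
        assert plan.groups == {1: ["a", "b"]}

    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError):
            CoassemblyPlan(groups={1: ["a"], 3: ["b"]}, source_k=2)  # non-consecutive
        with pytest.raises(ValueError):
            CoassemblyPlan(groups={1: ["a"], 2: ["a"]}, source_k=2)  # overlap
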