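import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from clonelineage.clustering import (
    ClusterAssignment,
    DistanceMatrix,
    adjusted_rand_index,
    cut_clusters,
    detect_unique,
    jaccard_distance,
    subsample_burden,
    ward_cluster,
)


def random_distance(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return DistanceMatrix(ids=[f"s{i}" for i in range(n)], values=v)


class TestJaccard:
    def test_identical_sets_distance_zero(self):
        d = jaccard_distance({"a": {1, 2}, "b": {1, 2}})
        assert d.values[0, 1] == 0

    def test_disjoint_sets_distance_one(self):
        d = jaccard_distance({"a": {1, 2}, "b": {3, 4}})
        assert d.values[0, 1] == 1

    def test_half_overlap(self):
        d = jaccard_distance({"a": {"A", "B", "C"}, "b": {"B", "C", "D"}})
        assert d.values[0, 1] == pytest.approx(0.5)  # 1 - 2/4

    def test_empty_vs_empty_is_one(self):
        d = jaccard_distance({"a": set(), "b": set(), "c": {1}})
        assert d.values[0, 1] == 1

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        sets = {f"s{i}": set(rng.integers(0, 30, size=rng.integers(0, 15)).tolist())
                for i in range(8)}
        d = jaccard_distance(sets)
        ids = d.ids
        for i, j in itertools.combinations(range(len(ids)), 2):
            a, b = sets[ids[i]], sets[ids[j]]
            expected = 1.0 if not (a | b) else 1 - len(a & b) / len(a | b)
            assert d.values[i, j] == pytest.approx(expected)


class TestWard:
    def test_closest_pair_merges_first(self):
        v = np.full((4, 4), 0.8)
        np.fill_diagonal(v, 0)
        v[1, 2] = v[2, 1] = 0.0
        dend = ward_cluster(DistanceMatrix(ids=list("abcd"), values=v))
        assert set(dend.merges[0][:2]) == {1, 2}

    def test_two_samples_single_merge_at_their_distance(self):
        v = np.array([[0, 0.4], [0.4, 0]])
        dend = ward_cluster(DistanceMatrix(ids=["a", "b"], values=v))
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.4)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dend = ward_cluster(random_distance(rng, 10))
            heights = [h for _, _, h, _ in dend.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_merge_sequence_matches_scipy_ward(self):
        """Independent oracle: scipy's Ward (= ward.D2 on distances)."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            dist = random_distance(rng, 7)
            ours = ward_cluster(dist)
            link = hierarchy.linkage(squareform(dist.values), method="ward")
            for (a, b, h, s), row in zip(ours.merges, link):
                assert {a, b} == {int(row[0]), int(row[1])}
                assert h == pytest.approx(row[2])
                assert s == int(row[3])

    def test_partition_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        dist = random_distance(rng, 8)
        perm = rng.permutation(8)
        permuted = DistanceMatrix(
            ids=[dist.ids[i] for i in perm],
            values=dist.values[np.ix_(perm, perm)],
        )
        a1 = cut_clusters(ward_cluster(dist), "fixed_k", k=3)
        a2 = cut_clusters(ward_cluster(permuted), "fixed_k", k=3)
        assert adjusted_rand_index(a1.labels, a2.labels) == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(DistanceMatrix(ids=["a"], values=np.zeros((1, 1))))


class TestCut:
    def test_all_distance_one_gives_singletons(self):
        v = 1 - np.eye(5)
        dist = DistanceMatrix(ids=list("abcde"), values=v)
        assignment = cut_clusters(ward_cluster(dist), "min_within_similarity",
                                  dist=dist, s_min=0.10)
        assert len(assignment.clusters()) == 5

    def test_two_clean_blocks_recovered(self):
        # within-block J ~ 0.4 (d = 0.6), across blocks J = 0 (d = 1)
        v = np.ones((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    v[i, j] = 0.0 if i == j else 0.6
        dist = DistanceMatrix(ids=list("abcdef"), values=v)
        assignment = cut_clusters(ward_cluster(dist), "min_within_similarity",
                                  dist=dist, s_min=0.10)
        clusters = assignment.clusters()
        assert sorted(map(sorted, clusters.values())) == [list("abc"), list("def")]

    def test_fixed_k_equal_n_gives_singletons(self):
        rng = np.random.default_rng(2)
        dist = random_distance(rng, 6)
        assignment = cut_clusters(ward_cluster(dist), "fixed_k", k=6)
        assert len(assignment.clusters()) == 6

    def test_unknown_policy_rejected(self):
        rng = np.random.default_rng(2)
        dist = random_distance(rng, 4)
        with pytest.raises(ValueError):
            cut_clusters(ward_cluster(dist), "no_such_policy")


class TestUnique:
    def test_fully_disjoint_sample_flagged(self):
        sets = {"a": {1, 2, 3}, "b": {1, 2, 4}, "c": {9, 10}}
        dist = jaccard_distance(sets)
        assignment = cut_clusters(ward_cluster(dist), "min_within_similarity",
                                  dist=dist)
        out = detect_unique(dist, assignment, j_max=0.02)
        assert out.unique["c"] and not out.unique["a"] and not out.unique["b"]
        assert out.labels["c"] == "Unique"

    def test_identical_samples_none_unique(self):
        sets = {"a": {1, 2}, "b": {1, 2}, "c": {1, 2}}
        dist = jaccard_distance(sets)
        assignment = cut_clusters(ward_cluster(dist), "min_within_similarity",
                                  dist=dist)
        out = detect_unique(dist, assignment)
        assert not any(out.unique.values())

    def test_simulated_singleton_lines_flagged(self):
        """With one line per founder and no shared sites, all are unique."""
        rng = np.random.default_rng(4)
        sets = {f"l{i}": set(range(100 * i, 100 * i + 40)) for i in range(5)}
        dist = jaccard_distance(sets)
        assignment = cut_clusters(ward_cluster(dist), "min_within_similarity",
                                  dist=dist)
        out = detect_unique(dist, assignment)
        assert all(out.unique.values())


class TestSubsampleBurden:
    def test_fraction_one_identity(self):
        sets = {"a": {1, 2, 3}, "b": {2, 3, 4}}
        assert subsample_burden(sets, 1.0, seed=0) == sets

    def test_exact_site_count_retained(self):
        sets = {"a": set(range(120)), "b": set(range(80, 200))}
        out = subsample_burden(sets, 0.5, seed=1)
        union = set().union(*out.values())
        assert len(union) <= 100  # floor(0.5 * 200) sites drawn
        # each retained call must come from the drawn union subset
        assert out["a"] <= sets["a"] and out["b"] <= sets["b"]

    def test_draw_size_is_floor_of_fraction(self):
        sets = {"a": set(range(200))}
        out = subsample_burden(sets, 0.5, seed=2)
        assert len(out["a"]) == 100

    def test_clustering_degrades_as_burden_drops(self):
        """Median ARI over seeds is non-increasing as sites are removed."""
        from clonelineage.experiments import BURDEN_GROUP_SIZES

        rng = np.random.default_rng(9)
        sets, truth = {}, {}
        counter = 0
        for g, size in enumerate(BURDEN_GROUP_SIZES[:6]):
            founder = list(range(counter, counter + 60))
            counter += 60
            for li in range(size):
                lid = f"G{g}L{li}"
                sets[lid] = {s for s in founder if rng.random() < 0.5}
                truth[lid] = g
        medians = []
        for fraction in (1.0, 0.3, 0.05):
            aris = []
            for seed in range(7):
                sub = subsample_burden(sets, fraction, seed=seed)
                dist = jaccard_distance(sub)
                assignment = cut_clusters(ward_cluster(dist), "fixed_k", k=6)
                aris.append(adjusted_rand_index(
                    truth, {s: assignment.labels[s] for s in truth}))
            medians.append(np.median(aris))
        assert medians[0] >= medians[1] >= medians[2]


def test_redundant_groups_recovered_at_100_mutations():
    """~100 detected mutations per line suffice for exact grouping."""
    from clonelineage.experiments import burden_threshold_experiment

    out = burden_threshold_experiment(
        seed=5, founder_burdens=(200,), n_replicates=5)
    assert out["per_burden_min_ari"][100.0] == 1.0
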