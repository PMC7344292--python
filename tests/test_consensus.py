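"""Cluster-count selection, k-means partitions, connectivity, meta-clustering."""

import numpy as np
import pytest
from sklearn.cluster import KMeans

import confact
from confact.consensus import (
    cluster_representation,
    connectivity_matrix,
    optimal_cluster_count,
    subtype,
    weighted_meta_cluster,
)
from confact.datatypes import FactorRepresentation, Partition
from confact.errors import ValidationError
from confact.metrics import adjusted_rand_index
from confact.rng import derive_seed


def _rep(x):
    return FactorRepresentation(np.asarray(x, dtype=float), np.asarray(x).shape[1])


def _blobs(centers, n_per, sd, seed):
    rng = np.random.default_rng(seed)
    parts = [c + rng.normal(0, sd, (n_per, len(c))) for c in centers]
    labels = np.repeat(np.arange(1, len(centers) + 1), n_per)
    return np.vstack(parts), labels


class TestOptimalClusterCount:
    def test_forced_range_returns_it(self):
        x, _ = _blobs([[0, 0], [5, 5]], 20, 1.0, 0)
        assert optimal_cluster_count(_rep(x), 2, 2, 5, 0) == 2

    def test_three_separated_blobs_found_in_19_of_20_seeds(self):
        centers = [[0, 0], [10, 0], [0, 10]]  # 10-sigma separation at sd=1
        hits = 0
        for seed in range(20):
            x, _ = _blobs(centers, 50, 1.0, seed)
            hits += optimal_cluster_count(_rep(x), 2, 8, 10, seed) == 3
        assert hits >= 19

    def test_plateau_rule_matches_brute_force_index_scan(self):
        """The chosen k is the smallest whose brute-force BSS/TSS gain drops
        below delta; for a structureless high-dimensional blob that is k_min."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (150, 20))
        tss = ((x - x.mean(axis=0)) ** 2).sum()
        r = {}
        for k in range(2, 10):
            best = min(
                KMeans(k, n_init=1, random_state=derive_seed(derive_seed(0, "optk", k), "start", s)).fit(x).inertia_
                for s in range(10)
            )
            r[k] = 1 - best / tss
        expected = next((k for k in range(2, 9) if r[k + 1] - r[k] < 0.05), 8)
        got = optimal_cluster_count(_rep(x), 2, 8, 10, 0)
        assert got == expected == 2

    def test_invalid_range_rejected(self):
        x, _ = _blobs([[0, 0], [5, 5]], 10, 1.0, 0)
        with pytest.raises(ValidationError):
            optimal_cluster_count(_rep(x), 5, 3, 5, 0)


class TestClusterRepresentation:
    def test_two_separated_blobs_recovered_exactly(self):
        x, truth = _blobs([[0, 0], [10, 10]], 40, 1.0, 1)
        p = cluster_representation(_rep(x), 2, 10, 0)
        assert adjusted_rand_index(p.labels, truth) == 1.0

    def test_returned_sse_not_worse_than_any_individual_start(self):
        x, _ = _blobs([[0, 0], [4, 0], [0, 4]], 25, 1.5, 2)
        p = cluster_representation(_rep(x), 3, 12, seed=5)
        for s in range(12):
            km = KMeans(3, n_init=1, random_state=derive_seed(5, "start", s)).fit(x)
            assert p.sse <= km.inertia_ + 1e-9

    def test_determinism_and_canonical_labels(self):
        x, _ = _blobs([[0, 0], [8, 8]], 30, 1.0, 3)
        a = cluster_representation(_rep(x), 2, 5, seed=9)
        b = cluster_representation(_rep(x), 2, 5, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.labels[0] == 1  # first patient defines cluster 1

    def test_k_exceeding_distinct_points_rejected(self):
        x = np.zeros((6, 2))
        x[3:] = 1.0
        with pytest.raises(ValidationError):
            cluster_representation(_rep(x), 3, 5, 0)


class TestConnectivity:
    def test_definition_on_worked_example(self):
        p = Partition(np.array([1, 1, 2]), 2, 0.0)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert np.array_equal(connectivity_matrix(p).values, expected)

    def test_single_cluster_gives_all_ones(self):
        p = Partition(np.ones(4, dtype=int), 1, 0.0)
        assert np.array_equal(connectivity_matrix(p).values, np.ones((4, 4)))


class TestWeightedMetaCluster:
    @staticmethod
    def _ensemble(label_lists):
        parts = [Partition(np.asarray(l), int(max(l)), 0.0) for l in label_lists]
        return [connectivity_matrix(p) for p in parts], parts

    def test_unanimous_ensemble_returns_the_shared_partition(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 3])
        conns, parts = self._ensemble([labels, labels, labels])
        res = weighted_meta_cluster(conns, parts, "auto")
        assert adjusted_rand_index(res.labels, labels) == 1.0
        assert np.isin(res.consensus, [0.0, 1.0]).all()

    def test_majority_of_three_beats_one_dissenter(self):
        rng = np.random.default_rng(0)
        majority = np.repeat([1, 2, 3], 30)
        dissent = rng.integers(1, 4, 90)
        dissent[:3] = [1, 2, 3]  # ensure all ids used
        conns, parts = self._ensemble([majority, majority, majority, dissent])
        res = weighted_meta_cluster(conns, parts, 3)
        assert adjusted_rand_index(res.labels, majority) == 1.0

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        lists = [rng.integers(1, 4, 60) for _ in range(4)]
        for l in lists:
            l[:3] = [1, 2, 3]
        conns, parts = self._ensemble(lists)
        a = weighted_meta_cluster(conns, parts, 3)
        order = [2, 0, 3, 1]
        b = weighted_meta_cluster([conns[i] for i in order], [parts[i] for i in order], 3)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_invariant_under_input_relabeling(self):
        base = np.repeat([1, 2, 3], 20)
        relab = np.choose(base - 1, [3, 1, 2])  # same partition, renamed ids
        conns_a, parts_a = self._ensemble([base, base])
        conns_b, parts_b = self._ensemble([base, relab])
        a = weighted_meta_cluster(conns_a, parts_a, 3)
        b = weighted_meta_cluster(conns_b, parts_b, 3)
        assert np.array_equal(a.labels, b.labels)

    def test_consensus_is_brute_force_mean_of_connectivities(self):
        rng = np.random.default_rng(2)
        lists = []
        for _ in range(5):
            l = rng.integers(1, 4, 40)
            l[:3] = [1, 2, 3]
            lists.append(l)
        conns, parts = self._ensemble(lists)
        res = weighted_meta_cluster(conns, parts, 3)
        brute = sum(c.values for c in conns) / len(conns)
        np.fill_diagonal(brute, 1.0)
        assert np.allclose(res.consensus, brute)

    def test_auto_k_is_mode_of_partition_counts(self):
        lists = [np.repeat([1, 2], 20), np.repeat([1, 2], 20),
                 np.tile([1, 2, 3, 4], 10)]
        conns, parts = self._ensemble(lists)
        res = weighted_meta_cluster(conns, parts, "auto")
        assert res.k_final == 2

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            weighted_meta_cluster([], [], 2)
        conns, parts = self._ensemble([np.repeat([1, 2], 10)])
        short_conns, short_parts = self._ensemble([np.repeat([1, 2], 5)])
        with pytest.raises(ValidationError):
            weighted_meta_cluster(conns + short_conns, parts + short_parts, 2)


class TestSubtypePipeline:
    def test_recovers_planted_subtypes(self, small_cohort):
        res = subtype(small_cohort.omics)
        assert adjusted_rand_index(res.labels, small_cohort.true_labels) >= 0.9

    def test_same_seed_gives_identical_result(self, small_cohort):
        cfg = confact.RunConfig(seed=4)
        a = subtype(small_cohort.omics, cfg)
        b = subtype(small_cohort.omics, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.consensus, b.consensus)

    def test_single_omics_input_runs(self, small_cohort):
        res = subtype([small_cohort.omics[0]])
        assert res.k_final >= 2
        assert len(res.labels) == small_cohort.omics[0].n_patients

    def test_patient_row_order_is_irrelevant(self, small_cohort):
        m0, m1 = small_cohort.omics
        rng = np.random.default_rng(0)
        perm = rng.permutation(m1.n_patients)
        m1_shuffled = confact.OmicsMatrix(
            m1.values[perm], [m1.patient_ids[i] for i in perm], m1.feature_ids, m1.data_type
        )
        a = subtype([m0, m1])
        b = subtype([m0, m1_shuffled])
        assert np.array_equal(a.labels, b.labels)

    def test_mismatched_patient_sets_rejected(self, small_cohort):
        m0, m1 = small_cohort.omics
        truncated = confact.OmicsMatrix(
            m1.values[:-1], m1.patient_ids[:-1], m1.feature_ids, m1.data_type
        )
        with pytest.raises(ValidationError):
            subtype([m0, truncated])
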