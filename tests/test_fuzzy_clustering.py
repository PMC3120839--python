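import numpy as np
import pytest

import ctfingerprint as cf
from ctfingerprint.errors import ValidationError

from conftest import expr, separated3_ct


@pytest.fixture(scope="module")
def two_clouds():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.2, (40, 3))
    b = rng.normal(4.0, 0.2, (40, 3))
    return expr(np.vstack([a, b]), clamp=10)


class TestFcmFit:
    def test_k1_degenerate(self, two_clouds):
        m = cf.fcm_fit(two_clouds, 1, 2.0, seed=0, n_restarts=1)
        np.testing.assert_allclose(m.centroids[0], two_clouds.values.mean(axis=0),
                                   atol=1e-9)
        assert np.all(m.memberships == 1.0)
        d2 = ((two_clouds.values - m.centroids[0]) ** 2).sum()
        assert m.objective == pytest.approx(d2)

    def test_separated_clouds_near_hard_membership(self, two_clouds):
        m = cf.fcm_fit(two_clouds, 2, 1.5, seed=0, n_restarts=5)
        assert np.all(m.memberships.max(axis=1) > 0.99)
        labels = m.hard_labels
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_membership_rows_sum_to_one(self, signal_expr):
        m = cf.fcm_fit(signal_expr, 4, 1.8, seed=1, n_restarts=3)
        np.testing.assert_allclose(m.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_fit_is_reproducible(self, signal_expr):
        a = cf.fcm_fit(signal_expr, 3, 1.5, seed=5, n_restarts=3)
        b = cf.fcm_fit(signal_expr, 3, 1.5, seed=5, n_restarts=3)
        np.testing.assert_array_equal(a.memberships, b.memberships)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_cell_order_permutation_same_partition(self, signal_expr):
        rng = np.random.default_rng(9)
        perm = rng.permutation(signal_expr.n_cells)
        shuffled = signal_expr.subset_cells(perm)
        a = cf.fcm_fit(signal_expr, 3, 1.5, seed=2, n_restarts=5)
        b = cf.fcm_fit(shuffled, 3, 1.5, seed=3, n_restarts=5)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a.hard_labels[perm], b.hard_labels) == 1.0

    def test_duplicated_cells_duplicate_memberships(self, two_clouds):
        doubled = cf.ExpressionMatrix(
            np.vstack([two_clouds.values, two_clouds.values]),
            [f"c{i}" for i in range(2 * two_clouds.n_cells)],
            two_clouds.gene_ids, clamp_bound=10)
        a = cf.fcm_fit(two_clouds, 2, 1.5, seed=0, n_restarts=5)
        b = cf.fcm_fit(doubled, 2, 1.5, seed=0, n_restarts=5)
        n = two_clouds.n_cells
        np.testing.assert_allclose(b.memberships[:n], b.memberships[n:], atol=1e-6)
        # same partition structure as the single-copy fit
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(np.tile(a.hard_labels, 2), b.hard_labels) == 1.0

    def test_m_to_one_limit_matches_kmeans(self, signal_expr):
        km = cf.kmeans_fit(signal_expr, 3, n_restarts=5, seed=1)
        fc = cf.fcm_fit(signal_expr, 3, 1.01, n_restarts=5, seed=1)
        assert cf.partition_agreement(km, fc) >= 0.99

    def test_m_to_infinity_limit_uniform(self, signal_expr):
        fc = cf.fcm_fit(signal_expr, 3, 50.0, n_restarts=2, seed=1)
        assert np.abs(fc.memberships - 1 / 3).max() < 0.01

    def test_objective_non_increasing(self, signal_expr):
        # best-restart objective from more iterations can't exceed fewer
        short = cf.fcm_fit(signal_expr, 3, 1.5, seed=4, n_restarts=1, max_iter=3)
        full = cf.fcm_fit(signal_expr, 3, 1.5, seed=4, n_restarts=1)
        assert full.objective <= short.objective + 1e-9

    def test_invalid_k_or_m_rejected(self, two_clouds):
        with pytest.raises(ValidationError):
            cf.fcm_fit(two_clouds, 0, 1.5)
        with pytest.raises(ValidationError):
            cf.fcm_fit(two_clouds, 200, 1.5)
        with pytest.raises(ValidationError):
            cf.fcm_fit(two_clouds, 2, 1.0)

    def test_metric_robustness_on_separated_fixture(self):
        ct, _ = separated3_ct(11)
        e = cf.normalize(ct)
        fits = [cf.fcm_fit(e, 3, 1.5, metric=met, seed=3, n_restarts=5)
                for met in (cf.EUCLIDEAN, cf.MANHATTAN, cf.minkowski(3.0))]
        for i in range(3):
            for j in range(i + 1, 3):
                assert cf.partition_agreement(fits[i], fits[j]) >= 0.9


class TestKmeansFit:
    def test_k_equals_n_cells_zero_objective(self):
        rng = np.random.default_rng(1)
        e = expr(rng.normal(size=(6, 2)), clamp=10)
        m = cf.kmeans_fit(e, 6, n_restarts=10, seed=0)
        assert m.objective == pytest.approx(0.0, abs=1e-18)

    def test_three_cloud_fixture_recovers_truth(self):
        ct, truth = separated3_ct(5)
        e = cf.normalize(ct)
        m = cf.kmeans_fit(e, 3, n_restarts=5, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, m.hard_labels) == 1.0


class TestProjection:
    def test_projecting_training_population_is_consistent(self, signal_expr):
        m = cf.fcm_fit(signal_expr, 3, 1.5, seed=0, n_restarts=5)
        u, occ = cf.project_population(m, signal_expr)
        np.testing.assert_allclose(u, m.memberships, atol=1e-9)
        np.testing.assert_allclose(occ.fractions, m.occupancy().fractions)

    def test_cell_at_centroid_gets_full_membership(self, signal_expr):
        m = cf.fcm_fit(signal_expr, 3, 1.5, seed=0, n_restarts=5)
        probe = cf.ExpressionMatrix(m.centroids[[1]], ["probe"],
                                    signal_expr.gene_ids, clamp_bound=10)
        u, _ = cf.project_population(m, probe)
        np.testing.assert_allclose(u[0], [0.0, 1.0, 0.0], atol=1e-12)

    def test_gene_panel_mismatch_rejected(self, signal_expr):
        m = cf.fcm_fit(signal_expr, 3, 1.5, seed=0, n_restarts=2)
        bad = cf.ExpressionMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "y"],
                                  clamp_bound=10)
        with pytest.raises(ValidationError):
            cf.project_population(m, bad)

    def test_skewed_population_occupancy_recovered(self, fixture_trio,
                                                   normalized_trio, signal_expr):
        """Projection onto cd34lo centroids recovers cd34hi's generating
        archetype weights within multinomial error (+/- 3 points)."""
        m = cf.fcm_fit(signal_expr, 3, 1.05, seed=0, n_restarts=5)
        # align clusters to archetypes by majority vote on the training truth
        truth = fixture_trio.labels["cd34lo"]
        mapping = {}
        for c in range(3):
            members = truth[m.hard_labels == c]
            mapping[c] = np.bincount(members, minlength=3).argmax()
        assert sorted(mapping.values()) == [0, 1, 2]
        hi = normalized_trio["cd34hi"].subset_genes(fixture_trio.signal_genes)
        _, occ = cf.project_population(m, hi)
        realized = np.bincount(fixture_trio.labels["cd34hi"], minlength=3) / 300
        for c in range(3):
            assert abs(occ.fractions[c] - realized[mapping[c]]) <= 0.03
        # rare archetype: occupancy within 3 points of the 0.04 weight itself
        arch0 = next(c for c, a in mapping.items() if a == 0)
        assert abs(occ.fractions[arch0] - 0.04) <= 0.03


class TestPartitionAgreement:
    def test_identical_partitions_score_one(self, signal_expr):
        m = cf.kmeans_fit(signal_expr, 3, n_restarts=3, seed=0)
        assert cf.partition_agreement(m, m) == 1.0

    def test_label_permutation_invariance(self, signal_expr):
        m = cf.kmeans_fit(signal_expr, 3, n_restarts=3, seed=0)
        relabeled = cf.ClusterModel(m.centroids[::-1], m.memberships[:, ::-1],
                                    m.m, m.k, m.metric, m.objective, m.n_iter,
                                    m.converged, m.seed, m.cell_ids, m.gene_ids)
        assert cf.partition_agreement(m, relabeled) == 1.0

    def test_random_partitions_score_near_zero(self):
        rng = np.random.default_rng(3)
        from sklearn.metrics import adjusted_rand_score
        hits = 0
        for _ in range(40):
            a = rng.integers(0, 3, 300)
            b = rng.integers(0, 3, 300)
            hits += abs(adjusted_rand_score(a, b)) < 0.05
        assert hits / 40 >= 0.95

    def test_cell_mismatch_rejected(self, signal_expr):
        m = cf.kmeans_fit(signal_expr, 3, n_restarts=2, seed=0)
        other = cf.kmeans_fit(signal_expr.subset_cells(range(100)), 3,
                              n_restarts=2, seed=0)
        with pytest.raises(ValidationError):
            cf.partition_agreement(m, other)


def test_distance_metric_aliases():
    assert cf.DistanceMetric("euclidean").p == 2.0
    assert cf.DistanceMetric("manhattan").p == 1.0
    assert cf.minkowski(3.0).p == 3.0
    with pytest.raises(ValidationError):
        cf.DistanceMetric("cosine")
    with pytest.raises(ValidationError):
        cf.minkowski(0.5)
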