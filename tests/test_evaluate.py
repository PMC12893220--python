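import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sidmgf import evaluate as ev
from sidmgf.datatypes import ActivityMatrix, DomainLabels, ExpressionMatrix

from naive_oracles import (
    exact_ranksum_pvalue,
    naive_ari,
    naive_davies_bouldin,
    naive_nmi,
    naive_silhouette,
)


def _labels(values):
    return DomainLabels([f"c{i}" for i in range(len(values))],
                        np.asarray(values, dtype=int))


class TestAri:
    def test_identical_partitions(self):
        assert ev.ari(_labels([0, 0, 1, 1]), _labels([0, 0, 1, 1])) == 1.0

    def test_crossed_partitions_hand_value(self):
        # contingency all-ones: (0 - 2/3) / (2 - 2/3) = -0.5
        assert ev.ari(_labels([1, 1, 2, 2]), _labels([1, 2, 1, 2])) == pytest.approx(-0.5)

    def test_single_cluster_prediction_is_chance(self):
        assert ev.ari(_labels([1, 1, 2, 2]), _labels([0, 0, 0, 0])) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.ari(_labels([0, 1]), _labels([0, 1, 1]))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 30))
        a = r.integers(0, 4, size=n)
        b = r.integers(0, 4, size=n)
        assert ev.ari(_labels(a), _labels(b)) == pytest.approx(
            naive_ari(a, b), abs=1e-12
        )


class TestNmi:
    def test_identical_partitions(self):
        assert ev.nmi(_labels([0, 1, 1, 2]), _labels([0, 1, 1, 2])) == 1.0

    def test_independent_balanced_design_zero(self):
        assert ev.nmi(_labels([1, 1, 2, 2]), _labels([1, 2, 1, 2])) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_cluster_both_sides(self):
        assert ev.nmi(_labels([0, 0, 0]), _labels([1, 1, 1])) == 1.0

    def test_matches_entropy_oracle(self, rng):
        a = rng.integers(0, 3, size=8)
        b = rng.integers(0, 3, size=8)
        assert ev.nmi(_labels(a), _labels(b)) == pytest.approx(
            naive_nmi(a, b), abs=1e-10
        )


class TestPairwiseF1:
    def test_identical_partitions(self):
        assert ev.pairwise_f1(_labels([0, 0, 1]), _labels([0, 0, 1])) == 1.0

    def test_all_merged_prediction(self):
        # P = 2/6, R = 1 -> F1 = 0.5
        assert ev.pairwise_f1(
            _labels([1, 1, 2, 2]), _labels([1, 1, 1, 1])
        ) == pytest.approx(0.5)

    def test_crossed_partitions_no_true_positives(self):
        assert ev.pairwise_f1(_labels([1, 1, 2, 2]), _labels([1, 2, 1, 2])) == 0.0

    def test_singleton_prediction_warns(self):
        with pytest.warns(UserWarning):
            out = ev.pairwise_f1(_labels([0, 0, 1, 1]), _labels([0, 1, 2, 3]))
        assert out == 0.0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_external_metrics_invariant_to_relabeling(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 25))
    truth = r.integers(0, 3, size=n)
    pred = r.integers(0, 3, size=n)
    perm = r.permutation(4)
    relabeled = perm[pred]
    for metric in (ev.ari, ev.nmi, ev.pairwise_f1):
        assert metric(_labels(truth), _labels(pred)) == pytest.approx(
            metric(_labels(truth), _labels(relabeled)), abs=1e-12
        )


def test_metrics_are_one_iff_same_partition(rng):
    truth = rng.integers(0, 3, size=12)
    same = (truth + 1) % 3  # relabeling of the same partition
    other = truth.copy()
    other[0] = (other[0] + 1) % 3
    for metric in (ev.ari, ev.nmi, ev.pairwise_f1):
        assert metric(_labels(truth), _labels(same)) == pytest.approx(1.0)
        assert metric(_labels(truth), _labels(other)) < 1.0


class TestSilhouetteDb:
    def test_two_tight_far_blobs(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.01, size=(10, 2)), rng.normal(50, 0.01, size=(10, 2))]
        )
        lab = _labels([0] * 10 + [1] * 10)
        sc, db = ev.silhouette_db(X, lab)
        assert sc > 0.99
        assert db < 0.01

    def test_relabeling_invariance(self, rng):
        X = rng.normal(size=(12, 3))
        lab = rng.integers(0, 3, size=12)
        s1 = ev.silhouette_db(X, _labels(lab))
        s2 = ev.silhouette_db(X, _labels((lab + 1) % 3))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_six_point_hand_instance(self):
        X = np.array(
            [[0.0, 0], [0.5, 0], [0.2, 0.4], [5.0, 5], [5.5, 5], [5.1, 5.6]]
        )
        lab = np.array([0, 0, 0, 1, 1, 1])
        sc, db = ev.silhouette_db(X, _labels(lab))
        assert sc == pytest.approx(naive_silhouette(X, lab), abs=1e-10)
        assert db == pytest.approx(naive_davies_bouldin(X, lab), abs=1e-10)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.silhouette_db(rng.normal(size=(5, 2)), _labels([0] * 5))


class TestLeiden:
    def test_two_far_blobs_fully_recovered(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, size=(30, 4)), rng.normal(30, 0.1, size=(30, 4))]
        )
        truth = _labels([0] * 30 + [1] * 30)
        lab = ev.leiden_cluster(X, n_domains=2, seed=0)
        assert ev.ari(truth, _labels(lab.labels)) == 1.0

    def test_cluster_count_monotone_in_resolution(self, rng):
        X = rng.normal(size=(60, 5))
        counts = [
            ev.leiden_cluster(X, resolution=res, seed=0).n_domains
            for res in (0.05, 0.3, 1.0, 2.5)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 4))
        l1 = ev.leiden_cluster(X, resolution=1.0, seed=5)
        l2 = ev.leiden_cluster(X, resolution=1.0, seed=5)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_exactly_one_selector_required(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            ev.leiden_cluster(X)
        with pytest.raises(ValueError):
            ev.leiden_cluster(X, n_domains=2, resolution=1.0)

    def test_more_domains_than_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.leiden_cluster(rng.normal(size=(5, 2)), n_domains=9)


class TestWilcoxonMarkers:
    def _expr(self, counts):
        counts = np.asarray(counts, float)
        n, g = counts.shape
        return ExpressionMatrix(
            counts, [f"c{i}" for i in range(n)],
            [f"g{j}" for j in range(g)],
            np.zeros((n, 2)),
        )

    def test_exclusive_gene_tops_its_domain(self, rng):
        counts = rng.poisson(1.0, size=(20, 5)).astype(float)
        lab = np.array([0] * 10 + [1] * 10)
        counts[lab == 0, 3] += 50  # marker for domain 0
        table = ev.wilcoxon_markers(self._expr(counts), _labels(lab))
        top = table[table.domain == 0].iloc[0]
        assert top.gene == "g3"
        assert top.statistic > 0

    def test_matches_exact_enumeration_three_vs_three(self):
        x = [1.0, 5.0, 3.0]
        y = [2.0, 0.5, 0.7]
        counts = np.array([x + y]).T
        lab = np.array([0, 0, 0, 1, 1, 1])
        table = ev.wilcoxon_markers(self._expr(counts), _labels(lab))
        p_normal = table[table.domain == 0].iloc[0].pval
        p_exact = exact_ranksum_pvalue(x, y)
        # normal approximation vs exact enumeration: same scale
        assert p_normal == pytest.approx(p_exact, abs=0.12)

    def test_permutation_invariance(self, rng):
        counts = rng.poisson(3.0, size=(12, 4)).astype(float)
        lab = rng.integers(0, 2, size=12)
        while len(np.unique(lab)) < 2 or min(np.bincount(lab)) < 2:
            lab = rng.integers(0, 2, size=12)
        t1 = ev.wilcoxon_markers(self._expr(counts), _labels(lab))
        perm = rng.permutation(12)
        e2 = ExpressionMatrix(
            counts[perm], [f"c{i}" for i in range(12)],
            [f"g{j}" for j in range(4)], np.zeros((12, 2)),
        )
        t2 = ev.wilcoxon_markers(e2, _labels(lab[perm]))
        merged = t1.merge(t2, on=["domain", "gene"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged.statistic_a, merged.statistic_b, atol=1e-10
        )


class TestDomainActivitySummary:
    def _activity(self, scores):
        scores = np.asarray(scores, float)
        return ActivityMatrix(
            scores, [f"c{i}" for i in range(len(scores))],
            [f"p{j}" for j in range(scores.shape[1])],
        )

    def test_identical_domains_correlate_perfectly(self):
        scores = np.tile([0.5, -0.2, 0.1], (6, 1))
        lab = _labels([0, 0, 0, 1, 1, 1])
        _, corr, _ = ev.domain_activity_summary(self._activity(scores), lab)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_correlation_matrix_symmetric_unit_diagonal(self, rng):
        scores = np.clip(rng.normal(0, 0.3, size=(12, 5)), -1, 1)
        lab = _labels(rng.integers(0, 3, size=12))
        _, corr, _ = ev.domain_activity_summary(self._activity(scores), lab)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0, atol=1e-12)

    def test_three_domain_hand_pearson(self):
        scores = np.array(
            [[0.1, 0.9, -0.5], [0.3, 0.7, -0.3],
             [-0.2, 0.1, 0.8], [0.0, 0.3, 0.6],
             [0.9, -0.9, 0.0], [0.7, -0.7, 0.2]]
        )
        lab = _labels([0, 0, 1, 1, 2, 2])
        med, corr, frac = ev.domain_activity_summary(self._activity(scores), lab)
        m0 = np.median(scores[:2], axis=0)
        m1 = np.median(scores[2:4], axis=0)
        expected = np.corrcoef(m0, m1)[0, 1]
        assert corr.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert frac.iloc[0, 0] == pytest.approx(1.0)  # both cells positive


class TestUmap:
    def test_shape_and_determinism(self, rng):
        X = rng.normal(size=(30, 6))
        p1 = ev.umap_project(X, seed=3)
        p2 = ev.umap_project(X, seed=3)
        assert p1.shape == (30, 2)
        np.testing.assert_allclose(p1, p2)

    def test_small_n_pca_fallback(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.warns(UserWarning, match="principal"):
            p = ev.umap_project(X, seed=0)
        assert p.shape == (6, 2)

    def test_planted_blobs_linearly_separable(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.2, size=(25, 5)), rng.normal(20, 0.2, size=(25, 5))]
        )
        y = np.array([0] * 25 + [1] * 25)
        proj = ev.umap_project(X, seed=1)
        from sklearn.linear_model import LogisticRegression

        acc = LogisticRegression().fit(proj, y).score(proj, y)
        assert acc == 1.0
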