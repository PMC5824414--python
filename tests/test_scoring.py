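import numpy as np
import pytest

from gimda import (
    AssociationMatrix,
    Config,
    GimdaError,
    build_feature_matrix,
    fit_weights,
    predict,
    rank_candidates,
    score_all,
)
from gimda.census import IsomerCountTensor, normalize_counts
from gimda.scoring import FeatureMatrix, WeightVector, precompute_semantic


def tensor_from(norm: np.ndarray) -> IsomerCountTensor:
    t = IsomerCountTensor(norm.copy())
    t.normalized = norm
    return t


def simple_assoc():
    return AssociationMatrix(
        np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8),
        ["d1", "d2"],
        ["m1", "m2", "m3"],
    )


class TestFeatureMatrix:
    def test_empty_partner_set_gives_zero_column(self):
        assoc = AssociationMatrix(
            np.array([[0, 0], [1, 0]], dtype=np.int8), ["d1", "d2"], ["m1", "m2"]
        )
        norm = np.random.default_rng(0).random((28, 2, 2))
        fm = build_feature_matrix(tensor_from(norm), assoc, "mirna_graph")
        # disease d1 knows no miRNAs: its pair columns are empty sums
        assert np.all(fm.values[:, :2] == 0.0)

    def test_single_partner_copies_normalized_row(self):
        assoc = AssociationMatrix(
            np.array([[1, 0], [0, 0]], dtype=np.int8), ["d1", "d2"], ["m1", "m2"]
        )
        norm = np.random.default_rng(1).random((28, 2, 2))
        fm = build_feature_matrix(tensor_from(norm), assoc, "mirna_graph")
        # P(d1) = {m1}: the column of pair (d1, m2) is norm[:, m1, m2]
        np.testing.assert_allclose(fm.values[:, 1], norm[:, 0, 1])

    def test_features_additive_over_partner_set(self):
        norm = np.random.default_rng(2).random((28, 3, 3))
        a1 = AssociationMatrix(
            np.array([[1, 0, 0]], dtype=np.int8), ["d"], ["m1", "m2", "m3"]
        )
        a2 = AssociationMatrix(
            np.array([[0, 1, 0]], dtype=np.int8), ["d"], ["m1", "m2", "m3"]
        )
        a12 = AssociationMatrix(
            np.array([[1, 1, 0]], dtype=np.int8), ["d"], ["m1", "m2", "m3"]
        )
        f1 = build_feature_matrix(tensor_from(norm), a1, "mirna_graph").values
        f2 = build_feature_matrix(tensor_from(norm), a2, "mirna_graph").values
        f12 = build_feature_matrix(tensor_from(norm), a12, "mirna_graph").values
        np.testing.assert_allclose(f12, f1 + f2)

    def test_disease_side_sums_over_known_diseases(self):
        assoc = simple_assoc()
        norm = np.random.default_rng(3).random((28, 2, 2))
        fd = build_feature_matrix(tensor_from(norm), assoc, "disease_graph")
        # Q(m1) = {d1}; the column of pair (d2, m1) is norm[:, d1, d2]
        np.testing.assert_allclose(fd.values[:, 3], norm[:, 0, 1])

    def test_unnormalized_tensor_rejected(self):
        with pytest.raises(GimdaError, match="normalis"):
            build_feature_matrix(
                IsomerCountTensor(np.zeros((28, 2, 2))), simple_assoc(), "mirna_graph"
            )


class TestFitWeights:
    def test_exact_recovery_at_lambda_zero(self):
        rng = np.random.default_rng(4)
        x = rng.random((28, 300))
        v_true = rng.normal(size=28)
        fm = FeatureMatrix(x, [("d", str(i)) for i in range(300)], "mirna_graph")
        v = fit_weights(fm, x.T @ v_true, 0.0)
        np.testing.assert_allclose(v.values, v_true, atol=1e-8)

    def test_one_hot_features_recover_unit_vector(self):
        x = np.eye(28)
        fm = FeatureMatrix(x, [("d", str(i)) for i in range(28)], "mirna_graph")
        labels = np.zeros(28)
        labels[0] = 1.0
        v = fit_weights(fm, labels, 0.0)
        np.testing.assert_allclose(v.values, labels, atol=1e-12)

    def test_ridge_shrinks_towards_zero(self):
        rng = np.random.default_rng(5)
        x = rng.random((28, 100))
        labels = rng.random(100)
        fm = FeatureMatrix(x, [("d", str(i)) for i in range(100)], "mirna_graph")
        norms = [
            np.linalg.norm(fit_weights(fm, labels, lam).values)
            for lam in (0.0, 1.0, 100.0, 1e6)
        ]
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 1e-3

    def test_singular_system_instructs_ridge(self):
        x = np.zeros((28, 10))
        x[0] = 1.0
        fm = FeatureMatrix(x, [("d", str(i)) for i in range(10)], "mirna_graph")
        with pytest.raises(GimdaError, match="ridge_lambda"):
            fit_weights(fm, np.ones(10), 0.0)

    def test_refit_on_own_predictions_is_idempotent(self):
        rng = np.random.default_rng(6)
        x = rng.random((28, 200))
        fm = FeatureMatrix(x, [("d", str(i)) for i in range(200)], "mirna_graph")
        v1 = fit_weights(fm, rng.random(200), 0.0)
        v2 = fit_weights(fm, x.T @ v1.values, 0.0)
        np.testing.assert_allclose(v2.values, v1.values, atol=1e-8)


class TestScoreAll:
    def test_final_score_is_average_of_sides(self):
        assoc = AssociationMatrix(
            np.array([[1, 0], [0, 1]], dtype=np.int8), ["d1", "d2"], ["m1", "m2"]
        )
        norm_m = np.zeros((28, 2, 2))
        norm_m[0, 0, 1] = 0.4  # known partner m1 -> candidate m2
        norm_d = np.zeros((28, 2, 2))
        norm_d[0, 1, 0] = 0.6  # known disease d2 -> candidate d1
        e0 = np.zeros(28)
        e0[0] = 1.0
        result = score_all(
            assoc,
            tensor_from(norm_m),
            tensor_from(norm_d),
            WeightVector(e0, "mirna_graph", 0.0),
            WeightVector(e0, "disease_graph", 0.0),
        )
        assert result.s_m[0, 1] == pytest.approx(0.4)
        assert result.s_d[0, 1] == pytest.approx(0.6)
        assert result.s[0, 1] == pytest.approx(0.5)

    def test_zero_weights_give_zero_scores(self):
        assoc = simple_assoc()
        norm = np.random.default_rng(7).random((28, 3, 3))
        norm_d = np.random.default_rng(8).random((28, 2, 2))
        zeros = WeightVector(np.zeros(28), "mirna_graph", 0.0)
        zeros_d = WeightVector(np.zeros(28), "disease_graph", 0.0)
        result = score_all(assoc, tensor_from(norm), tensor_from(norm_d), zeros, zeros_d)
        assert np.all(result.s == 0.0)

    def test_new_disease_ranking_follows_disease_graph(self):
        # a disease with no known miRNAs scores s_d / 2, so its within-row
        # ranking must equal the disease-graph ranking
        assoc = AssociationMatrix(
            np.array([[0, 0, 0], [1, 1, 0]], dtype=np.int8),
            ["new", "old"],
            ["m1", "m2", "m3"],
        )
        rng = np.random.default_rng(9)
        norm_m = rng.random((28, 3, 3))
        norm_d = rng.random((28, 2, 2))
        v = WeightVector(rng.random(28), "mirna_graph", 0.0)
        vd = WeightVector(rng.random(28), "disease_graph", 0.0)
        result = score_all(assoc, tensor_from(norm_m), tensor_from(norm_d), v, vd)
        assert np.all(result.s_m[0] == 0.0)
        np.testing.assert_allclose(result.s[0], result.s_d[0] / 2.0)
        assert list(np.argsort(result.s[0])) == list(np.argsort(result.s_d[0]))


class TestRankCandidates:
    def _scores(self):
        assoc = AssociationMatrix(
            np.array([[1, 0, 0]], dtype=np.int8), ["d"], ["m1", "m2", "m3"]
        )
        s = np.array([[0.9, 0.1, 0.9]])
        from gimda.scoring import ScoreMatrix

        return ScoreMatrix(s, s, s, assoc.values.astype(bool), ["d"], ["m1", "m2", "m3"])

    def test_known_pairs_excluded_and_sorted(self):
        ranked = rank_candidates(self._scores(), "d")
        assert [m for m, _ in ranked] == ["m3", "m2"]

    def test_ties_break_lexicographically(self):
        scores = self._scores()
        scores.s = np.array([[0.9, 0.5, 0.5]])
        ranked = rank_candidates(scores, "d")
        assert [m for m, _ in ranked] == ["m2", "m3"]

    def test_unknown_disease_fails(self):
        with pytest.raises(GimdaError, match="unknown disease"):
            rank_candidates(self._scores(), "nope")


class TestPredictPipeline:
    def test_planted_world_end_to_end(self, small_world, catalog):
        result = predict(
            small_world.assoc,
            Config(),
            mirna_sim=small_world.mirna_sim,
            dags=small_world.dags,
            catalog=catalog,
        )
        assert result.s.shape == small_world.assoc.values.shape
        assert np.isfinite(result.s).all()
        # known positives should outrank unknown pairs on average
        known = result.s[small_world.assoc.values == 1]
        unknown = result.s[small_world.assoc.values == 0]
        assert known.mean() > unknown.mean()

    def test_semantic_cache_matches_direct_dags(self, small_world, catalog):
        cache = precompute_semantic(
            small_world.dags, small_world.assoc.disease_ids, 0.5
        )
        via_cache = predict(
            small_world.assoc,
            Config(),
            semantic=cache,
            mirna_sim=small_world.mirna_sim,
            catalog=catalog,
        )
        via_dags = predict(
            small_world.assoc,
            Config(),
            dags=small_world.dags,
            mirna_sim=small_world.mirna_sim,
            catalog=catalog,
        )
        np.testing.assert_allclose(via_cache.s, via_dags.s)
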