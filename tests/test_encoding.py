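"""RSA encoding core: first-order similarities, the weighted-sum
predictor, Spearman scoring and leave-two-out evaluation."""

import numpy as np
import pytest

from eegrsa.encoding import (
    SimilarityMatrix,
    leave_two_out,
    model_similarity,
    predict_response,
    restriction_pool,
    score_prediction,
    time_resolved,
)
from eegrsa.errors import (
    DegenerateModelError,
    InvalidConfigError,
    InvalidInputError,
    UndefinedCorrelationError,
)


class TestModelSimilarity:
    def test_affine_transform_gives_correlation_one(self):
        v = np.array([1.0, 4.0, 2.0, 7.0])
        s = model_similarity({"a": v, "b": 2 * v + 3, "c": v[::-1]})
        assert s.values[s.index("a"), s.index("b")] == pytest.approx(1.0)

    def test_negated_vector_gives_minus_one(self):
        v = np.array([1.0, -2.0, 5.0])
        s = model_similarity({"a": v, "b": -v, "c": v + np.array([0, 1, 0])})
        assert s.values[s.index("a"), s.index("b")] == pytest.approx(-1.0)

    def test_centered_orthogonal_vectors_give_zero(self):
        a = np.array([1.0, -1.0, 0.0])
        b = np.array([1.0, 1.0, -2.0])  # centered, a.b = 0
        s = model_similarity({"a": a, "b": b, "c": a + b})
        assert s.values[s.index("a"), s.index("b")] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_vector_named_in_error(self):
        with pytest.raises(DegenerateModelError, match="flatline"):
            model_similarity(
                {"ok": np.array([1.0, 2.0]), "flatline": np.array([3.0, 3.0]),
                 "ok2": np.array([0.0, 5.0])}
            )

    def test_diagonal_is_one_and_symmetric(self, rng):
        s = model_similarity({f"e{k}": rng.normal(size=6) for k in range(5)})
        np.testing.assert_allclose(np.diag(s.values), 1.0)
        np.testing.assert_allclose(s.values, s.values.T)


class TestPredictResponse:
    def _sims(self, weights):
        ids = ("d", "a", "b", "c")
        vals = np.eye(4)
        vals[0, 1:] = vals[1:, 0] = weights
        return SimilarityMatrix(ids, vals, "pearson_vector")

    def test_toy_weighted_sum(self):
        sims = self._sims([0.5, -0.2, 0.1])
        responses = {
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
        }
        pred = predict_response("d", ["a", "b", "c"], responses, sims)
        np.testing.assert_allclose(pred, [0.6, -0.1])

    def test_single_train_item_with_unit_similarity(self):
        sims = self._sims([1.0, 0.0, 0.0])
        r = {"a": np.array([3.0, 1.0, 4.0])}
        np.testing.assert_allclose(
            predict_response("d", ["a"], r, sims), r["a"]
        )

    def test_all_zero_similarities_give_zero_vector(self):
        sims = self._sims([0.0, 0.0, 0.0])
        r = {k: np.ones(3) for k in "abc"}
        np.testing.assert_allclose(
            predict_response("d", ["a", "b", "c"], r, sims), 0.0
        )

    def test_missing_ids_rejected(self):
        sims = self._sims([0.5, 0.5, 0.5])
        with pytest.raises(InvalidInputError):
            predict_response("d", ["zzz"], {"zzz": np.ones(2)}, sims)
        with pytest.raises(InvalidInputError):
            predict_response("d", ["a"], {"b": np.ones(2)}, sims)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Independent brute-force loop over training items."""
        for _ in range(100):
            n = int(rng.integers(3, 7))
            ids = tuple(f"e{k}" for k in range(n))
            vals = rng.normal(size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 1.0)
            sims = SimilarityMatrix(ids, vals, "pearson_vector")
            responses = {e: rng.normal(size=4) for e in ids[1:]}
            got = predict_response(ids[0], list(ids[1:]), responses, sims)
            want = np.zeros(4)
            for k, e in enumerate(ids[1:], start=1):
                want = want + vals[0, k] * responses[e]
            np.testing.assert_allclose(got, want, rtol=1e-12)


class TestScorePrediction:
    def test_monotone_transform_scores_one(self, rng):
        p = rng.normal(size=10)
        assert score_prediction(p, np.exp(p)) == pytest.approx(1.0)

    def test_reversed_order_scores_minus_one(self):
        p = np.array([1.0, 2.0, 3.0, 4.0])
        assert score_prediction(p, p[::-1]) == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        assert score_prediction([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            score_prediction([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _self_consistent_fixture(n_entities=5, n_features=12, seed=0):
    """Responses generated by the predictor's own weighted-sum rule: with
    all-positive similarities and responses u_e * f (u > 0), every
    leave-two-out prediction is a positive multiple of f."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=8)
    vectors = {
        f"e{k}": base + 0.1 * rng.normal(size=8) for k in range(n_entities)
    }
    u = rng.uniform(0.5, 1.5, size=n_entities)
    f = rng.normal(size=n_features)
    responses = {f"e{k}": u[k] * f for k in range(n_entities)}
    return vectors, responses


class TestLeaveTwoOut:
    def test_self_consistent_responses_score_one(self):
        vectors, responses = _self_consistent_fixture()
        score = leave_two_out(vectors, responses)
        assert score.score == pytest.approx(1.0, abs=1e-12)
        assert score.n_pairs == 10  # C(5, 2)

    def test_restriction_counts_pairs_from_pool_only(self, small_study):
        _, _, corpus, subjects = small_study
        people = restriction_pool(corpus.records, "person")
        assert len(people) == 8
        responses = {
            e: subjects[0].response(e).ravel() for e in corpus.entity_ids
        }
        vectors = {e: corpus.true_vectors[e] for e in corpus.entity_ids}
        score = leave_two_out(
            vectors, responses, restrict_test_to=people
        )
        assert score.n_pairs == 28  # C(8, 2)

    def test_restrict_all_equals_unrestricted(self, small_study):
        _, _, corpus, subjects = small_study
        responses = {
            e: subjects[0].response(e).ravel() for e in corpus.entity_ids
        }
        vectors = {e: corpus.true_vectors[e] for e in corpus.entity_ids}
        confounds = corpus.confounds()
        a = leave_two_out(vectors, responses, confounds=confounds)
        b = leave_two_out(
            vectors,
            responses,
            confounds=confounds,
            restrict_test_to="all",
            records=corpus.records,
        )
        assert a.score == b.score and a.n_pairs == b.n_pairs

    def test_scale_invariance_of_scores(self, rng):
        vectors = {f"e{k}": rng.normal(size=6) for k in range(6)}
        responses = {f"e{k}": rng.normal(size=9) for k in range(6)}
        a = leave_two_out(vectors, responses)
        scaled = {e: 3.7 * r for e, r in responses.items()}
        b = leave_two_out(vectors, scaled)
        assert a.score == pytest.approx(b.score, abs=1e-12)

    def test_pool_too_small_rejected(self, rng):
        vectors = {f"e{k}": rng.normal(size=4) for k in range(5)}
        responses = {f"e{k}": rng.normal(size=6) for k in range(5)}
        with pytest.raises(InvalidConfigError):
            leave_two_out(vectors, responses, restrict_test_to=["e0"])

    def test_fewer_than_four_entities_rejected(self, rng):
        vectors = {f"e{k}": rng.normal(size=4) for k in range(3)}
        responses = {f"e{k}": rng.normal(size=6) for k in range(3)}
        with pytest.raises(InvalidConfigError):
            leave_two_out(vectors, responses)

    def test_constant_response_pairs_skipped_with_warning(self, rng):
        vectors = {f"e{k}": rng.normal(size=4) for k in range(5)}
        responses = {f"e{k}": rng.normal(size=8) for k in range(5)}
        responses["e0"] = np.zeros(8)  # constant observation: undefined rank corr
        with pytest.warns(UserWarning, match="skipped"):
            score = leave_two_out(vectors, responses)
        assert score.n_pairs == 6  # C(5,2) minus the 4 pairs containing e0


class TestTimeResolved:
    def test_planted_window_scores_highest(self, small_study):
        cfg, _, corpus, subjects = small_study
        vectors = {e: corpus.true_vectors[e] for e in corpus.entity_ids}
        frames = [
            time_resolved(ds, vectors, confounds=corpus.confounds())
            for ds in subjects
        ]
        mat = np.vstack([f.score.values for f in frames])
        times = subjects[0].times_ms
        win = (times >= 300) & (times < 500)
        assert mat[:, win].mean() > mat[:, ~win].mean() + 0.1

    def test_deterministic(self, small_study):
        _, _, corpus, subjects = small_study
        vectors = {e: corpus.true_vectors[e] for e in corpus.entity_ids}
        a = time_resolved(subjects[0], vectors, confounds=corpus.confounds())
        b = time_resolved(subjects[0], vectors, confounds=corpus.confounds())
        np.testing.assert_array_equal(a.score.values, b.score.values)

    def test_single_channel_units_skip_with_warning(self, small_study, rng):
        """One-channel feature vectors have a single value per unit: every
        rank correlation is undefined and all units skip."""
        from eegrsa.simulate import SubjectDataset

        _, _, corpus, _ = small_study
        ids = corpus.entity_ids
        ds = SubjectDataset(
            subject_id="sub-xx",
            entity_ids=list(ids),
            data=rng.normal(size=(len(ids), 1, 10)),
            channel_names=["only"],
            times_ms=np.arange(0, 200, 20),
        )
        vectors = {e: corpus.true_vectors[e] for e in ids}
        with pytest.warns(UserWarning, match="skipped"):
            frame = time_resolved(ds, vectors)
        assert (frame.n_pairs == 0).all()
        assert frame.score.isna().all()
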