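"""Passage assembly, layer pooling and the two-stage entity-vector mean."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegrsa.embeddings import (
    Passage,
    Token,
    ToyContextualProvider,
    ToyStaticProvider,
    assemble_passages,
    entity_vector,
    pool_layers,
)
from eegrsa.errors import EmptyRepresentationError, InvalidInputError


def toks(n, prefix="w", content=True):
    return [Token(f"{prefix}{k}", content) for k in range(n)]


class TestAssemblePassages:
    def test_greedy_merge_closes_at_threshold(self):
        # sentence lengths 8, 15, 25: the first passage closes at 8+15=23
        sentences = [toks(8, "a"), toks(15, "b"), toks(25, "c")]
        passages = assemble_passages(sentences, min_words=20)
        assert [len(p) for p in passages] == [23, 25]

    def test_single_long_sentence_is_one_passage(self):
        passages = assemble_passages([toks(40)], min_words=20)
        assert [len(p) for p in passages] == [40]

    def test_short_tail_kept_by_default(self):
        passages = assemble_passages([toks(5, "a"), toks(5, "b")], min_words=20)
        assert [len(p) for p in passages] == [10]

    def test_short_tail_merge_backward_option(self):
        sentences = [toks(25, "a"), toks(5, "b")]
        kept = assemble_passages(sentences, min_words=20)
        merged = assemble_passages(sentences, min_words=20, keep_short_tail=False)
        assert [len(p) for p in kept] == [25, 5]
        assert [len(p) for p in merged] == [30]

    def test_all_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            assemble_passages([[], []])

    def test_token_order_and_union_preserved(self):
        sentences = [toks(12, "a"), toks(9, "b"), toks(4, "c")]
        passages = assemble_passages(sentences, min_words=20)
        flat = [t for p in passages for t in p.tokens]
        assert flat == [t for s in sentences for t in s]

    def test_punctuation_does_not_count_toward_threshold(self):
        words = toks(19)
        punct = [Token(".", False)] * 5
        passages = assemble_passages([words + punct, toks(3, "x")], min_words=20)
        # 19 words + punctuation stays open until the next sentence
        assert len(passages) == 1


class TestPoolLayers:
    def test_identical_layers_unchanged(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(pool_layers([v, v, v, v]), v)

    def test_top_four_of_24_layers(self):
        layers = np.zeros((24, 4))
        layers[-4:] = np.eye(4)
        np.testing.assert_allclose(pool_layers(layers), [0.25, 0.25, 0.25, 0.25])

    def test_fewer_layers_than_top_k_uses_all(self):
        layers = np.array([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_allclose(pool_layers(layers, top_k=4), [1.0, 1.0])

    def test_ragged_layers_rejected(self):
        with pytest.raises(InvalidInputError):
            pool_layers([[1.0, 2.0], [1.0]])


def _passage(pairs):
    return Passage([Token(s, c) for s, c in pairs])


class TestEntityVector:
    def test_single_passage_mean(self):
        table = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        prov = ToyStaticProvider(table)
        p = _passage([("a", True), ("b", True)])
        ev = entity_vector([p], prov)
        np.testing.assert_allclose(ev.values, [0.5, 0.5])
        assert ev.n_content_tokens_used == 2

    def test_two_stage_mean_weights_passages_not_tokens(self):
        table = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        prov = ToyStaticProvider(table)
        p1 = _passage([("a", True)] * 2)  # passage mean (1, 0), 2 tokens
        p2 = _passage([("b", True)] * 6)  # passage mean (0, 1), 6 tokens
        ev = entity_vector([p1, p2], prov)
        np.testing.assert_allclose(ev.values, [0.5, 0.5])  # not (0.25, 0.75)

    def test_function_word_only_passage_contributes_nothing(self):
        table = {"a": np.array([1.0, 0.0]), "il": np.array([9.0, 9.0])}
        prov = ToyStaticProvider(table)
        p_fn = _passage([("il", False)] * 3)
        p_ok = _passage([("a", True)])
        ev = entity_vector([p_fn, p_ok], prov)
        np.testing.assert_allclose(ev.values, [1.0, 0.0])
        assert ev.n_passages_used == 1
        with pytest.raises(EmptyRepresentationError):
            entity_vector([p_fn], prov, entity_id="x17")

    def test_error_names_the_entity(self):
        prov = ToyStaticProvider({"a": np.array([1.0])})
        with pytest.raises(EmptyRepresentationError, match="x17"):
            entity_vector([_passage([("zzz", True)])], prov, entity_id="x17")

    def test_oov_content_words_skipped_not_zero_imputed(self):
        table = {"a": np.array([2.0, 4.0])}
        prov = ToyStaticProvider(table)
        p = _passage([("a", True), ("missing", True)])
        ev = entity_vector([p], prov)
        np.testing.assert_allclose(ev.values, [2.0, 4.0])
        assert ev.n_content_tokens_used == 1

    def test_provider_agnosticism(self):
        """A contextual provider that ignores context and replays the
        static table at every layer yields the same entity vectors."""
        rng = np.random.default_rng(0)
        table = {f"w{k}": rng.normal(size=5) for k in range(8)}
        table["il"] = rng.normal(size=5)
        static = ToyStaticProvider(table)
        contextual = ToyContextualProvider(table, n_layers=7)
        passages = [
            _passage([("w0", True), ("il", False), ("w3", True)]),
            _passage([("w5", True), ("w5", True), ("w1", True)]),
        ]
        ev_s = entity_vector(passages, static)
        ev_c = entity_vector(passages, contextual)
        np.testing.assert_allclose(ev_s.values, ev_c.values)

    def test_duplicate_tokens_counted_twice(self):
        table = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        prov = ToyStaticProvider(table)
        p = _passage([("a", True), ("a", True), ("b", True)])
        np.testing.assert_allclose(entity_vector([p], prov).values, [2 / 3, 1 / 3])

    @settings(derandomize=True, max_examples=25)
    @given(st.data())
    def test_function_word_vectors_never_influence_result(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        content_words = [f"c{k}" for k in range(5)]
        fn_words = [f"f{k}" for k in range(3)]
        table1 = {w: rng.normal(size=4) for w in content_words + fn_words}
        table2 = dict(table1)
        for w in fn_words:  # scramble only the function-word vectors
            table2[w] = rng.normal(size=4) * 100
        n_sent = data.draw(st.integers(1, 4))
        sentences = []
        for _ in range(n_sent):
            sent = []
            for _ in range(data.draw(st.integers(1, 8))):
                if rng.random() < 0.6:
                    sent.append(Token(content_words[rng.integers(5)], True))
                else:
                    sent.append(Token(fn_words[rng.integers(3)], False))
            sentences.append(sent)
        if not any(t.is_content for s in sentences for t in s):
            sentences[0].append(Token("c0", True))
        passages = assemble_passages(sentences, min_words=6)
        ev1 = entity_vector(passages, ToyStaticProvider(table1))
        ev2 = entity_vector(passages, ToyStaticProvider(table2))
        np.testing.assert_allclose(ev1.values, ev2.values)

    def test_two_stage_equals_one_stage_iff_equal_counts(self):
        rng = np.random.default_rng(3)
        table = {f"w{k}": rng.normal(size=4) for k in range(10)}
        prov = ToyStaticProvider(table)

        def one_stage(passages):
            vs = [
                table[t.surface]
                for p in passages
                for t in p.tokens
                if t.is_content
            ]
            return np.mean(vs, axis=0)

        equal = [_passage([(f"w{k}", True) for k in (0, 1)]) for _ in range(3)]
        np.testing.assert_allclose(
            entity_vector(equal, prov).values, one_stage(equal)
        )
        unequal = [
            _passage([("w0", True)]),
            _passage([(f"w{k}", True) for k in range(1, 7)]),
        ]
        assert not np.allclose(
            entity_vector(unequal, prov).values, one_stage(unequal)
        )
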