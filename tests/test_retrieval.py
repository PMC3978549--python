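"""Retrieval stack: tokenizer, tf-idf index, cosine ranking, Rocchio
updates, and feedback-session semantics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokestories import CorpusConfig, generate_corpus
from strokestories.retrieval import (
    Index,
    RocchioParams,
    build_index,
    rocchio_update,
    run_feedback_session,
    search,
    tokenize,
    vectorize_query,
)


class Doc:
    def __init__(self, id, text):
        self.id, self.text = id, text


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("I felt confused!", ["felt", "confused"]),
        ("called 911.", ["called", "911"]),
        ("", []),
        ("A 12 ab 123", ["ab", "123"]),
        ("Emergency-Room visit", ["emergency", "room", "visit"]),
    ])
    def test_rules(self, text, expected):
        assert tokenize(text) == expected


class TestBuildIndex:
    def test_ubiquitous_term_dropped(self):
        docs = [Doc("a", "stroke apple"), Doc("b", "stroke banana"),
                Doc("c", "stroke cherry")]
        index = build_index(docs)
        for vec in index.doc_vectors.values():
            assert "stroke" not in vec

    def test_single_term_doc_has_unit_norm(self):
        docs = [Doc("a", "apple"), Doc("b", "banana banana")]
        index = build_index(docs)
        assert math.isclose(
            sum(w * w for w in index.doc_vectors["b"].values()), 1.0)

    def test_weights_match_hand_computed_tfidf(self):
        """3-doc corpus with hand-set tf/df; expected weights computed
        by direct arithmetic of (1+ln tf)*ln(N/df), then L2-normalized."""
        docs = [
            Doc("d1", "apple apple banana"),
            Doc("d2", "banana cherry"),
            Doc("d3", "cherry apple durian"),
        ]
        # df: apple 2, banana 2, cherry 2, durian 1; N = 3
        ln = math.log
        raw_d1 = {"apple": (1 + ln(2)) * ln(3 / 2), "banana": ln(3 / 2)}
        norm = math.sqrt(sum(w * w for w in raw_d1.values()))
        expected_d1 = {t: w / norm for t, w in raw_d1.items()}
        index = build_index(docs)
        assert index.n_docs == 3
        assert index.df == {"apple": 2, "banana": 2, "cherry": 2, "durian": 1}
        assert index.doc_vectors["d1"] == pytest.approx(expected_d1)
        raw_d3 = {"cherry": ln(3 / 2), "apple": ln(3 / 2), "durian": ln(3)}
        norm3 = math.sqrt(sum(w * w for w in raw_d3.values()))
        assert index.doc_vectors["d3"] == pytest.approx(
            {t: w / norm3 for t, w in raw_d3.items()})

    def test_duplicate_ids_hard_error(self):
        with pytest.raises(ValueError):
            build_index([Doc("a", "x y"), Doc("a", "z w")])


class TestSearch:
    def _toy_index(self):
        docs = [
            Doc("d1", "apple banana"),
            Doc("d2", "banana cherry cherry"),
            Doc("d3", "cherry durian"),
            Doc("d4", "durian apple apple"),
            Doc("d5", "apple cherry durian"),
        ]
        return build_index(docs)

    def test_query_equal_to_document_ranks_it_first(self):
        index = self._toy_index()
        q = dict(index.doc_vectors["d2"])
        results = search(index, q, 3)
        assert results[0][0] == "d2"
        assert results[0][1] == pytest.approx(1.0)

    def test_k_larger_than_corpus_returns_all(self):
        index = self._toy_index()
        assert len(search(index, {"apple": 1.0}, 10)) == 5

    def test_ranking_matches_brute_force_cosine(self):
        """Full ranking equals exhaustive dense cosine enumeration."""
        index = self._toy_index()
        q = {"apple": 0.8, "cherry": 0.6}
        qn = math.sqrt(sum(v * v for v in q.values()))
        expected = []
        vocab = sorted(index.df)
        for pid, vec in index.doc_vectors.items():
            dot = sum(q.get(t, 0.0) * vec.get(t, 0.0) for t in vocab)
            expected.append((pid, dot / qn))
        expected.sort(key=lambda x: (-x[1], x[0]))
        got = search(index, q, 5)
        assert [p for p, _ in got] == [p for p, _ in expected]
        assert [s for _, s in got] == pytest.approx([s for _, s in expected])

    def test_insertion_order_invariance(self):
        docs = [Doc(f"d{i}", t) for i, t in enumerate(
            ["apple banana", "cherry apple", "banana cherry", "durian"])]
        q = {"apple": 1.0, "banana": 0.5}
        r1 = search(build_index(docs), q, 4)
        r2 = search(build_index(list(reversed(docs))), q, 4)
        assert r1 == r2

    def test_ties_broken_by_ascending_id(self):
        docs = [Doc("b", "apple zebra"), Doc("a", "apple yak"),
                Doc("c", "quince")]
        index = build_index(docs)
        results = search(index, {"apple": 1.0}, 2)
        assert [p for p, _ in results] == ["a", "b"]

    def test_excluded_ids_never_returned(self):
        index = self._toy_index()
        results = search(index, {"apple": 1.0}, 5, excluded={"d1", "d4"})
        assert {"d1", "d4"}.isdisjoint({p for p, _ in results})


class TestRocchio:
    def test_identity_with_no_feedback(self):
        q = {"a": 0.6, "b": 0.8}
        assert rocchio_update(q, [], [], RocchioParams(1.0, 0.75, 0.15)) == \
            pytest.approx(q)

    def test_pure_substitution(self):
        r = {"x": 0.6, "y": 0.8}
        out = rocchio_update({"a": 1.0}, [r], [], RocchioParams(0.0, 1.0, 0.0))
        assert out == pytest.approx(r)

    def test_hand_arithmetic_example(self):
        # alpha=1, beta=0.75, gamma=0.15:
        # a: 1 + 0.75*0.5          = 1.375
        # b: 0.75*0.5 - 0.15*1.0   = 0.225
        out = rocchio_update({"a": 1.0}, [{"a": 0.5, "b": 0.5}], [{"b": 1.0}],
                             RocchioParams(1.0, 0.75, 0.15))
        norm = math.sqrt(1.375 ** 2 + 0.225 ** 2)
        assert out == pytest.approx({"a": 1.375 / norm, "b": 0.225 / norm})

    def test_negative_weights_clipped(self):
        out = rocchio_update({"a": 0.1}, [], [{"a": 1.0, "b": 1.0}],
                             RocchioParams(1.0, 0.75, 0.5))
        assert "a" not in out and "b" not in out

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_equals_dense_vector_oracle(self, data):
        """Sparse update equals a brute-force dense implementation on
        vocabularies of at most 50 terms."""
        vocab_size = data.draw(st.integers(1, 50))
        vocab = [f"t{i}" for i in range(vocab_size)]
        weight = st.floats(0.0, 5.0, allow_nan=False, width=32)

        def vec(d):
            dense = [d.draw(weight) for _ in vocab]
            return dense

        q_dense = vec(data)
        n_rel = data.draw(st.integers(0, 3))
        n_irr = data.draw(st.integers(0, 3))
        rel_dense = [vec(data) for _ in range(n_rel)]
        irr_dense = [vec(data) for _ in range(n_irr)]
        alpha, beta, gamma = (data.draw(st.floats(0, 2, allow_nan=False))
                              for _ in range(3))

        def sparse(dense):
            return {t: w for t, w in zip(vocab, dense) if w != 0.0}

        out = rocchio_update(sparse(q_dense),
                             [sparse(v) for v in rel_dense],
                             [sparse(v) for v in irr_dense],
                             RocchioParams(alpha, beta, gamma))

        acc = np.asarray(q_dense, dtype=float) * alpha
        if rel_dense:
            acc = acc + beta * np.mean(rel_dense, axis=0)
        if irr_dense:
            acc = acc - gamma * np.mean(irr_dense, axis=0)
        acc = np.clip(acc, 0.0, None)
        norm = np.linalg.norm(acc)
        expected = {} if norm == 0 else {
            t: w / norm for t, w in zip(vocab, acc) if w > 0.0
        }
        assert set(out) == set(expected)
        for t in expected:
            assert out[t] == pytest.approx(expected[t], abs=1e-9)


def gold_judge(posts):
    by_id = {p.id: p for p in posts}

    def judge(doc_id):
        g = by_id[doc_id].gold
        return "relevant" if (g is not None and g.is_stroke) else "irrelevant"
    return judge


class TestFeedbackSession:
    def test_all_irrelevant_leaves_relevant_set_empty(self, small_corpus):
        index = build_index(small_corpus)
        log = run_feedback_session(index, "apple banana",
                                   lambda _id: "irrelevant",
                                   batch_size=5, rounds=2)
        assert log.relevant_ids == []

    def test_single_round_is_plain_search(self, small_corpus):
        index = build_index(small_corpus)
        judge = gold_judge(small_corpus)
        proto = "my speech was slurred and i was diagnosed with stroke"
        log = run_feedback_session(index, proto, judge, batch_size=5, rounds=1)
        assert len(log.rounds) == 1
        plain = search(index, vectorize_query(index, proto), 5)
        assert log.rounds[0].results == plain

    def test_judged_docs_never_reappear(self, small_corpus):
        index = build_index(small_corpus)
        log = run_feedback_session(index, "stroke emergency room",
                                   gold_judge(small_corpus),
                                   batch_size=10, rounds=4)
        seen = set()
        for rnd in log.rounds:
            ids = {p for p, _ in rnd.results}
            assert ids.isdisjoint(seen)
            seen |= ids

    def test_skip_neutrality(self, small_corpus):
        """Turning irrelevant judgments into skips changes no query
        vector at any round — skips only leave the queue."""
        index = build_index(small_corpus)
        base = gold_judge(small_corpus)

        def skipping(doc_id):
            label = base(doc_id)
            return "skip" if label == "irrelevant" else label

        # with gamma=0 an irrelevant judgment is inert, exactly like a
        # skip must be: the two sessions must agree on every query vector
        # and every result page
        params = RocchioParams(1.0, 0.75, 0.0)
        log_c = run_feedback_session(index, "stroke emergency room",
                                     base, batch_size=8, rounds=3,
                                     params=params)
        log_d = run_feedback_session(index, "stroke emergency room",
                                     skipping, batch_size=8, rounds=3,
                                     params=params)
        for rc, rd in zip(log_c.rounds, log_d.rounds):
            assert rc.query == pytest.approx(rd.query)
            assert rc.results == rd.results
        # and skipped documents still leave the judging queue
        skipped_r1 = {j.doc_id for j in log_d.rounds[0].judgments
                      if j.label == "skip"}
        later = {p for r in log_d.rounds[1:] for p, _ in r.results}
        assert skipped_r1 and skipped_r1.isdisjoint(later)

    def test_empty_index_is_hard_error(self):
        with pytest.raises(ValueError):
            run_feedback_session(Index(0, {}, {}), "x", lambda _id: "skip")

    def test_feedback_improves_precision_single_seed(self):
        """On one benchmark corpus, precision@20 at round 3 is at least
        round 1 (qualitative feedback-improvement claim, one seed)."""
        posts = generate_corpus(CorpusConfig(seed=13))
        index = build_index(posts)
        from strokestories.lexicons import PROTOTYPE_STORY
        log = run_feedback_session(index, PROTOTYPE_STORY, gold_judge(posts),
                                   batch_size=20, rounds=3)
        series = log.precision_series
        assert len(series) == 3
        assert series[2] >= series[0]
        # single-round dips bounded
        for a, b in zip(series, series[1:]):
            assert b >= a - 0.05
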