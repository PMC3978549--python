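"""Ranked retrieval with Rocchio relevance feedback.

A story corpus is indexed into tf-idf document vectors; a free-text
*prototype story* seeds the query; each feedback round the user (or a
gold-label oracle) marks retrieved posts relevant, irrelevant, or skips
them, and the query is moved toward the relevant vectors and away from
the irrelevant ones:

    q' = alpha*q0 + (beta/|R|) * sum(R) - (gamma/|I|) * sum(I)

Negative weights are clipped to zero and the result re-normalized.
Skipped documents are only removed from the judging queue — they never
touch the query.  Default (alpha, beta, gamma) = (1.0, 0.75, 0.15), the
classical SMART settings; the source system left them unspecified.

Everything here is deliberately self-contained (no external search
engine): the contract is ranked retrieval over a desk-scale corpus,
fully inspectable and testable.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "tokenize",
    "SparseVector",
    "Index",
    "RocchioParams",
    "Judgment",
    "RoundLog",
    "RetrievalLog",
    "build_index",
    "vectorize_query",
    "search",
    "rocchio_update",
    "run_feedback_session",
]

SparseVector = dict[str, float]

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics; keep alphabetic tokens of
    length >= 2 and all-digit tokens of length >= 3 (so "911" survives
    but stray single letters and two-digit noise do not).  No stemming,
    no stopword list."""
    out = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if tok.isdigit():
            if len(tok) >= 3:
                out.append(tok)
        elif len(tok) >= 2:
            out.append(tok)
    return out


def _l2_normalize(vec: SparseVector) -> SparseVector:
    norm = math.sqrt(sum(w * w for w in vec.values()))
    if norm == 0.0:
        return {}
    return {t: w / norm for t, w in vec.items()}


@dataclass
class Index:
    """Inverted tf-idf index: document count, per-term document
    frequency, and one L2-normalized sparse vector per document.

    Term weight is (1 + ln tf) * ln(N / df); terms occurring in every
    document get idf 0 and are dropped from the vectors (df is still
    recorded for query weighting)."""

    n_docs: int
    df: dict[str, int]
    doc_vectors: dict[str, SparseVector]

    def idf(self, term: str) -> float:
        d = self.df.get(term)
        if not d:
            return 0.0
        return math.log(self.n_docs / d)


def _tf_weights(tokens: Sequence[str]) -> dict[str, int]:
    tf: dict[str, int] = {}
    for t in tokens:
        tf[t] = tf.get(t, 0) + 1
    return tf


def build_index(posts: Iterable) -> Index:
    """Index posts (anything with ``id`` and ``text`` attributes, or
    ``{"id":..., "text":...}`` mappings).  Duplicate ids are a hard
    error."""
    docs: dict[str, list[str]] = {}
    for post in posts:
        pid = post["id"] if isinstance(post, Mapping) else post.id
        text = post["text"] if isinstance(post, Mapping) else post.text
        if pid in docs:
            raise ValueError(f"duplicate document id: {pid!r}")
        docs[pid] = tokenize(text)
    n = len(docs)
    df: dict[str, int] = {}
    for tokens in docs.values():
        for t in set(tokens):
            df[t] = df.get(t, 0) + 1
    vectors: dict[str, SparseVector] = {}
    for pid, tokens in docs.items():
        tf = _tf_weights(tokens)
        vec = {}
        for t, c in tf.items():
            idf = math.log(n / df[t])
            if idf > 0.0:
                vec[t] = (1.0 + math.log(c)) * idf
        vectors[pid] = _l2_normalize(vec)
    return Index(n_docs=n, df=df, doc_vectors=vectors)


def vectorize_query(index: Index, text: str) -> SparseVector:
    """Weight free text against the index vocabulary, same scheme as
    documents; out-of-vocabulary terms are dropped."""
    tf = _tf_weights(tokenize(text))
    vec = {}
    for t, c in tf.items():
        idf = index.idf(t)
        if idf > 0.0:
            vec[t] = (1.0 + math.log(c)) * idf
    return _l2_normalize(vec)


def search(index: Index, query: SparseVector, k: int,
           excluded: Optional[set[str]] = None) -> list[tuple[str, float]]:
    """Top-k documents by cosine score, descending; ties broken by
    ascending document id; excluded ids never returned.  k larger than
    the corpus simply returns everything eligible."""
    if k < 1:
        raise ValueError("k must be >= 1")
    excluded = excluded or set()
    q = _l2_normalize(query)
    scored = []
    for pid, dvec in index.doc_vectors.items():
        if pid in excluded:
            continue
        if len(q) < len(dvec):
            s = sum(w * dvec.get(t, 0.0) for t, w in q.items())
        else:
            s = sum(w * q.get(t, 0.0) for t, w in dvec.items())
        scored.append((pid, s))
    scored.sort(key=lambda x: (-x[1], x[0]))
    return scored[:k]


@dataclass
class RocchioParams:
    alpha: float = 1.0
    beta: float = 0.75
    gamma: float = 0.15

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("Rocchio weights must be non-negative")


def rocchio_update(q0: SparseVector,
                   relevant: Sequence[SparseVector],
                   irrelevant: Sequence[SparseVector],
                   params: RocchioParams = RocchioParams()) -> SparseVector:
    """One Rocchio step.  Empty relevant/irrelevant sets contribute
    nothing (their term is omitted, not divided by zero); negative
    resulting weights are clipped to zero; the result is re-normalized
    to unit length."""
    acc: dict[str, float] = {}
    for t, w in q0.items():
        acc[t] = acc.get(t, 0.0) + params.alpha * w
    if relevant:
        b = params.beta / len(relevant)
        for vec in relevant:
            for t, w in vec.items():
                acc[t] = acc.get(t, 0.0) + b * w
    if irrelevant:
        g = params.gamma / len(irrelevant)
        for vec in irrelevant:
            for t, w in vec.items():
                acc[t] = acc.get(t, 0.0) - g * w
    clipped = {t: w for t, w in acc.items() if w > 0.0}
    return _l2_normalize(clipped)


@dataclass
class Judgment:
    doc_id: str
    label: str  # {relevant, irrelevant, skip}

    def __post_init__(self):
        if self.label not in ("relevant", "irrelevant", "skip"):
            raise ValueError(f"invalid judgment label {self.label!r}")


@dataclass
class RoundLog:
    query: SparseVector
    results: list[tuple[str, float]]
    judgments: list[Judgment]
    precision_at_k: float


@dataclass
class RetrievalLog:
    rounds: list[RoundLog] = field(default_factory=list)

    @property
    def relevant_ids(self) -> list[str]:
        return [j.doc_id for r in self.rounds for j in r.judgments
                if j.label == "relevant"]

    @property
    def precision_series(self) -> list[float]:
        return [r.precision_at_k for r in self.rounds]

    def to_json(self) -> dict:
        return {
            "rounds": [
                {
                    "query": r.query,
                    "results": [[pid, s] for pid, s in r.results],
                    "judgments": [
                        {"doc_id": j.doc_id, "label": j.label} for j in r.judgments
                    ],
                    "precision_at_k": r.precision_at_k,
                }
                for r in self.rounds
            ]
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)


def run_feedback_session(index: Index, prototype_text: str,
                         judge: Callable[[str], str],
                         batch_size: int = 10, rounds: int = 3,
                         params: RocchioParams = RocchioParams()) -> RetrievalLog:
    """Run a feedback session against the index.

    Each round searches for ``batch_size`` unjudged documents, collects
    a judgment per result from ``judge`` (returning ``relevant``,
    ``irrelevant`` or ``skip``), records precision@batch, and — between
    rounds — folds the relevant/irrelevant document vectors into the
    query.  Skips are excluded from future result pages but never touch
    the query; with ``rounds=1`` no update is ever applied.
    """
    if index.n_docs == 0:
        raise ValueError("cannot search an empty index")
    q = vectorize_query(index, prototype_text)
    judged: set[str] = set()
    log = RetrievalLog()
    for rnd in range(rounds):
        results = search(index, q, batch_size, excluded=judged)
        if not results:
            break
        judgments = []
        for pid, _score in results:
            label = judge(pid)
            judgments.append(Judgment(doc_id=pid, label=label))
            judged.add(pid)
        n_rel = sum(j.label == "relevant" for j in judgments)
        log.rounds.append(RoundLog(
            query=dict(q), results=results, judgments=judgments,
            precision_at_k=n_rel / len(results),
        ))
        if rnd < rounds - 1:
            rel = [index.doc_vectors[j.doc_id] for j in judgments
                   if j.label == "relevant"]
            irr = [index.doc_vectors[j.doc_id] for j in judgments
                   if j.label == "irrelevant"]
            if rel or irr:
                q = rocchio_update(q, rel, irr, params)
    return log
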