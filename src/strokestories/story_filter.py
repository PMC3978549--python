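"""Personal-story gate in front of the searchable index.

The original crawl passed every post through a supervised personal-story
classifier operating at precision 0.66 and recall 0.50 — it finds about
half of all personal stories, and a third of what it flags are not
stories.  That classifier's features live in prior work and cannot be
reproduced, so this module offers two interchangeable stand-ins:

* :func:`noise_filter` — the contractual noise model.  It selects
  ``TP = round(recall * n_stories)`` true stories and
  ``FP = round(TP * (1 - precision) / precision)`` non-stories uniformly
  at random, so the measured operating point matches the targets exactly
  up to integer rounding at any corpus size.
* :func:`train_story_classifier` — a convenience baseline: a
  bag-of-words logistic classifier trained on gold-labelled posts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .retrieval import tokenize

__all__ = [
    "PrecisionRecall",
    "noise_filter",
    "evaluate_filter",
    "StoryClassifier",
    "train_story_classifier",
    "classify",
]


@dataclass
class PrecisionRecall:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PrecisionRecall":
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        return cls(precision=precision, recall=recall, tp=tp, fp=fp, fn=fn)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def noise_filter(posts: Sequence, precision_target: float = 0.66,
                 recall_target: float = 0.5, seed: int = 0) -> set[str]:
    """Flag posts so the flagged set hits the target operating point.

    Posts must carry gold profiles (``post.gold.is_story``).  True
    positives are drawn uniformly from the story pool, false positives
    uniformly from the non-story pool; a non-story pool too small to
    supply the required false positives is a hard error naming the
    shortfall.
    """
    if not 0.0 < precision_target <= 1.0:
        raise ValueError("precision_target must be in (0, 1]")
    if not 0.0 <= recall_target <= 1.0:
        raise ValueError("recall_target must be in [0, 1]")
    story_ids = [p.id for p in posts if p.gold is not None and p.gold.is_story]
    nonstory_ids = [p.id for p in posts if p.gold is None or not p.gold.is_story]
    tp = _round_half_up(recall_target * len(story_ids))
    fp = _round_half_up(tp * (1.0 - precision_target) / precision_target)
    if fp > len(nonstory_ids):
        raise ValueError(
            f"non-story pool too small for target precision: need {fp} "
            f"false positives, pool has {len(nonstory_ids)} "
            f"(short {fp - len(nonstory_ids)})"
        )
    rng = np.random.default_rng(seed)
    flagged = set(rng.choice(story_ids, size=tp, replace=False)) if tp else set()
    if fp:
        flagged |= set(rng.choice(nonstory_ids, size=fp, replace=False))
    return {str(i) for i in flagged}


def evaluate_filter(flagged_ids: Iterable[str],
                    gold_story_ids: Iterable[str]) -> PrecisionRecall:
    """Exact confusion counts of a flagged set against the gold story set."""
    flagged = set(flagged_ids)
    gold = set(gold_story_ids)
    tp = len(flagged & gold)
    fp = len(flagged - gold)
    fn = len(gold - flagged)
    return PrecisionRecall.from_counts(tp=tp, fp=fp, fn=fn)


@dataclass
class StoryClassifier:
    """Bag-of-words linear classifier: vocabulary, term weights, intercept.

    Decision rule: flag as story when the sigmoid of the linear score
    exceeds 0.5; empty (token-free) text is non-story by convention.
    JSON-serializable so trained models travel as plain text.
    """

    vocabulary: dict[str, int]
    weights: list[float]
    intercept: float
    version: int = 1

    def score(self, text: str) -> float:
        tokens = tokenize(text)
        if not tokens:
            return -np.inf
        z = self.intercept
        for t in tokens:
            j = self.vocabulary.get(t)
            if j is not None:
                z += self.weights[j]
        return z

    def to_json(self) -> dict:
        return {
            "version": self.version,
            "vocabulary": self.vocabulary,
            "weights": list(self.weights),
            "intercept": self.intercept,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "StoryClassifier":
        return cls(
            vocabulary=obj["vocabulary"], weights=list(obj["weights"]),
            intercept=float(obj["intercept"]), version=int(obj.get("version", 1)),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "StoryClassifier":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def train_story_classifier(posts: Sequence, labels: Sequence[int],
                           seed: int = 0) -> StoryClassifier:
    """Train the baseline classifier on gold-labelled posts
    (label 1 = personal story).  Single-class data is a hard error."""
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    texts = [p["text"] if isinstance(p, dict) else p.text for p in posts]
    vec = CountVectorizer(analyzer=tokenize)
    X = vec.fit_transform(texts)
    clf = LogisticRegression(solver="liblinear", random_state=seed, C=1.0)
    clf.fit(X, labels)
    vocab = {t: int(j) for t, j in vec.vocabulary_.items()}
    return StoryClassifier(
        vocabulary=vocab,
        weights=[float(w) for w in clf.coef_[0]],
        intercept=float(clf.intercept_[0]),
    )


def classify(model: StoryClassifier, post) -> str:
    """Return ``story`` or ``nonstory`` for one post at threshold 0.5."""
    text = post["text"] if isinstance(post, dict) else getattr(post, "text", post)
    return "story" if model.score(text) > 0.0 else "nonstory"
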