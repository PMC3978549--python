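"""Corpus and configuration file formats.

Corpora travel as newline-delimited JSON, one post per line with keys
``id``, ``date``, ``text`` and (synthetic corpora only) ``gold``; UTF-8
throughout.  write -> read is the identity on valid corpora.  Configs
load from YAML or JSON and are schema-validated on load.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from .coding import CodedStory
from .synthetic import BlogPost, CorpusConfig, PrevalenceTable, StoryProfile

__all__ = ["read_corpus", "write_corpus", "load_corpus_config",
           "corpus_config_to_dict"]

log = logging.getLogger("strokestories")

_CODED_FIELDS = [f.name for f in dataclasses.fields(CodedStory)]


def _gold_to_dict(profile: StoryProfile) -> dict:
    out: dict = {"distractor_class": profile.distractor_class}
    if profile.voice is not None:
        out["voice"] = profile.voice
    if profile.topic is not None:
        out["topic"] = profile.topic
    if profile.gold is not None:
        coded = {}
        for f in _CODED_FIELDS:
            v = getattr(profile.gold, f)
            if f == "symptoms" or v is not None:
                coded[f] = v
        out["coded"] = coded
    return out


def _gold_from_dict(obj: dict) -> StoryProfile:
    gold = None
    if "coded" in obj:
        coded = dict(obj["coded"])
        coded.setdefault("story_id", "")
        gold = CodedStory(**coded)
    return StoryProfile(
        voice=obj.get("voice"),
        distractor_class=obj.get("distractor_class", "none"),
        gold=gold,
        topic=obj.get("topic"),
    )


def write_corpus(posts: list[BlogPost], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            rec = {"id": post.id, "date": post.date, "text": post.text}
            if post.gold is not None:
                rec["gold"] = _gold_to_dict(post.gold)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_corpus(path) -> list[BlogPost]:
    """Read a newline-delimited JSON corpus.

    Malformed lines and missing mandatory keys are errors naming the
    line number; duplicate ids are errors; an empty file yields an
    empty corpus with a logged warning.
    """
    posts: list[BlogPost] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{lineno}: malformed JSON ({e.msg})") from e
            for key in ("id", "date", "text"):
                if key not in obj:
                    raise ValueError(f"{path}:{lineno}: missing key {key!r}")
            if obj["id"] in seen:
                raise ValueError(f"{path}:{lineno}: duplicate id {obj['id']!r}")
            seen.add(obj["id"])
            gold = _gold_from_dict(obj["gold"]) if "gold" in obj else None
            posts.append(BlogPost(id=obj["id"], date=obj["date"],
                                  text=obj["text"], gold=gold))
    if not posts:
        log.warning("corpus at %s is empty", path)
    return posts


def corpus_config_to_dict(config: CorpusConfig) -> dict:
    out = dataclasses.asdict(config)
    out["symptom_prevalence"] = config.symptom_prevalence.rates
    return out


def load_corpus_config(path) -> CorpusConfig:
    """Load a CorpusConfig from YAML or JSON; unknown keys and invalid
    values are errors (validated on load)."""
    text = Path(path).read_text(encoding="utf-8")
    obj = yaml.safe_load(text) or {}
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(CorpusConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "symptom_prevalence" in obj:
        obj["symptom_prevalence"] = PrevalenceTable(obj["symptom_prevalence"])
    config = CorpusConfig(**obj)
    config.validate()
    return config
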