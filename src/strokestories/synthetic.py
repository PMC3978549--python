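"""Seeded synthetic weblog corpora with planted stroke narratives.

The real study mined a two-year crawl of weblog posts; that corpus is
not redistributable, so this module generates stand-in corpora whose
*statistical structure* matches what the study observed: a mix of
non-story posts, non-stroke personal stories, and stroke stories whose
gold codes follow the reported margins — narrator split roughly 50/50
first/third person, patient sex split roughly 52/48, per-symptom
prevalences by sex (mental status change additionally by narrator,
the study's headline interaction), stroke-type mix roughly 67:29
ischemic:hemorrhagic among typed stories, and a seven-band age
distribution.

Symptom flags are drawn independently per symptom at the configured
marginal rates: the source tables report marginals only, so any joint
structure would be invented.  That simplification is deliberate and
documented.

Two generation modes exist because they answer different questions:
``exact_margins`` plants the configured narrator/sex/stroke-type counts
with zero error (largest-remainder apportionment), which downstream
tabulation tests need; ``sampled`` draws them binomially, which
prevalence-recovery tests need.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import lexicons
from .coding import (
    AGE_BANDS,
    CodedStory,
    NONTRADITIONAL_SYMPTOMS,
    RELATIONS,
    SYMPTOMS,
    TRADITIONAL_SYMPTOMS,
    age_band_for,
)

__all__ = [
    "PrevalenceTable",
    "CorpusConfig",
    "StoryProfile",
    "BlogPost",
    "default_prevalence",
    "sample_profile",
    "render_story",
    "generate_corpus",
    "largest_remainder",
]

_AGE_BAND_RANGES = {
    "0-17": (5, 17), "18-29": (18, 29), "30-44": (30, 44),
    "45-64": (45, 64), "65-75": (65, 75), "76-84": (76, 84),
    "85+": (85, 97),
}


class PrevalenceTable:
    """Per-symptom reporting probabilities, split by patient sex.

    For mental status change the rate is additionally split by narrator
    (first/third person), since that interaction is the structure the
    downstream analyses look for.  ``rates[symptom][sex]`` is either a
    float or a ``{"first": p, "third": p}`` mapping.
    """

    def __init__(self, rates: dict[str, dict]):
        missing = set(SYMPTOMS) - set(rates)
        extra = set(rates) - set(SYMPTOMS)
        if missing or extra:
            raise ValueError(
                f"prevalence table must cover the closed symptom taxonomy exactly; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for sym, by_sex in rates.items():
            for sex in ("female", "male"):
                v = by_sex[sex]
                vals = v.values() if isinstance(v, dict) else [v]
                for p in vals:
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"prevalence out of [0,1]: {sym}/{sex}={p}")
        self.rates = rates

    def rate(self, symptom: str, sex: str, narrator: str = "first") -> float:
        v = self.rates[symptom][sex]
        return v[narrator] if isinstance(v, dict) else v


def default_prevalence() -> PrevalenceTable:
    """Default rates: observed symptom frequencies by sex (n=91 women,
    n=83 men), with mental status change split by narrator."""
    f, m = 91, 83
    return PrevalenceTable({
        "hemiparesis": {"female": 68 / f, "male": 63 / m},
        "impaired_speech_or_comprehension": {"female": 59 / f, "male": 47 / m},
        "visual_disturbance": {"female": 11 / f, "male": 5 / m},
        "ataxia_discoordination": {"female": 16 / f, "male": 11 / m},
        "vertigo": {"female": 13 / f, "male": 13 / m},
        "balance_difficulty": {"female": 7 / f, "male": 8 / m},
        "pain_excl_headache": {"female": 5 / f, "male": 5 / m},
        "mental_status_change": {
            "female": {"first": 27 / 48, "third": 12 / 43},
            "male": {"first": 16 / 44, "third": 11 / 39},
        },
        "headache": {"female": 16 / f, "male": 11 / m},
        "lightheadedness": {"female": 5 / f, "male": 3 / m},
        "other_neurologic": {"female": 13 / f, "male": 9 / m},
        "nonneurologic": {"female": 4 / f, "male": 5 / m},
    })


# Hemiparesis subtype mix (body, face, both) conditional on hemiparesis.
_SUBTYPE_MIX = {
    "female": {"body": 30 / 68, "face": 2 / 68, "both": 36 / 68},
    "male": {"body": 33 / 63, "face": 4 / 63, "both": 26 / 63},
}


@dataclass
class CorpusConfig:
    """Composition and margins of one synthetic corpus.

    Defaults encode the study-scale structure on a 2000-post desk corpus:
    200 stroke stories among 800 other personal stories and 1000
    non-story posts, with the reported narrator, sex, stroke-type, age
    and symptom margins.
    """

    n_stroke_stories: int = 200
    n_other_stories: int = 800
    n_nonstory_posts: int = 1000
    narrator_first_fraction: float = 97 / 191
    female_fraction: float = 91 / 174
    stroke_type_mix: dict = field(default_factory=lambda: {
        "ischemic": 67 / 174, "hemorrhagic": 29 / 174, "unknown": 78 / 174,
    })
    symptom_prevalence: PrevalenceTable = field(default_factory=default_prevalence)
    age_band_weights: dict = field(default_factory=lambda: {
        band: w / 85 for band, w in zip(AGE_BANDS, (3, 14, 24, 27, 11, 3, 3))
    })
    age_report_fraction: float = 85 / 174
    witness_fraction: float = 40 / 94
    relation_mix: dict = field(default_factory=lambda: {
        "adult_child": 39 / 94, "spouse": 24 / 94, "other_relative": 15 / 94,
        "friend": 5 / 94, "stranger": 11 / 94,
    })
    sought_assistance_fraction: float = 0.965
    delay_report_fraction: float = 156 / 174
    delayed_fraction: dict = field(default_factory=lambda: {
        "female": 35 / 80, "male": 24 / 76,
    })
    immediate_treatment_fraction: float = 0.905
    mode: str = "sampled"                  # {exact_margins, sampled}
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_stroke_stories", "n_other_stories", "n_nonstory_posts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("narrator_first_fraction", "female_fraction",
                     "age_report_fraction", "witness_fraction",
                     "sought_assistance_fraction", "delay_report_fraction",
                     "immediate_treatment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        for name, mix, keys in (
            ("stroke_type_mix", self.stroke_type_mix, ("ischemic", "hemorrhagic", "unknown")),
            ("age_band_weights", self.age_band_weights, AGE_BANDS),
            ("relation_mix", self.relation_mix, RELATIONS),
        ):
            if set(mix) != set(keys):
                raise ValueError(f"{name} keys must be {keys}")
            if any(w < 0 for w in mix.values()):
                raise ValueError(f"{name} weights must be >= 0")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1")
        if self.mode not in ("exact_margins", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class StoryProfile:
    """What the renderer needs to write one post.

    Stroke stories carry exactly one gold :class:`CodedStory`;
    distractors carry none.
    """

    voice: Optional[str] = None             # {first, third}; None for distractors
    distractor_class: str = "none"          # {none, other_story, nonstory}
    gold: Optional[CodedStory] = None
    topic: Optional[str] = None             # distractor topic

    def __post_init__(self):
        if self.distractor_class == "none" and self.gold is None:
            raise ValueError("stroke profile must carry a gold CodedStory")
        if self.distractor_class != "none" and self.gold is not None:
            raise ValueError("distractor profiles carry no gold CodedStory")

    @property
    def is_story(self) -> bool:
        """Personal story (stroke or otherwise), as opposed to non-story post."""
        return self.distractor_class in ("none", "other_story")

    @property
    def is_stroke(self) -> bool:
        return self.distractor_class == "none"


@dataclass
class BlogPost:
    id: str
    date: str          # ISO-8601
    text: str
    gold: Optional[StoryProfile] = None


def largest_remainder(total: int, weights: dict[str, float]) -> dict[str, int]:
    """Apportion ``total`` units over categories by the largest-remainder
    rule: floor every target, then hand the leftover units to the
    categories with the largest fractional parts (ties broken by
    category order).  Exact-margin planting goes through this so that
    awkward cases (odd totals at fraction 0.5) resolve deterministically
    rather than silently."""
    keys = list(weights)
    targets = {k: total * weights[k] for k in keys}
    counts = {k: int(np.floor(targets[k])) for k in keys}
    leftover = total - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(targets[k] - counts[k]), keys.index(k)))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def sample_profile(prev: PrevalenceTable, rng: np.random.Generator, *,
                   sex: str = "female", narrator: str = "first") -> StoryProfile:
    """Draw one stroke-story profile with symptoms sampled independently
    at the configured per-sex (and, for mental status change,
    per-narrator) rates.  Independence across symptoms is a documented
    simplification."""
    gold = CodedStory(story_id="", narrator=narrator, patient_sex=sex)
    for sym in SYMPTOMS:
        gold.symptoms[sym] = bool(
            rng.random() < prev.rate(sym, sex, narrator)
        )
    if gold.symptoms["hemiparesis"]:
        mix = _SUBTYPE_MIX[sex]
        gold.hemiparesis_subtype = _choice(rng, mix)
    return StoryProfile(voice=narrator, gold=gold)


def _choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


_PRONOUNS = {
    ("first", None): {"subj": "i", "poss": "my", "obj": "me"},
    ("third", "female"): {"subj": "she", "poss": "her", "obj": "her"},
    ("third", "male"): {"subj": "he", "poss": "his", "obj": "him"},
}


def _fill(template: str, pron: dict[str, str]) -> str:
    s = template.format(**pron)
    return s[0].upper() + s[1:] + "."


def _render_medical_distractor(rng: np.random.Generator) -> str:
    """A stroke-mimic story: same narrative machinery and symptom
    language as a stroke story, but a non-stroke diagnosis.  Only the
    substance separates these from true positives, which is what makes
    them hard negatives for retrieval."""
    voice = "first" if rng.random() < 0.5 else "third"
    sex = "female" if rng.random() < 0.5 else "male"
    pron = _PRONOUNS[("first", None)] if voice == "first" else _PRONOUNS[("third", sex)]
    month = lexicons.MONTHS[int(rng.integers(12))]
    sents: list[str] = []
    if voice == "first":
        sents.append(f"Last {month} something happened that changed everything.")
        sents.append("I am a " + ("woman." if sex == "female" else "man."))
    else:
        rel = ("adult_child", "spouse", "other_relative")[int(rng.integers(3))]
        noun = lexicons.RELATION_NOUNS[(rel, sex)]
        sents.append(f"Something scary happened to {noun} last {month}.")
    symptoms, subtype, diagnosis = lexicons.MIMIC_SYNDROMES[
        int(rng.integers(len(lexicons.MIMIC_SYNDROMES)))]
    n_sym = int(rng.integers(1, len(symptoms) + 1))
    for i in rng.choice(len(symptoms), size=n_sym, replace=False):
        sym = symptoms[int(i)]
        if sym == "hemiparesis":
            pool = lexicons.HEMIPARESIS_SUBTYPE_TEMPLATES[subtype or "face"]
        else:
            pool = lexicons.SYMPTOM_TEMPLATES[sym]
        template, _sig = pool[int(rng.integers(len(pool)))]
        sents.append(_fill(template, pron))
    if voice == "first":
        sents.append("The paramedics took me to the emergency room.")
    else:
        sents.append(f"{pron['subj'].capitalize()} was rushed to the emergency "
                     "room by the paramedics.")
    sents.append(diagnosis)
    n_filler = int(rng.integers(1, 3))
    fillers = rng.choice(len(lexicons.STROKE_FILLER), size=n_filler, replace=False)
    sents.extend(_fill(lexicons.STROKE_FILLER[i], {}) for i in fillers)
    closing = "I am" if voice == "first" else f"{pron['subj'].capitalize()} is"
    sents.append(f"{closing} doing better now.")
    return " ".join(sents)


def render_story(profile: StoryProfile, rng: np.random.Generator) -> str:
    """Render a profile to free text.

    Every gold-flagged symptom contributes at least one phrase from its
    lexicon; first-person texts speak as the patient, third-person texts
    name a patient other than the narrator.  Surface form (templates,
    filler, month) varies with the generator state.
    """
    if profile.distractor_class == "nonstory":
        k = int(rng.integers(3, 7))
        picks = rng.choice(len(lexicons.NONSTORY_SENTENCES), size=k, replace=False)
        return " ".join(
            _fill(lexicons.NONSTORY_SENTENCES[i], {}) for i in picks
        )
    if profile.distractor_class == "other_story":
        topic = profile.topic or "travel"
        if topic == "medical":
            return _render_medical_distractor(rng)
        pool = lexicons.OTHER_STORY_SENTENCES[topic]
        k = int(rng.integers(3, min(7, len(pool) + 1)))
        picks = rng.choice(len(pool), size=k, replace=False)
        return " ".join(_fill(pool[i], {}) for i in picks)

    gold = profile.gold
    assert gold is not None
    voice = profile.voice or gold.narrator or "first"
    sex = gold.patient_sex or "female"
    pron = _PRONOUNS[("first", None)] if voice == "first" else _PRONOUNS[("third", sex)]
    month = lexicons.MONTHS[int(rng.integers(12))]

    sents: list[str] = []
    if voice == "first":
        sents.append(f"Last {month} something happened that changed everything.")
        noun = "woman" if sex == "female" else "man"
        if gold.age_years is not None:
            sents.append(f"I am a {noun}, {gold.age_years} years old.")
        else:
            sents.append(f"I am a {noun}.")
    else:
        rel = gold.relation or "friend"
        noun = lexicons.RELATION_NOUNS[(rel, sex)]
        sents.append(
            f"Something terrible happened to {noun} last {month}."
        )
        if gold.witness:
            sents.append("I was right there when it started.")
        elif gold.witness is False:
            sents.append("I was not there when it began and only heard about it after.")
        if gold.age_years is not None:
            sents.append(f"{pron['subj'].capitalize()} is {gold.age_years} years old.")

    symptom_sents = []
    for sym in SYMPTOMS:
        if not gold.symptoms.get(sym, False):
            continue
        if sym == "hemiparesis":
            pool = lexicons.HEMIPARESIS_SUBTYPE_TEMPLATES[
                gold.hemiparesis_subtype or "body"
            ]
        else:
            pool = lexicons.SYMPTOM_TEMPLATES[sym]
        template, _sig = pool[int(rng.integers(len(pool)))]
        symptom_sents.append(_fill(template, pron))
    order = rng.permutation(len(symptom_sents))
    sents.extend(symptom_sents[i] for i in order)

    if gold.sought_assistance is False:
        sents.append(
            f"{pron['subj'].capitalize()} never saw a doctor about it at the time."
        )
    else:
        if gold.delayed_assistance is True:
            who = "I" if voice == "first" else "We"
            sents.append(f"{who} waited hours before calling for help, hoping it would pass.")
        elif gold.delayed_assistance is False:
            who = "I" if voice == "first" else "We"
            sents.append(f"{who} called 911 straight away.")
        if voice == "first":
            sents.append("The paramedics took me to the emergency room.")
        else:
            sents.append(
                f"{pron['subj'].capitalize()} was rushed to the emergency room "
                "by the paramedics."
            )
        if gold.stroke_type == "ischemic":
            sents.append("The scans showed an ischemic stroke.")
        elif gold.stroke_type == "hemorrhagic":
            sents.append("They found a hemorrhagic stroke, bleeding in the brain.")
        elif rng.random() < 0.5:
            sents.append("The doctors said it was a stroke.")
        else:
            sents.append("The doctors were not sure at first what had happened.")
        if gold.immediate_treatment is True:
            sents.append(
                f"They started treatment as soon as {pron['subj']} arrived."
            )
        elif gold.immediate_treatment is False:
            sents.append(f"It took a long time before anyone treated {pron['obj']}.")

    n_filler = int(rng.integers(1, 4))
    fillers = rng.choice(len(lexicons.STROKE_FILLER), size=n_filler, replace=False)
    sents.extend(_fill(lexicons.STROKE_FILLER[i], {}) for i in fillers)
    closing = "I am" if voice == "first" else f"{pron['subj'].capitalize()} is"
    sents.append(f"{closing} doing better now.")
    return " ".join(sents)


def _assign_exact(rng, n, fraction, values):
    counts = largest_remainder(n, {values[0]: fraction, values[1]: 1 - fraction})
    arr = [values[0]] * counts[values[0]] + [values[1]] * counts[values[1]]
    return list(rng.permutation(arr))


def _assign_exact_multi(rng, n, mix):
    counts = largest_remainder(n, mix)
    arr = [k for k, c in counts.items() for _ in range(c)]
    return list(rng.permutation(arr))


def generate_corpus(config: CorpusConfig) -> list[BlogPost]:
    """Generate one corpus: stroke stories with gold codes, non-stroke
    personal stories, and non-story posts, shuffled together.  The same
    (config, seed) pair always yields a byte-identical corpus."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stroke_stories

    if config.mode == "exact_margins":
        narrators = _assign_exact(rng, n, config.narrator_first_fraction,
                                  ("first", "third"))
        sexes = _assign_exact(rng, n, config.female_fraction, ("female", "male"))
        types = _assign_exact_multi(rng, n, config.stroke_type_mix)
    else:
        narrators = ["first" if rng.random() < config.narrator_first_fraction
                     else "third" for _ in range(n)]
        sexes = ["female" if rng.random() < config.female_fraction
                 else "male" for _ in range(n)]
        types = [_choice(rng, config.stroke_type_mix) for _ in range(n)]

    profiles: list[StoryProfile] = []
    for i in range(n):
        prof = sample_profile(config.symptom_prevalence, rng,
                              sex=sexes[i], narrator=narrators[i])
        gold = prof.gold
        gold.stroke_type = types[i]
        if narrators[i] == "third":
            gold.relation = _choice(rng, config.relation_mix)
            gold.witness = bool(rng.random() < config.witness_fraction)
        if rng.random() < config.age_report_fraction:
            band = _choice(rng, config.age_band_weights)
            lo, hi = _AGE_BAND_RANGES[band]
            gold.age_years = int(rng.integers(lo, hi + 1))
            gold.age_band = age_band_for(gold.age_years)
        gold.sought_assistance = bool(
            rng.random() < config.sought_assistance_fraction
        )
        if gold.sought_assistance:
            if rng.random() < config.delay_report_fraction:
                gold.delayed_assistance = bool(
                    rng.random() < config.delayed_fraction[sexes[i]]
                )
            gold.immediate_treatment = bool(
                rng.random() < config.immediate_treatment_fraction
            )
        profiles.append(prof)

    for _ in range(config.n_other_stories):
        profiles.append(StoryProfile(
            distractor_class="other_story",
            topic=_choice(rng, lexicons.OTHER_STORY_TOPIC_WEIGHTS),
        ))
    for _ in range(config.n_nonstory_posts):
        profiles.append(StoryProfile(distractor_class="nonstory"))

    order = rng.permutation(len(profiles))
    start = datetime.date(2010, 1, 1)
    span = (datetime.date(2011, 12, 31) - start).days + 1
    posts: list[BlogPost] = []
    for pos, idx in enumerate(order):
        prof = profiles[int(idx)]
        pid = f"post-{pos:05d}"
        if prof.gold is not None:
            prof.gold.story_id = pid
        date = (start + datetime.timedelta(days=int(rng.integers(span)))).isoformat()
        text = render_story(prof, rng)
        posts.append(BlogPost(id=pid, date=date, text=text, gold=prof))
    return posts
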