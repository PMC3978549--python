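"""Synthetic corpus generator: margins, determinism, rendering, and
prevalence recovery."""

import io
import itertools

import numpy as np
import pytest

from strokestories import (
    CorpusConfig,
    PrevalenceTable,
    StoryProfile,
    default_prevalence,
    generate_corpus,
    render_story,
    sample_profile,
    write_corpus,
)
from strokestories.coding import SYMPTOMS, CodedStory
from strokestories.lexicons import (
    HEMIPARESIS_SUBTYPE_TEMPLATES,
    SYMPTOM_TEMPLATES,
)
from strokestories.synthetic import largest_remainder


def flat_prevalence(value: float) -> PrevalenceTable:
    return PrevalenceTable(
        {k: {"female": value, "male": value} for k in SYMPTOMS}
    )


def serialized(posts) -> bytes:
    buf = io.StringIO()

    class _W:
        def __init__(self):
            self.chunks = []

        def write(self, s):
            self.chunks.append(s)

    import json
    return "\n".join(
        json.dumps({"id": p.id, "date": p.date, "text": p.text}, sort_keys=True)
        for p in posts
    ).encode()


class TestGenerateCorpus:
    def test_no_planting_when_no_stroke_stories(self):
        cfg = CorpusConfig(n_stroke_stories=0, n_other_stories=0,
                           n_nonstory_posts=10, seed=3)
        posts = generate_corpus(cfg)
        assert len(posts) == 10
        assert all(p.gold.gold is None for p in posts)

    def test_exact_margins_reproduce_narrator_split(self):
        """191 stories at the observed narrator fraction plant exactly
        97 first-person and 94 third-person narrators."""
        cfg = CorpusConfig(n_stroke_stories=191, n_other_stories=50,
                           n_nonstory_posts=50, mode="exact_margins", seed=5)
        posts = generate_corpus(cfg)
        golds = [p.gold.gold for p in posts if p.gold.is_stroke]
        assert len(golds) == 191
        narrators = [g.narrator for g in golds]
        assert narrators.count("first") == 97
        assert narrators.count("third") == 94

    def test_exact_margins_sex_and_stroke_type(self):
        cfg = CorpusConfig(n_stroke_stories=174, n_other_stories=0,
                           n_nonstory_posts=10, mode="exact_margins", seed=6)
        golds = [p.gold.gold for p in generate_corpus(cfg) if p.gold.is_stroke]
        sexes = [g.patient_sex for g in golds]
        types = [g.stroke_type for g in golds]
        assert sexes.count("female") == 91 and sexes.count("male") == 83
        assert types.count("ischemic") == 67
        assert types.count("hemorrhagic") == 29
        assert types.count("unknown") == 78

    def test_same_seed_same_bytes(self):
        cfgs = [CorpusConfig(n_stroke_stories=30, n_other_stories=40,
                             n_nonstory_posts=40, seed=9) for _ in range(2)]
        a, b = (serialized(generate_corpus(c)) for c in cfgs)
        assert a == b

    def test_different_seed_differs(self):
        a = serialized(generate_corpus(
            CorpusConfig(n_stroke_stories=30, n_other_stories=40,
                         n_nonstory_posts=40, seed=9)))
        b = serialized(generate_corpus(
            CorpusConfig(n_stroke_stories=30, n_other_stories=40,
                         n_nonstory_posts=40, seed=10)))
        assert a != b

    def test_ids_unique_and_dates_in_window(self, small_corpus):
        ids = [p.id for p in small_corpus]
        assert len(set(ids)) == len(ids)
        assert all("2010-01-01" <= p.date <= "2011-12-31"
                   for p in small_corpus)


class TestLargestRemainder:
    def test_exact_split(self):
        assert largest_remainder(191, {"a": 97 / 191, "b": 94 / 191}) == \
            {"a": 97, "b": 94}

    def test_odd_total_half_fraction_goes_to_first_category(self):
        # documented floor-then-remainder rule: both floor to 2, the one
        # leftover unit goes to the first category (tie on remainders)
        assert largest_remainder(5, {"a": 0.5, "b": 0.5}) == {"a": 3, "b": 2}

    def test_total_preserved(self, rng):
        for _ in range(50):
            w = rng.dirichlet([1, 1, 1])
            n = int(rng.integers(1, 500))
            counts = largest_remainder(n, dict(zip("abc", w)))
            assert sum(counts.values()) == n


class TestRenderStory:
    def _profile(self, **symptoms):
        gold = CodedStory(story_id="x", narrator="first", patient_sex="female")
        for k in SYMPTOMS:
            gold.symptoms[k] = symptoms.get(k, False)
        if gold.symptoms.get("hemiparesis"):
            gold.hemiparesis_subtype = symptoms.get("subtype", "body")
        return StoryProfile(voice="first", gold=gold)

    def test_flagged_symptom_contributes_a_lexicon_phrase(self, rng):
        prof = self._profile(hemiparesis=True, subtype="body")
        text = render_story(prof, rng).lower()
        sigs = [sig for _, sig in HEMIPARESIS_SUBTYPE_TEMPLATES["body"]]
        assert any(s in text for s in sigs)

    def test_third_person_names_patient_not_narrator(self, rng):
        gold = CodedStory(story_id="x", narrator="third", patient_sex="female",
                          relation="spouse", witness=True)
        for k in SYMPTOMS:
            gold.symptoms[k] = False
        text = render_story(StoryProfile(voice="third", gold=gold), rng).lower()
        assert "my wife" in text
        assert "i am a woman" not in text

    def test_surface_variety_across_draws(self, rng):
        prof = self._profile(headache=True, vertigo=True)
        texts = {render_story(prof, rng) for _ in range(100)}
        assert len(texts) >= 2

    def test_distractor_profiles_carry_no_gold(self):
        with pytest.raises(ValueError):
            StoryProfile(distractor_class="other_story",
                         gold=CodedStory(story_id="x"))
        with pytest.raises(ValueError):
            StoryProfile(distractor_class="none", gold=None)


class TestSampleProfile:
    def test_zero_prevalence_all_flags_false(self, rng):
        prof = sample_profile(flat_prevalence(0.0), rng)
        assert not any(prof.gold.symptoms.values())

    def test_unit_prevalence_always_flagged(self, rng):
        for _ in range(20):
            prof = sample_profile(flat_prevalence(1.0), rng)
            assert all(prof.gold.symptoms.values())

    def test_female_speech_rate_recovers_table_value(self, rng):
        """At the observed female rate (59/91 = .648), n=2000 draws land
        within 3 binomial SE."""
        prev = default_prevalence()
        p = prev.rate("impaired_speech_or_comprehension", "female")
        hits = sum(
            sample_profile(prev, rng, sex="female")
            .gold.symptoms["impaired_speech_or_comprehension"]
            for _ in range(2000)
        )
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(hits / 2000 - p) < 3 * se

    def test_prevalence_recovery_every_symptom(self):
        """Sampled mode recovers every configured marginal rate within
        3 binomial SE at n=2000 (seeded)."""
        rng = np.random.default_rng(2024)
        prev = default_prevalence()
        n = 2000
        for sex, narrator in itertools.product(("female",), ("first",)):
            profs = [sample_profile(prev, rng, sex=sex, narrator=narrator)
                     for _ in range(n)]
            for sym in SYMPTOMS:
                p = prev.rate(sym, sex, narrator)
                obs = np.mean([pr.gold.symptoms[sym] for pr in profs])
                se = np.sqrt(p * (1 - p) / n)
                assert abs(obs - p) <= 3 * se, (sym, obs, p)


class TestSignatureDisjointness:
    def test_no_signature_triggers_a_foreign_symptom(self):
        """Every filled template must contain its own signature and no
        other symptom's — the auto-coder round trip rests on this."""
        pronouns = [
            {"subj": "i", "poss": "my", "obj": "me"},
            {"subj": "she", "poss": "her", "obj": "her"},
            {"subj": "he", "poss": "his", "obj": "him"},
        ]
        all_sigs = {
            sym: [sig for _, sig in pool]
            for sym, pool in SYMPTOM_TEMPLATES.items()
        }
        for sym, pool in SYMPTOM_TEMPLATES.items():
            for template, sig in pool:
                for pron in pronouns:
                    filled = template.format(**pron).lower()
                    assert sig in filled, (sym, template)
                    for other, sigs in all_sigs.items():
                        if other == sym:
                            continue
                        for s in sigs:
                            assert s not in filled, (sym, other, s)


class TestConfigValidation:
    def test_bad_mixture_weights(self):
        cfg = CorpusConfig()
        cfg.stroke_type_mix = {"ischemic": 0.5, "hemorrhagic": 0.5,
                               "unknown": 0.5}
        with pytest.raises(ValueError):
            cfg.validate()

    def test_negative_counts(self):
        cfg = CorpusConfig(n_stroke_stories=-1)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_prevalence_table_must_cover_taxonomy(self):
        with pytest.raises(ValueError):
            PrevalenceTable({"headache": {"female": 0.5, "male": 0.5}})
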