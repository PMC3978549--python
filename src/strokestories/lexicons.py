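"""Phrase pools for the synthetic corpus and the lexicon-inversion coder.

Every symptom template carries pronoun slots (``{subj}``, ``{poss}``,
``{obj}``) so one pool serves first- and third-person narration, plus a
pronoun-free *signature* substring.  The renderer emits the filled
template; the auto-coder flags a symptom iff one of its signatures
occurs in the text.  Signatures are kept mutually non-overlapping across
symptoms — the round-trip guarantee of the whole synthetic bench rests
on that property, and a test enforces it.

Distractor pools deliberately reuse emergency-room vocabulary and the
polysemous word "stroke" (heat stroke, golf strokes) so that ranked
retrieval has genuinely confusable negatives to reject.
"""

from __future__ import annotations

# (template, signature) per symptom; signature is a substring of the filled
# template for every pronoun binding.
SYMPTOM_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "hemiparesis": [],  # populated from subtype pools below
    "impaired_speech_or_comprehension": [
        ("{poss} speech did not make sense and was slurred",
         "speech did not make sense"),
        ("{subj} could not get the words out right no matter how hard {subj} tried",
         "could not get the words out"),
        ("{poss} words came out slurred and garbled",
         "slurred and garbled"),
        ("{subj} could not understand what people were saying to {obj}",
         "could not understand what people were saying"),
    ],
    "visual_disturbance": [
        ("{poss} vision went blurry in one eye", "vision went blurry"),
        ("{subj} started seeing double all of a sudden", "seeing double"),
        ("everything went dark on one side of {poss} vision",
         "dark on one side of"),
    ],
    "ataxia_discoordination": [
        ("{poss} hand would not do what {subj} wanted it to",
         "hand would not do what"),
        ("{subj} kept fumbling and dropping things", "fumbling and dropping"),
        ("{poss} movements were clumsy and uncoordinated",
         "clumsy and uncoordinated"),
    ],
    "vertigo": [
        ("the room was spinning around {obj}", "room was spinning"),
        ("{subj} felt a violent spinning sensation that would not stop",
         "spinning sensation"),
    ],
    "balance_difficulty": [
        ("{subj} kept tipping over to one side when {subj} tried to walk",
         "tipping over"),
        ("{subj} could hardly stand without holding onto the wall",
         "stand without holding"),
        ("{subj} staggered across the kitchen like something was badly wrong",
         "staggered across"),
    ],
    "pain_excl_headache": [
        ("a sharp pain shot down {poss} neck and shoulder",
         "sharp pain shot down"),
        ("{poss} whole left side ached terribly", "ached terribly"),
        ("a stabbing pain gripped {poss} back", "stabbing pain"),
    ],
    "mental_status_change": [
        ("{subj} felt confused and could not think clearly",
         "confused and could not think"),
        ("{subj} was disoriented and did not know where {subj} was",
         "disoriented"),
        ("{subj} blacked out and lost consciousness for a while",
         "lost consciousness"),
    ],
    "headache": [
        ("it was the worst headache of {poss} life", "worst headache"),
        ("{poss} head was pounding like never before", "head was pounding"),
        ("a sudden crushing headache came on out of nowhere",
         "crushing headache"),
    ],
    "lightheadedness": [
        ("{subj} felt lightheaded and woozy", "lightheaded"),
        ("{subj} felt faint, like {subj} might pass out", "might pass out"),
    ],
    "other_neurologic": [
        ("{subj} felt sick to {poss} stomach and nauseous", "nauseous"),
        ("{subj} got hiccups that would not stop", "hiccups"),
        ("a wave of weakness washed over {poss} whole body",
         "weakness washed over"),
    ],
    "nonneurologic": [
        ("{poss} chest felt tight and {poss} heart was racing",
         "heart was racing"),
        ("{subj} was suddenly short of breath", "short of breath"),
        ("{poss} heart started pounding with palpitations", "palpitations"),
    ],
}

HEMIPARESIS_SUBTYPE_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "body": [
        ("{subj} could not pick up {poss} arm or leg on one side",
         "arm or leg on one side"),
        ("{poss} right arm went completely limp", "arm went completely limp"),
        ("{subj} had no strength down one side of {poss} body",
         "no strength down one side"),
    ],
    "face": [
        ("one side of {poss} face was drooping", "face was drooping"),
        ("{poss} smile came out crooked on one side", "smile came out crooked"),
    ],
    "both": [
        ("{poss} face drooped and {poss} arm hung useless on the same side",
         "face drooped and"),
        ("half of {poss} face sagged while that arm and leg gave out",
         "face sagged while"),
    ],
}
SYMPTOM_TEMPLATES["hemiparesis"] = [
    t for pool in HEMIPARESIS_SUBTYPE_TEMPLATES.values() for t in pool
]

# Patient nouns for third-person narration, keyed by (relation, patient sex).
RELATION_NOUNS: dict[tuple[str, str], str] = {
    ("adult_child", "female"): "my mother",
    ("adult_child", "male"): "my father",
    ("spouse", "female"): "my wife",
    ("spouse", "male"): "my husband",
    ("other_relative", "female"): "my aunt",
    ("other_relative", "male"): "my uncle",
    ("friend", "female"): "my friend",
    ("friend", "male"): "my friend",
    ("stranger", "female"): "a stranger",
    ("stranger", "male"): "a stranger",
}

MONTHS = ("january", "february", "march", "april", "may", "june", "july",
          "august", "september", "october", "november", "december")

# Neutral filler, free of every signature above.
STROKE_FILLER = (
    "it all happened so fast",
    "nothing like this had ever happened before",
    "looking back the signs were there",
    "the whole family was terrified",
    "writing this down helps me process it",
    "every minute felt like an hour",
    "we are still coming to terms with it",
    "recovery has been slow but steady since then",
)

OTHER_STORY_SENTENCES: dict[str, tuple[str, ...]] = {
    "travel": (
        "we spent the whole morning wandering the old town",
        "i missed the connecting train and slept in the station",
        "the beach was packed but the water was perfect",
        "i nearly got heat stroke hiking the canyon at noon",
        "i got sunburned badly enough to spend a day indoors",
        "our luggage turned up three days late",
        "the street food was the best part of the trip",
    ),
    "sports": (
        "our team finally won the league match on saturday",
        "i shaved two strokes off my golf game this summer",
        "the coach made us run drills until sunset",
        "my backstroke still needs work before the meet",
        "my breaststroke is finally faster than my backstroke",
        "we lost in the final minute on a penalty",
        "training for the marathon is taking over my weekends",
    ),
    "work": (
        "the quarterly report was due and the printer died",
        "my manager moved the deadline up a week",
        "i finally got the promotion i had been chasing",
        "the new hire quit after three days",
        "we shipped the release two days early for once",
    ),
    "minor_emergency": (
        "i twisted an ankle at practice and dad drove me to the emergency room",
        "the paramedics checked him over after the fender bender",
        "we called 911 when the neighbor's grill caught fire",
        "the doctor said it was just a bad sprain and sent us home",
        "the emergency room was packed so we waited half the night",
        "she needed two stitches but the nurse was lovely about it",
        "they ran a scan just to be safe and everything looked fine",
        "the doctors kept him overnight for observation",
        "he was diagnosed with a mild concussion after the fall",
    ),
    "health_scare": (
        "halfway through the marathon my buddy collapsed and we feared the worst",
        "we thought it was a stroke at first but the tests came back clear",
        "the doctors ran every scan they had and found nothing serious",
        "grandpa gave us a scare at dinner but it was only low blood sugar",
        "the paramedics said her blood pressure had dropped from the heat",
        "after the tests the doctor said it was a pinched nerve and not a heart attack",
        "they took him to the hospital but it turned out to be dehydration",
        "the emergency room doctor sent us home with fluids and rest",
    ),
}

# Non-stroke medical-emergency stories are rendered through the same
# narrative machinery as stroke stories (opener, emergency-room block,
# filler, closing).  They are *stroke mimics*: conditions that present
# with genuinely stroke-like symptom language — migraine with aura,
# inner-ear vertigo, Bell's palsy, hypoglycemia, panic attack — so that
# only the substance of the story separates them from true positives.
# These emulate the retrieved-but-irrelevant stories a prototype-story
# query inevitably drags in, and are the retrieval task's hard negatives.
# Each entry: (symptom keys to narrate, hemiparesis subtype if any,
# diagnosis sentence).
MIMIC_SYNDROMES = (
    (("visual_disturbance", "headache", "lightheadedness"), None,
     "It turned out to be a migraine with aura."),
    (("vertigo", "balance_difficulty", "other_neurologic"), None,
     "It turned out to be an inner ear infection."),
    (("nonneurologic", "lightheadedness"), None,
     "The doctors said it was a panic attack."),
    (("hemiparesis",), "face",
     "The diagnosis came back as bell's palsy."),
    (("mental_status_change", "lightheadedness"), None,
     "It was low blood sugar, not a stroke."),
    (("impaired_speech_or_comprehension", "headache"), None,
     "They said it was a complicated migraine, not a stroke."),
)

# Topic mix for non-stroke personal stories: the medical near-misses get
# the largest share, mirroring how many retrieved-but-irrelevant stories
# a story-seeded query returns.
OTHER_STORY_TOPIC_WEIGHTS = {
    "travel": 0.15, "sports": 0.15, "work": 0.15,
    "minor_emergency": 0.15, "health_scare": 0.15, "medical": 0.25,
}

NONSTORY_SENTENCES = (
    "this camera produces stunning photos for the price",
    "the battery life is easily the best in its class",
    "here are five tips for keeping your garden alive in august",
    "the council voted to extend the bike lane downtown",
    "whisk the eggs and sugar until pale and fluffy",
    "the sequel improves on the original in every way",
    "local markets reported higher prices this quarter",
    "preheat the oven and line the tray with parchment",
    "the update fixes the login bug many users reported",
    "critics are divided on the director's latest film",
)

# The fictional prototype story used as the initial retrieval query.  The
# original study's exemplar is not reproduced anywhere; this one is the
# package's own, written in the same colloquial register and seeded with
# the same kind of symptom and emergency keywords.
PROTOTYPE_STORY = (
    "Last spring I had a stroke and I still can hardly believe it. "
    "It came out of nowhere while I was making breakfast. "
    "My speech did not make sense and was slurred. "
    "I could not pick up my arm or leg on one side. "
    "I felt confused and could not think clearly. "
    "My wife called 911 and the paramedics came within minutes. "
    "At the emergency room the doctors ran scans and I was diagnosed with stroke. "
    "They started treatment right there at the hospital."
)


def _sigs(key: str) -> list[str]:
    return [sig for _, sig in SYMPTOM_TEMPLATES[key]]


def auto_code_lexicons() -> dict[str, list[str]]:
    """Signature lists for :func:`strokestories.coding.auto_code`.

    Covers every symptom key plus the reserved marker keys for narrator,
    patient sex, relation, witness, stroke type and assistance fields.
    """
    lex: dict[str, list[str]] = {k: _sigs(k) for k in SYMPTOM_TEMPLATES}
    for sub, pool in HEMIPARESIS_SUBTYPE_TEMPLATES.items():
        lex[f"_hemiparesis_{sub}"] = [sig for _, sig in pool]
    lex["_narrator_third"] = [
        "my mother", "my father", "my wife", "my husband",
        "my aunt", "my uncle", "my friend", "a stranger",
    ]
    lex["_sex_female"] = ["i am a woman", "she was rushed", "she is doing"]
    lex["_sex_male"] = ["i am a man", "he was rushed", "he is doing"]
    lex["_rel_adult_child"] = ["my mother", "my father"]
    lex["_rel_spouse"] = ["my wife", "my husband"]
    lex["_rel_other_relative"] = ["my aunt", "my uncle"]
    lex["_rel_friend"] = ["my friend"]
    lex["_rel_stranger"] = ["a stranger"]
    lex["_witness_yes"] = ["i was right there when"]
    lex["_witness_no"] = ["i was not there when", "i only heard about"]
    lex["_type_ischemic"] = ["ischemic stroke"]
    lex["_type_hemorrhagic"] = ["hemorrhagic stroke", "bleeding in the brain"]
    lex["_sought_no"] = ["never saw a doctor about"]
    lex["_delay_yes"] = ["waited hours before"]
    lex["_delay_no"] = ["straight away"]
    lex["_treatment_immediate"] = ["treatment as soon as"]
    lex["_treatment_delayed"] = ["before anyone treated"]
    return lex
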