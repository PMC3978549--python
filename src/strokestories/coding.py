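"""Code book for stroke-experience narratives.

The schema captures what a human coder records for each relevant story:
who tells it (the patient, or a third person with a stated relation),
the patient's sex and age, which symptoms of the closed coding taxonomy
the narrative reports, the medically stated stroke type, and whether and
how promptly medical assistance was sought.

Symptoms split into two classes.  *Traditional* symptoms are focal
neurological signs (hemiparesis/hemiplegia, impaired speech or
comprehension, visual disturbance, ataxia/discoordination, vertigo,
difficulty with balance).  *Nontraditional* symptoms are non-focal
(pain excluding headache, mental status change, headache,
lightheadedness, other neurologic, nonneurologic).  Headache is
classed nontraditional because it is not a focal sign and is common
across many conditions.  Each symptom is a dichotomous flag covering the
window from symptom onset until medical assistance was secured.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TRADITIONAL_SYMPTOMS",
    "NONTRADITIONAL_SYMPTOMS",
    "SYMPTOMS",
    "SYMPTOM_TAXONOMY",
    "AGE_BANDS",
    "RELATIONS",
    "CodedStory",
    "classify_symptom",
    "derive_flags",
    "validate",
    "percent_agreement",
    "cohen_kappa",
    "auto_code",
    "age_band_for",
    "read_records_csv",
    "write_records_csv",
]

TRADITIONAL_SYMPTOMS: tuple[str, ...] = (
    "hemiparesis",
    "impaired_speech_or_comprehension",
    "visual_disturbance",
    "ataxia_discoordination",
    "vertigo",
    "balance_difficulty",
)

NONTRADITIONAL_SYMPTOMS: tuple[str, ...] = (
    "pain_excl_headache",
    "mental_status_change",
    "headache",
    "lightheadedness",
    "other_neurologic",
    "nonneurologic",
)

#: Closed taxonomy: 6 traditional keys (hemiparesis carries a
#: body/face/both subtype recorded separately) and 6 nontraditional keys.
SYMPTOMS: tuple[str, ...] = TRADITIONAL_SYMPTOMS + NONTRADITIONAL_SYMPTOMS

SYMPTOM_TAXONOMY: dict[str, str] = {
    **{k: "traditional" for k in TRADITIONAL_SYMPTOMS},
    **{k: "nontraditional" for k in NONTRADITIONAL_SYMPTOMS},
}

AGE_BANDS: tuple[str, ...] = (
    "0-17", "18-29", "30-44", "45-64", "65-75", "76-84", "85+",
)

RELATIONS: tuple[str, ...] = (
    "adult_child", "spouse", "other_relative", "friend", "stranger",
)

HEMIPARESIS_SUBTYPES: tuple[str, ...] = ("body", "face", "both")

STROKE_TYPES: tuple[str, ...] = ("ischemic", "hemorrhagic", "unknown")

_AGE_BAND_EDGES = {
    "0-17": (0, 17), "18-29": (18, 29), "30-44": (30, 44),
    "45-64": (45, 64), "65-75": (65, 75), "76-84": (76, 84),
    "85+": (85, 200),
}


def age_band_for(age_years: int) -> str:
    """Map an age in years onto the coding scheme's 7 age bands."""
    for band, (lo, hi) in _AGE_BAND_EDGES.items():
        if lo <= age_years <= hi:
            return band
    raise ValueError(f"age out of range: {age_years}")


@dataclass
class CodedStory:
    """One coded narrative: the full record a coder fills in per story.

    ``narrator`` is ``first`` when the patient tells the story, ``third``
    otherwise; ``witness`` and ``relation`` apply only to third-person
    narrators.  Stories that do not identify the patient's sex are kept
    but flagged excluded rather than deleted (``excluded_no_sex``).
    Optional fields are ``None`` when the narrative does not report them.
    """

    story_id: str
    narrator: Optional[str] = None              # {first, third}
    witness: Optional[bool] = None              # third-person only
    relation: Optional[str] = None              # third-person only
    patient_sex: Optional[str] = None           # {female, male}
    age_years: Optional[int] = None
    age_band: Optional[str] = None
    symptoms: dict[str, bool] = field(default_factory=dict)
    hemiparesis_subtype: Optional[str] = None   # {body, face, both}
    stroke_type: Optional[str] = None           # {ischemic, hemorrhagic, unknown}
    sought_assistance: Optional[bool] = None
    delayed_assistance: Optional[bool] = None
    immediate_treatment: Optional[bool] = None

    @property
    def excluded_no_sex(self) -> bool:
        """Stories without patient sex were set aside by the study protocol."""
        return self.patient_sex is None

    def symptom(self, key: str) -> bool:
        if key not in SYMPTOM_TAXONOMY:
            raise KeyError(f"unknown symptom key: {key!r}")
        return bool(self.symptoms.get(key, False))


def classify_symptom(key: str) -> str:
    """Return ``traditional`` or ``nontraditional`` for a symptom key.

    The taxonomy is closed: any key outside it is a hard error.
    """
    try:
        return SYMPTOM_TAXONOMY[key]
    except KeyError:
        raise KeyError(f"unknown symptom key: {key!r}") from None


def derive_flags(record: CodedStory) -> dict[str, bool]:
    """Derived group indicators used by the narrator analyses.

    ``any_nontraditional_excl_msc`` exists because mental status change is
    analysed on its own; the remaining nontraditional symptoms are pooled.
    """
    trad = any(record.symptom(k) for k in TRADITIONAL_SYMPTOMS)
    nontrad = any(record.symptom(k) for k in NONTRADITIONAL_SYMPTOMS)
    excl = any(
        record.symptom(k) for k in NONTRADITIONAL_SYMPTOMS
        if k != "mental_status_change"
    )
    return {
        "any_traditional": trad,
        "any_nontraditional": nontrad,
        "any_nontraditional_excl_msc": excl,
    }


def validate(record: CodedStory) -> list[str]:
    """Check schema invariants; returns violation messages (empty = valid).

    Violations are data, not exceptions: a coder-facing tool reports them
    all at once instead of dying on the first.
    """
    v: list[str] = []
    if record.narrator is not None and record.narrator not in ("first", "third"):
        v.append(f"narrator: invalid value {record.narrator!r}")
    if record.narrator == "first":
        if record.relation is not None:
            v.append("relation: present but narrator is first-person")
        if record.witness is not None:
            v.append("witness: present but narrator is first-person")
    if record.patient_sex is not None and record.patient_sex not in ("female", "male"):
        v.append(f"patient_sex: invalid value {record.patient_sex!r}")
    if record.relation is not None and record.relation not in RELATIONS:
        v.append(f"relation: invalid value {record.relation!r}")
    if record.age_band is not None and record.age_band not in AGE_BANDS:
        v.append(f"age_band: invalid value {record.age_band!r}")
    if record.age_years is not None and record.age_band is not None:
        if age_band_for(record.age_years) != record.age_band:
            v.append(
                f"age_band: {record.age_band} inconsistent with "
                f"age_years={record.age_years}"
            )
    for key in record.symptoms:
        if key not in SYMPTOM_TAXONOMY:
            v.append(f"symptoms: unknown key {key!r}")
    has_hemi = record.symptoms.get("hemiparesis", False)
    if has_hemi and record.hemiparesis_subtype is None:
        v.append("hemiparesis_subtype: required when hemiparesis is reported")
    if not has_hemi and record.hemiparesis_subtype is not None:
        v.append("hemiparesis_subtype: present without hemiparesis")
    if (record.hemiparesis_subtype is not None
            and record.hemiparesis_subtype not in HEMIPARESIS_SUBTYPES):
        v.append(f"hemiparesis_subtype: invalid value {record.hemiparesis_subtype!r}")
    if record.stroke_type is not None and record.stroke_type not in STROKE_TYPES:
        v.append(f"stroke_type: invalid value {record.stroke_type!r}")
    return v


# Fields entering the coder-agreement comparison: everything a coder fills
# in, with the 13 symptom flags expanded to one cell each.
_AGREEMENT_SCALAR_FIELDS = (
    "narrator", "witness", "relation", "patient_sex", "age_years", "age_band",
    "hemiparesis_subtype", "stroke_type", "sought_assistance",
    "delayed_assistance", "immediate_treatment",
)


def _cells(record: CodedStory) -> list[object]:
    row: list[object] = [getattr(record, f) for f in _AGREEMENT_SCALAR_FIELDS]
    row.extend(bool(record.symptoms.get(k, False)) for k in SYMPTOMS)
    return row


def percent_agreement(
    coder_a: Sequence[CodedStory], coder_b: Sequence[CodedStory]
) -> float:
    """Raw per-field agreement between two coders over the same stories.

    The fraction of (story, field) cells on which the coders agree, over
    all schema fields; a missing value agreeing with a missing value
    counts as agreement.  Per-field (rather than per-story) granularity
    is this package's stated reading of the reported metric.
    """
    a_by_id = {r.story_id: r for r in coder_a}
    b_by_id = {r.story_id: r for r in coder_b}
    if set(a_by_id) != set(b_by_id):
        missing = set(a_by_id) ^ set(b_by_id)
        raise ValueError(f"coder record sets cover different stories: {sorted(missing)}")
    if not a_by_id:
        raise ValueError("no records to compare")
    agree = total = 0
    for sid, ra in a_by_id.items():
        for ca, cb in zip(_cells(ra), _cells(b_by_id[sid])):
            total += 1
            agree += ca == cb
    return agree / total


def cohen_kappa(
    coder_a: Sequence[CodedStory], coder_b: Sequence[CodedStory]
) -> float:
    """Chance-corrected agreement (Cohen's kappa) over the same cells.

    Offered alongside :func:`percent_agreement`, clearly labelled: the
    study's reported figure is raw percent agreement, not kappa.  Cells
    are pooled across fields; each cell pair is one rating.
    """
    a_by_id = {r.story_id: r for r in coder_a}
    b_by_id = {r.story_id: r for r in coder_b}
    if set(a_by_id) != set(b_by_id):
        raise ValueError("coder record sets cover different stories")
    pairs = [
        (str(ca), str(cb))
        for sid, ra in a_by_id.items()
        for ca, cb in zip(_cells(ra), _cells(b_by_id[sid]))
    ]
    n = len(pairs)
    po = sum(a == b for a, b in pairs) / n
    cats = sorted({c for p in pairs for c in p})
    pa = {c: sum(a == c for a, _ in pairs) / n for c in cats}
    pb = {c: sum(b == c for _, b in pairs) / n for c in cats}
    pe = sum(pa[c] * pb[c] for c in cats)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def auto_code(text: str, lexicons: Mapping[str, Sequence[str]],
              story_id: str = "") -> CodedStory:
    """Lexicon-inversion coder: flag a symptom iff one of its phrases occurs.

    This is the mechanical inverse of the synthetic generator's renderer,
    used to close the generate -> render -> code loop in end-to-end tests.
    It is not a clinical NLP system.  Narrator, patient sex and stroke
    type are read off marker phrases when the lexicon mapping carries the
    reserved ``_narrator_third``, ``_sex_female``/``_sex_male`` and
    ``_type_*`` entries.
    """
    for key in SYMPTOMS:
        if key not in lexicons:
            raise KeyError(f"lexicons do not cover symptom {key!r}")
    low = text.lower()
    rec = CodedStory(story_id=story_id)
    for key in SYMPTOMS:
        rec.symptoms[key] = any(p.lower() in low for p in lexicons[key])
    if rec.symptoms.get("hemiparesis"):
        for sub in HEMIPARESIS_SUBTYPES:
            marker = lexicons.get(f"_hemiparesis_{sub}", ())
            if any(p.lower() in low for p in marker):
                rec.hemiparesis_subtype = sub
                break
        else:
            rec.hemiparesis_subtype = "body"
    third_markers = lexicons.get("_narrator_third", ())
    rec.narrator = "third" if any(p.lower() in low for p in third_markers) else "first"
    for sex in ("female", "male"):
        if any(p.lower() in low for p in lexicons.get(f"_sex_{sex}", ())):
            rec.patient_sex = sex
            break
    for st in ("ischemic", "hemorrhagic"):
        if any(p.lower() in low for p in lexicons.get(f"_type_{st}", ())):
            rec.stroke_type = st
            break
    if rec.narrator == "third":
        for rel in RELATIONS:
            if any(p.lower() in low for p in lexicons.get(f"_rel_{rel}", ())):
                rec.relation = rel
                break
        if any(p.lower() in low for p in lexicons.get("_witness_yes", ())):
            rec.witness = True
        elif any(p.lower() in low for p in lexicons.get("_witness_no", ())):
            rec.witness = False
    m = re.search(r"\b(\d{1,3}) years old\b", low)
    if m:
        rec.age_years = int(m.group(1))
        rec.age_band = age_band_for(rec.age_years)
    if any(p.lower() in low for p in lexicons.get("_sought_no", ())):
        rec.sought_assistance = False
    else:
        rec.sought_assistance = True
        if any(p.lower() in low for p in lexicons.get("_delay_yes", ())):
            rec.delayed_assistance = True
        elif any(p.lower() in low for p in lexicons.get("_delay_no", ())):
            rec.delayed_assistance = False
        if any(p.lower() in low for p in lexicons.get("_treatment_immediate", ())):
            rec.immediate_treatment = True
        elif any(p.lower() in low for p in lexicons.get("_treatment_delayed", ())):
            rec.immediate_treatment = False
    return rec


# ---------------------------------------------------------------------------
# CSV round-trip.  One column per schema field; controlled vocabularies
# spelled exactly as in the type definitions; empty cell = missing.

_CSV_COLUMNS = (
    ("story_id",), _AGREEMENT_SCALAR_FIELDS, SYMPTOMS,
)
_BOOL_FIELDS = {
    "witness", "sought_assistance", "delayed_assistance", "immediate_treatment",
}


def _csv_header() -> list[str]:
    return ["story_id", *_AGREEMENT_SCALAR_FIELDS, *SYMPTOMS]


def write_records_csv(records: Iterable[CodedStory], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_csv_header())
        for r in records:
            row = [r.story_id]
            for f in _AGREEMENT_SCALAR_FIELDS:
                val = getattr(r, f)
                if val is None:
                    row.append("")
                elif isinstance(val, bool):
                    row.append("true" if val else "false")
                else:
                    row.append(str(val))
            row.extend(
                "true" if r.symptoms.get(k, False) else "false" for k in SYMPTOMS
            )
            w.writerow(row)


def read_records_csv(path) -> list[CodedStory]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            rec = CodedStory(story_id=row["story_id"])
            for f in _AGREEMENT_SCALAR_FIELDS:
                raw = row.get(f, "")
                if raw == "" or raw is None:
                    continue
                if f in _BOOL_FIELDS:
                    setattr(rec, f, raw == "true")
                elif f == "age_years":
                    rec.age_years = int(raw)
                else:
                    setattr(rec, f, raw)
            for k in SYMPTOMS:
                rec.symptoms[k] = row.get(k, "false") == "true"
            records.append(rec)
    return records
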