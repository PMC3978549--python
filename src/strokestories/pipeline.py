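"""End-to-end reproducible runs: simulate -> filter -> retrieve ->
auto-code -> tabulate -> test.

One seed drives every stochastic stage (stage-local generators are
derived at fixed offsets), so identical configs produce identical
artifact checksums; the manifest records them for verification.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from . import __version__
from .coding import SYMPTOMS, auto_code, write_records_csv
from .corpus_io import corpus_config_to_dict, write_corpus
from .lexicons import PROTOTYPE_STORY, auto_code_lexicons
from .retrieval import RocchioParams, build_index, run_feedback_session
from .stats import (
    SmallExpectedCountWarning,
    crosstab,
    logistic_from_2x2,
    pearson_chi2,
)
from .story_filter import evaluate_filter, noise_filter
from .synthetic import CorpusConfig, generate_corpus

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline",
           "analyze_records", "analyses_to_markdown"]

log = logging.getLogger("strokestories")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    precision_target: float = 0.66
    recall_target: float = 0.5
    rocchio: RocchioParams = field(default_factory=RocchioParams)
    batch_size: int = 40
    rounds: int = 5
    prototype_text: str = PROTOTYPE_STORY
    out_dir: str = "pipeline-out"
    seed: int = 0

    def __post_init__(self):
        # one seed fans out to the stages at fixed offsets
        self.corpus.seed = self.seed

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["corpus"] = corpus_config_to_dict(self.corpus)
        return out


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: str
    finished: str
    checksums: dict[str, str]
    stages: dict[str, dict]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _safe_p(table) -> str:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallExpectedCountWarning)
            return pearson_chi2(table).p_printed_3dp
    except ValueError:
        return "n/a"


def analyze_records(records) -> dict[str, pd.DataFrame]:
    """Crosstab-and-test analyses mirroring the printed tables, computed
    from coded records: narrator profiles, symptoms by sex, mental
    status change by sex and narrator, pooled nontraditional symptoms
    by narrator, symptoms by stroke type, and delay by sex."""
    usable = [r for r in records if not r.excluded_no_sex]
    if not usable:
        raise ValueError("empty selection: no records with patient sex")
    out: dict[str, pd.DataFrame] = {}

    def rows_of(table, p):
        return [
            {"category": str(rl),
             **{str(cl): int(table.counts[i, j])
                for j, cl in enumerate(table.col_labels)},
             "P": p if i == 0 else ""}
            for i, rl in enumerate(table.row_labels)
        ]

    t = crosstab(usable, "narrator", "patient_sex")
    rows = rows_of(t, _safe_p(t))
    out["narrator_profiles"] = pd.DataFrame(rows)

    rows = []
    for sym in SYMPTOMS:
        t = crosstab(usable, "patient_sex", sym)
        rows.append({
            "symptom": sym,
            "female_yes": int(t.counts[0, 0]) if "female" in t.row_labels else 0,
            "male_yes": (int(t.counts[t.row_labels.index("male"), 0])
                         if "male" in t.row_labels else 0),
            "P": _safe_p(t),
        })
    out["symptoms_by_sex"] = pd.DataFrame(rows)

    rows = []
    for narrator in ("first", "third"):
        try:
            t = crosstab(usable, "patient_sex", "mental_status_change",
                         where=lambda r, n=narrator: r.narrator == n)
            rows.extend([{"narrator": narrator, **row}
                         for row in rows_of(t, _safe_p(t))])
        except ValueError:
            pass
    out["msc_by_sex_and_narrator"] = pd.DataFrame(rows)

    t = crosstab(usable, "narrator", "any_nontraditional_excl_msc")
    p = _safe_p(t)
    logit_line = ""
    if t.counts.shape == (2, 2) and (t.counts.sum(axis=1) > 0).all():
        try:
            fit = logistic_from_2x2(t, names=["intercept", "first_person"])
            logit_line = f"OR={fit.odds_ratios[1]:.2f}"
        except ValueError:
            pass
    rows = rows_of(t, p)
    if rows and logit_line:
        rows[0]["logistic"] = logit_line
    out["nontrad_excl_msc_by_narrator"] = pd.DataFrame(rows)

    typed = [r for r in usable if r.stroke_type in ("ischemic", "hemorrhagic")]
    rows = []
    if typed:
        for sym in SYMPTOMS:
            try:
                t = crosstab(typed, "stroke_type", sym)
                rows.append({
                    "symptom": sym,
                    "ischemic_yes": (int(t.counts[t.row_labels.index("ischemic"), 0])
                                     if "ischemic" in t.row_labels else 0),
                    "hemorrhagic_yes": (int(t.counts[t.row_labels.index("hemorrhagic"), 0])
                                        if "hemorrhagic" in t.row_labels else 0),
                    "P": _safe_p(t),
                })
            except ValueError:
                pass
    out["symptoms_by_stroke_type"] = pd.DataFrame(rows)

    delayed = [r for r in usable if r.delayed_assistance is not None]
    if delayed:
        t = crosstab(delayed, "patient_sex", "delayed_assistance")
        out["delay_by_sex"] = pd.DataFrame(rows_of(t, _safe_p(t)))
    else:
        out["delay_by_sex"] = pd.DataFrame()
    return out


def analyses_to_markdown(analyses: dict[str, pd.DataFrame]) -> str:
    chunks = []
    for name, df in analyses.items():
        chunks.append(f"## {name}\n")
        chunks.append(df.to_markdown(index=False) if not df.empty else "(empty)")
        chunks.append("")
    return "\n".join(chunks)


def run_pipeline(config: PipelineConfig,
                 judge: Optional[Callable] = None) -> RunManifest:
    """Execute the whole pipeline and write artifacts + manifest under
    ``config.out_dir``.  Any stage failure raises :class:`PipelineError`
    naming the stage."""
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    try:
        posts = generate_corpus(config.corpus)
        write_corpus(posts, out / "corpus.jsonl")
        stages["simulate"] = {"n_posts": len(posts)}
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("simulate", str(e)) from e

    try:
        flagged = noise_filter(posts, config.precision_target,
                               config.recall_target, seed=config.seed + 1)
        (out / "flagged_ids.txt").write_text(
            "".join(f"{i}\n" for i in sorted(flagged)), encoding="utf-8")
        gold_story_ids = {p.id for p in posts
                         if p.gold is not None and p.gold.is_story}
        pr = evaluate_filter(flagged, gold_story_ids)
        stages["filter"] = {"n_flagged": len(flagged),
                            "precision": pr.precision, "recall": pr.recall}
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("filter", str(e)) from e

    try:
        by_id = {p.id: p for p in posts}
        searchable = [by_id[i] for i in sorted(flagged)]
        index = build_index(searchable)
        if judge is None:
            def judge(doc_id: str) -> str:
                g = by_id[doc_id].gold
                if g is not None and g.is_stroke:
                    return "skip" if g.gold.patient_sex is None else "relevant"
                return "irrelevant"
        session = run_feedback_session(
            index, config.prototype_text, judge,
            batch_size=config.batch_size, rounds=config.rounds,
            params=config.rocchio,
        )
        session.save(out / "session.json")
        stages["retrieve"] = {
            "precision_series": session.precision_series,
            "n_relevant": len(session.relevant_ids),
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("retrieve", str(e)) from e

    try:
        lex = auto_code_lexicons()
        records = [auto_code(by_id[i].text, lex, story_id=i)
                   for i in session.relevant_ids]
        write_records_csv(records, out / "records.csv")
        stages["auto_code"] = {"n_records": len(records)}
    except Exception as e:
        raise PipelineError("auto_code", str(e)) from e

    try:
        analyses = analyze_records(records)
        md = analyses_to_markdown(analyses)
        (out / "report.md").write_text(md, encoding="utf-8")
        for name, df in analyses.items():
            df.to_csv(out / f"report_{name}.csv", index=False)
        stages["tabulate"] = {"analyses": sorted(analyses)}
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("tabulate", str(e)) from e

    # the hash identifies the scientific configuration; where the
    # artifacts land is not part of it
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    config_blob = json.dumps(hashed, sort_keys=True).encode()
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_blob).hexdigest(),
        version=__version__,
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        checksums=checksums,
        stages=stages,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_json(), indent=1, sort_keys=True),
        encoding="utf-8")
    return manifest
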