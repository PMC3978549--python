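"""The printed study tables as a versioned fixture asset.

The asset ships with the package and stores, exactly as printed, the
counts of the six summary tables plus the in-text contingency analyses
(age by sex; narrator profiles; symptoms by sex; mental status change by
sex and narrator; pooled nontraditional symptoms; symptoms by stroke
type; delay in seeking assistance).  A SHA-256 checksum guards against
silent edits, and the margins are re-validated on every load.

:func:`reproduce_tables` recomputes each table's percentage cells and
its P column (uncorrected Pearson chi-square) from the stored counts;
:func:`expand_table` materializes coded records consistent with any
single table's margins — joint consistency *across* tables cannot be
recovered from marginals and is not claimed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .coding import CodedStory
from .stats import (
    ContingencyTable,
    SmallExpectedCountWarning,
    pearson_chi2,
    round_half_up,
)

__all__ = [
    "load_fixture_tables",
    "expand_table",
    "section_table",
    "symptom_row_table",
    "reproduce_tables",
    "report_to_markdown",
]

_ASSET = "printed_tables.json"


def _asset_bytes(name: str) -> bytes:
    return resources.files("strokestories.data").joinpath(name).read_bytes()


def load_fixture_tables() -> dict:
    """Load and validate the printed-table asset.

    A checksum mismatch (tampered or corrupted asset) and any margin
    inconsistency are hard errors.
    """
    raw = _asset_bytes(_ASSET)
    expected = _asset_bytes(_ASSET.replace(".json", ".sha256")).decode().strip()
    actual = hashlib.sha256(raw).hexdigest()
    if actual != expected:
        raise ValueError(
            f"fixture asset checksum mismatch: {actual} != {expected}"
        )
    fixture = json.loads(raw)
    _validate_margins(fixture)
    return fixture


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"fixture margin check failed: {msg}")


def _validate_margins(fx: dict) -> None:
    t1 = fx["table1"]
    sums = np.array([[r[1], r[2]] for r in t1["rows"]]).sum(axis=0)
    _check(sums[0] == t1["denominators"]["female"], "table1 female total")
    _check(sums[1] == t1["denominators"]["male"], "table1 male total")
    for tname in ("table2", "table4", "table5"):
        for sec in fx[tname]["sections"]:
            dens = list(sec["denominators"].values())
            sums = np.array([[r[1], r[2]] for r in sec["rows"]]).sum(axis=0)
            _check(list(sums) == dens, f"{tname}/{sec['name']} totals")
    for tname in ("table3", "table6"):
        t = fx[tname]
        dens = list(t["denominators"].values())
        for row in t["rows"]:
            _check(row[1] <= dens[0] and row[2] <= dens[1],
                   f"{tname}/{row[0]} exceeds denominator")
        sub = t["hemiparesis_subtype"]
        subsums = np.array([[r[1], r[2]] for r in sub["rows"]]).sum(axis=0)
        hemi = next(r for r in t["rows"] if r[0] == "hemiparesis")
        _check(list(subsums) == [hemi[1], hemi[2]],
               f"{tname} subtype totals vs hemiparesis row")


def section_table(section: dict) -> ContingencyTable:
    """A section's rows as a ContingencyTable (rows = categories,
    columns = the two groups)."""
    rows = section["rows"]
    return ContingencyTable(
        row_labels=[r[0] for r in rows],
        col_labels=list(section.get("denominators", {"a": 0, "b": 0})),
        counts=np.array([[r[1], r[2]] for r in rows]),
    )


def symptom_row_table(table: dict, symptom: str) -> ContingencyTable:
    """One symptom row against its complement: the 2x2 behind that
    row's P value (groups as rows, reported yes/no as columns)."""
    dens = list(table["denominators"].values())
    row = next(r for r in table["rows"] if r[0] == symptom)
    return ContingencyTable(
        row_labels=list(table["denominators"]),
        col_labels=["yes", "no"],
        counts=np.array([[row[1], dens[0] - row[1]],
                         [row[2], dens[1] - row[2]]]),
    )


def _recompute_p(table: ContingencyTable) -> tuple[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallExpectedCountWarning)
        res = pearson_chi2(table)
    return res.p_printed_3dp, res.p


def _pct(n: int, d: int) -> str:
    return f"{n} ({round_half_up(100.0 * n / d, 1)})"


def reproduce_tables(fixture: Optional[dict] = None,
                     which: Optional[list[str]] = None) -> dict[str, pd.DataFrame]:
    """Recompute every table: percentage cells to one decimal and the P
    column from the stored counts (transposed to groups-as-rows 2x2, or
    the printed r x 2 for multi-category sections), alongside the
    P value as printed."""
    fx = fixture or load_fixture_tables()
    report: dict[str, pd.DataFrame] = {}
    names = which or ["table1", "table2", "table3", "table4", "table5",
                      "table6", "in_text"]

    if "table1" in names:
        t1 = fx["table1"]
        dens = t1["denominators"]
        report["table1"] = pd.DataFrame(
            [{"age_band": r[0],
              "women": _pct(r[1], dens["female"]),
              "men": _pct(r[2], dens["male"])}
             for r in t1["rows"]]
        )

    for tname in ("table2", "table4", "table5"):
        if tname not in names:
            continue
        rows = []
        for sec in fx[tname]["sections"]:
            dens = list(sec["denominators"].values())
            groups = list(sec["denominators"])
            if sec["printed_p"] is None:
                p3, _ = "n/a", None
            else:
                p3, _ = _recompute_p(section_table(sec))
            for i, r in enumerate(sec["rows"]):
                rows.append({
                    "section": sec["name"], "category": r[0],
                    groups[0]: _pct(r[1], dens[0]),
                    groups[1]: _pct(r[2], dens[1]),
                    "P": p3 if i == 0 else "",
                    "P_printed": (sec["printed_p"] or "n/a") if i == 0 else "",
                })
        report[tname] = pd.DataFrame(rows)

    for tname in ("table3", "table6"):
        if tname not in names:
            continue
        t = fx[tname]
        dens = list(t["denominators"].values())
        groups = list(t["denominators"])
        rows = []
        for r in t["rows"]:
            p3, _ = _recompute_p(symptom_row_table(t, r[0]))
            rows.append({
                "symptom": r[0],
                groups[0]: _pct(r[1], dens[0]),
                groups[1]: _pct(r[2], dens[1]),
                "P": p3, "P_printed": r[3],
            })
        sub = t["hemiparesis_subtype"]
        sdens = list(sub["denominators"].values())
        p3, _ = _recompute_p(section_table(sub))
        for i, r in enumerate(sub["rows"]):
            rows.append({
                "symptom": f"  hemiparesis/{r[0]}",
                groups[0]: _pct(r[1], sdens[0]),
                groups[1]: _pct(r[2], sdens[1]),
                "P": p3 if i == 0 else "",
                "P_printed": sub["printed_p"] if i == 0 else "",
            })
        report[tname] = pd.DataFrame(rows)

    if "in_text" in names:
        rows = []
        it = fx["in_text"]
        for key in ("msc_by_narrator", "nontrad_excl_msc_by_narrator",
                    "any_nontrad_by_stroke_type", "delay_by_sex"):
            sec = it[key]
            table = ContingencyTable(
                row_labels=[r[0] for r in sec["rows"]],
                col_labels=["yes", "no"],
                counts=np.array([[r[1], r[2]] for r in sec["rows"]]),
            )
            p3, _ = _recompute_p(table)
            for r in sec["rows"]:
                rows.append({
                    "analysis": key, "group": r[0],
                    "yes": _pct(r[1], r[1] + r[2]),
                    "no": _pct(r[2], r[1] + r[2]),
                    "P": p3 if r is sec["rows"][0] else "",
                    "P_printed": sec["printed_p"] if r is sec["rows"][0] else "",
                })
        report["in_text"] = pd.DataFrame(rows)
    return report


def report_to_markdown(report: dict[str, pd.DataFrame],
                       fixture: Optional[dict] = None) -> str:
    fx = fixture or load_fixture_tables()
    chunks = []
    for name, df in report.items():
        title = fx.get(name, {}).get("title", name) if name != "in_text" \
            else "In-text contingency analyses"
        chunks.append(f"## {name}: {title}\n")
        chunks.append(df.to_markdown(index=False))
        chunks.append("")
    return "\n".join(chunks)


# ---------------------------------------------------------------------------
# Record expansion: materialize coded records whose per-variable margins
# equal one table's printed counts.  Flags are assigned to deterministic
# record prefixes, so every variable's margin is exact while the joint
# distribution is arbitrary (the marginals carry no joint information).

def _first_k(records: list[CodedStory], keys: list[str], k: int, setter) -> None:
    for rec in records[:k]:
        setter(rec, True)
    for rec in records[k:]:
        setter(rec, False)


def expand_table(fixture: dict, name: str) -> list[CodedStory]:
    """Materialize CodedStory records consistent with one table."""
    fx = fixture
    if name == "table1":
        recs = []
        for r in fx["table1"]["rows"]:
            for sex, count in (("female", r[1]), ("male", r[2])):
                recs.extend(
                    CodedStory(story_id=f"t1-{sex}-{r[0]}-{i}",
                               patient_sex=sex, age_band=r[0])
                    for i in range(count)
                )
        return recs

    if name in ("table4", "table5"):
        symptom = ("mental_status_change" if name == "table4" else "headache")
        recs = []
        for sec in fx[name]["sections"]:
            yes_row, no_row = sec["rows"]
            for sex_i, sex in enumerate(("female", "male")):
                for flag, row in ((True, yes_row), (False, no_row)):
                    for i in range(row[1 + sex_i]):
                        rec = CodedStory(
                            story_id=f"{name}-{sec['name']}-{sex}-{flag}-{i}",
                            narrator=sec["name"], patient_sex=sex,
                        )
                        rec.symptoms[symptom] = flag
                        recs.append(rec)
        return recs

    if name == "table2":
        recs = []
        for sex_i, sex in enumerate(("female", "male")):
            sections = {s["name"]: s for s in fx["table2"]["sections"]}
            nar = sections["narrator"]
            n_first = nar["rows"][0][1 + sex_i]
            n_third = nar["rows"][1][1 + sex_i]
            for i in range(n_first):
                recs.append(CodedStory(story_id=f"t2-{sex}-first-{i}",
                                       narrator="first", patient_sex=sex))
            third = [CodedStory(story_id=f"t2-{sex}-third-{i}",
                                narrator="third", patient_sex=sex)
                     for i in range(n_third)]
            n_wit = sections["witness"]["rows"][0][1 + sex_i]
            for j, rec in enumerate(third):
                rec.witness = j < n_wit
            rels = ([(r[0], r[1 + sex_i])
                     for r in sections["relationship_relative"]["rows"]]
                    + [(r[0], r[1 + sex_i])
                       for r in sections["relationship_nonrelative"]["rows"]])
            j = 0
            for rel, count in rels:
                for _ in range(count):
                    third[j].relation = rel
                    j += 1
            recs.extend(third)
        return recs

    if name in ("table3", "table6"):
        t = fx[name]
        group_var = "patient_sex" if name == "table3" else "stroke_type"
        groups = list(t["denominators"])
        recs_by_group = {}
        for gi, g in enumerate(groups):
            n = t["denominators"][g]
            recs = [CodedStory(story_id=f"{name}-{g}-{i}") for i in range(n)]
            for rec in recs:
                setattr(rec, group_var, g)
            for row in t["rows"]:
                k = row[1 + gi]
                for j, rec in enumerate(recs):
                    rec.symptoms[row[0]] = j < k
            sub = t["hemiparesis_subtype"]
            j = 0
            for srow in sub["rows"]:
                for _ in range(srow[1 + gi]):
                    recs[j].hemiparesis_subtype = srow[0]
                    j += 1
            recs_by_group[g] = recs
        return [r for g in groups for r in recs_by_group[g]]

    raise KeyError(f"no expansion for {name!r}")
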