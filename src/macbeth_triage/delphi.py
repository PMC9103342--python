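"""Bookkeeping for the modified Delphi rounds and DPSIR structuring.

The expert panel's free-text reports are coded by humans into keyword
codes before they reach this module (the anonymization posture: narratives
never enter the artifact).  What remains is exact bookkeeping: frequency
tallies of the round-1 codes (typical-case statistics), grouping of the
stage-2 answers into the five DPSIR buckets via the fixed question →
category map, and unanimity-style consensus flags for round-2 feedback.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

DPSIR_CATEGORIES = ("Drivers", "Pressures", "State", "Impact", "Response")

#: The seven stage-2 questions map onto DPSIR: socioeconomic causes (Q1),
#: oppression/threats (Q2), physical / emotional / psychological changes
#: (Q3–Q5), impacts on the individual and family (Q6), and the protection
#: network's possible responses (Q7).
STAGE2_QUESTION_MAP: dict[str, str] = {
    "Q1": "Drivers",
    "Q2": "Pressures",
    "Q3": "State",
    "Q4": "State",
    "Q5": "State",
    "Q6": "Impact",
    "Q7": "Response",
}


@dataclass
class CodedResponse:
    respondent: str
    round: int
    question: str
    codes: list[str] = field(default_factory=list)
    dpsir_tag: str | None = None
    vote: str | None = None  # agree / disagree / amend (round-2 feedback)


@dataclass
class TallyTable:
    dimension: str
    rows: list[tuple[str, int]]  # descending count, then code

    @property
    def total(self) -> int:
        return sum(c for _, c in self.rows)

    def count(self, code: str) -> int:
        for c, n in self.rows:
            if c == code:
                return n
        return 0


def tally(responses: list[CodedResponse], dimension: str) -> TallyTable:
    """Exact frequency counts of the codes in one namespace (question id)."""
    counter: Counter[str] = Counter()
    for r in responses:
        if r.question == dimension:
            counter.update(r.codes)
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return TallyTable(dimension=dimension, rows=rows)


def dpsir_bucket(
    responses: list[CodedResponse],
    question_map: dict[str, str] | None = None,
) -> dict[str, Counter]:
    """Group stage-2 codes into DPSIR buckets by their question id.

    A code mentioned under two questions lands in both buckets; within a
    bucket duplicates merge with counts, and no code is ever dropped (the
    multiset of inputs equals the multiset across buckets).
    """
    qmap = question_map or STAGE2_QUESTION_MAP
    buckets: dict[str, Counter] = {cat: Counter() for cat in DPSIR_CATEGORIES}
    for r in responses:
        try:
            cat = qmap[r.question]
        except KeyError:
            raise ValueError(f"unknown stage-2 question id {r.question!r}") from None
        buckets[cat].update(r.codes)
    return buckets


@dataclass
class ConsensusSummary:
    by_item: dict[str, bool]
    n_consensus: int
    n_items: int
    dissent: dict[str, list[str]]  # item -> respondents not agreeing


def consensus(
    round2: list[CodedResponse],
    panel: set[str],
    threshold: float = 1.0,
) -> ConsensusSummary:
    """Per-item consensus flags for the round-2 agree/disagree/amend votes.

    The default rule is unanimity across the panel (every panel member
    voted "agree"); ``threshold`` relaxes it to a fraction of agreeing
    members.  A vote from outside the panel is an error.
    """
    votes: dict[str, dict[str, str]] = {}
    for r in round2:
        if r.respondent not in panel:
            raise ValueError(f"respondent {r.respondent!r} is not on the panel")
        if r.vote is None:
            raise ValueError(f"response to {r.question!r} by {r.respondent!r} has no vote")
        votes.setdefault(r.question, {})[r.respondent] = r.vote
    by_item: dict[str, bool] = {}
    dissent: dict[str, list[str]] = {}
    for item, item_votes in votes.items():
        agreeing = {p for p, v in item_votes.items() if v == "agree"}
        not_agreeing = sorted(panel - agreeing)
        by_item[item] = len(agreeing) / len(panel) >= threshold
        if not_agreeing:
            dissent[item] = not_agreeing
    return ConsensusSummary(
        by_item=by_item,
        n_consensus=sum(by_item.values()),
        n_items=len(by_item),
        dissent=dissent,
    )


def read_responses(path: str | Path) -> list[CodedResponse]:
    """Read coded responses from CSV (respondent, round, question, code,
    dpsir_tag, vote); one row per code mention."""
    out: list[CodedResponse] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CodedResponse(
                    respondent=row["respondent"],
                    round=int(row["round"]),
                    question=row["question"],
                    codes=[row["code"]] if row.get("code") else [],
                    dpsir_tag=row.get("dpsir_tag") or None,
                    vote=row.get("vote") or None,
                )
            )
    return out
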