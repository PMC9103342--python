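"""Domain types for the value tree, severity descriptors, and case profiles.

The decision model is organised as a value tree in the Value-Focused
Thinking sense: a strategic objective (guaranteeing the health, safety and
protection of a child or adolescent victim of sexual violence) branches
into areas of concern (family aspects, threats, physical / emotional /
psychological changes) whose leaves are evaluable criteria.  Each criterion
carries a *descriptor*: an ordered list of performance levels from least to
most severe, two of which are designated the **good** and **neutral**
reference levels.  Neutral is a threshold: a case below it on some
criterion is an emergency on that criterion, between neutral and good it is
urgent, at or above good it is on track.

Case profiles assign one descriptor level per criterion.  Turning a
narrative report into level assignments is a human (clinical) step; this
module only resolves structured label/id assignments against descriptors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


class CodingError(ValueError):
    """Raised when a raw case assignment cannot be resolved against the tree."""


@dataclass(frozen=True)
class PerformanceLevel:
    """One rung of a descriptor. ``rank`` 0 is the least severe level."""

    id: str
    label: str
    rank: int
    definition: str = ""
    supplementary: bool = False


@dataclass
class Descriptor:
    """Ordered performance levels with designated good and neutral anchors."""

    levels: list[PerformanceLevel]
    good_level: str
    neutral_level: str

    def level(self, level_id: str) -> PerformanceLevel:
        for lv in self.levels:
            if lv.id == level_id:
                return lv
        raise KeyError(level_id)

    def level_ids(self) -> list[str]:
        return [lv.id for lv in self.levels]

    def rank(self, level_id: str) -> int:
        return self.level(level_id).rank

    def resolve(self, token: str) -> str:
        """Resolve a level id or label, case-insensitively; exact match only.

        Raises :class:`CodingError` if the token matches no level or more
        than one (a label colliding with another level's id).
        """
        needle = token.strip().casefold()
        hits = {
            lv.id
            for lv in self.levels
            if lv.id.casefold() == needle or lv.label.casefold() == needle
        }
        if not hits:
            raise CodingError(f"no performance level matches {token!r}")
        if len(hits) > 1:
            raise CodingError(f"ambiguous performance level {token!r}: {sorted(hits)}")
        return hits.pop()

    def validate(self, where: str = "descriptor") -> list[str]:
        v: list[str] = []
        if len(self.levels) < 2:
            v.append(f"{where}: fewer than 2 levels")
            return v
        ranks = [lv.rank for lv in self.levels]
        if sorted(ranks) != list(range(len(self.levels))):
            v.append(f"{where}: ranks are not consecutive integers from 0 (got {ranks})")
        labels = [lv.label.casefold() for lv in self.levels]
        if len(set(labels)) != len(labels):
            v.append(f"{where}: duplicate level labels")
        ids = self.level_ids()
        if len(set(ids)) != len(ids):
            v.append(f"{where}: duplicate level ids")
        known = set(ids)
        for role, lid in (("good", self.good_level), ("neutral", self.neutral_level)):
            if lid not in known:
                v.append(f"{where}: {role} anchor {lid!r} is not a level")
        if self.good_level in known and self.neutral_level in known:
            if self.good_level == self.neutral_level:
                v.append(f"{where}: anchors coincide ({self.good_level!r})")
            elif self.rank(self.good_level) >= self.rank(self.neutral_level):
                v.append(
                    f"{where}: good anchor {self.good_level!r} must be strictly "
                    f"more attractive (lower rank) than neutral {self.neutral_level!r}"
                )
        return v


@dataclass
class Criterion:
    id: str
    name: str
    area_of_concern: str
    descriptor: Descriptor


@dataclass
class ValueTree:
    """Objective → areas of concern → criteria (leaves)."""

    objective: str
    areas_of_concern: list[str]
    criteria: list[Criterion]

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def criterion_ids(self) -> list[str]:
        return [c.id for c in self.criteria]


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)


@dataclass
class CaseProfile:
    """Resolved level assignment per criterion for one case.

    Criteria a given sector model does not evaluate may simply be absent.
    """

    case_id: str
    assignments: dict[str, str] = field(default_factory=dict)
    provenance: str = ""


def validate_tree(tree: ValueTree) -> ValidationReport:
    """Check every structural invariant; violations are returned, not raised."""
    v: list[str] = []
    if not tree.criteria:
        v.append("tree: no leaves (zero criteria)")
    seen: set[str] = set()
    areas = set(tree.areas_of_concern)
    for c in tree.criteria:
        if c.id in seen:
            v.append(f"criterion {c.id!r}: duplicate id")
        seen.add(c.id)
        if c.area_of_concern not in areas:
            v.append(
                f"criterion {c.id!r}: area of concern {c.area_of_concern!r} "
                "is not a branch of the tree"
            )
        v.extend(c.descriptor.validate(where=f"criterion {c.id!r}"))
    return ValidationReport(ok=not v, violations=v)


def code_case(
    raw_assignments: dict[str, str],
    tree: ValueTree,
    case_id: str = "case",
    provenance: str = "",
) -> CaseProfile:
    """Resolve label-or-id assignments to a :class:`CaseProfile`.

    Matching is a case-insensitive exact match on level id or label, so the
    operation is idempotent on already-resolved ids.  Unknown criteria or
    unresolvable labels raise :class:`CodingError` naming every offender.
    """
    if not raw_assignments:
        warnings.warn("no criteria coded: empty assignment map", stacklevel=2)
        return CaseProfile(case_id=case_id, assignments={}, provenance=provenance)
    resolved: dict[str, str] = {}
    problems: list[str] = []
    for crit_id, token in raw_assignments.items():
        try:
            crit = tree.criterion(crit_id)
        except KeyError:
            problems.append(f"unknown criterion {crit_id!r}")
            continue
        try:
            resolved[crit_id] = crit.descriptor.resolve(token)
        except CodingError as exc:
            problems.append(f"criterion {crit_id!r}: {exc}")
    if problems:
        raise CodingError("; ".join(problems))
    return CaseProfile(case_id=case_id, assignments=resolved, provenance=provenance)
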