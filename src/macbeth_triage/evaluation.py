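"""Additive evaluation of a coded case and per-criterion triage.

A sector model is one decision unit's view: a subset of the tree's
criteria, an anchored value scale per criterion (good = 100, neutral = 0)
and a normalized swing-weight vector.  Evaluation is the additive value
model: each criterion scores its assigned level on the anchored scale, and
the global score is the weighted sum.

Triage is *per criterion*, not global: a negative score means the case sits
below the neutral threshold on that criterion and needs urgent (immediate)
care; a zero score sits exactly at neutral and becomes a referral that can
wait; a positive score is at-or-above territory to be followed up
periodically.  The global score is reported for monitoring a case over
time but deliberately plays no part in classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .macbeth import ZERO_EPSILON, AnchoredValueScale  # noqa: F401  (re-export)
from .value_model import CaseProfile
from .weighting import SwingRanking, WeightVector


@dataclass
class SectorModel:
    """One decision unit's criteria subset, scales, weights and swing ranking."""

    sector_id: str
    criteria: list[str]
    scales: dict[str, AnchoredValueScale]
    weights: WeightVector
    ranking: SwingRanking
    notes: str = ""

    def validate(self) -> list[str]:
        v: list[str] = []
        crit = set(self.criteria)
        if set(self.scales) != crit:
            v.append(f"sector {self.sector_id!r}: scales cover {sorted(self.scales)}, criteria are {sorted(crit)}")
        if set(self.weights.weights) != crit:
            v.append(f"sector {self.sector_id!r}: weights do not cover the criteria subset")
        if set(self.ranking.criteria()) != crit:
            v.append(f"sector {self.sector_id!r}: swing ranking does not cover the criteria subset")
        return v


@dataclass
class EvaluationResult:
    sector_id: str
    case_id: str
    per_criterion: dict[str, float]
    global_score: float
    skipped: list[str] = field(default_factory=list)
    not_assessed: list[str] = field(default_factory=list)


@dataclass
class TriageResult:
    """Disjoint partition of the evaluated criteria into the three classes."""

    urgent: list[str]
    referral: list[str]
    follow_up: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    not_assessed: list[str] = field(default_factory=list)

    def class_of(self, criterion: str) -> str:
        for name in ("urgent", "referral", "follow_up"):
            if criterion in getattr(self, name):
                return name
        raise KeyError(criterion)


def evaluate(model: SectorModel, profile: CaseProfile) -> EvaluationResult:
    """Score a coded case against a sector model.

    Criteria of the model missing from the profile are skipped with a
    warning; profile criteria outside the model's subset are reported as
    "not assessed" (e.g. a sector that declined to evaluate STIs), never
    silently folded into the referral class.
    """
    per: dict[str, float] = {}
    skipped: list[str] = []
    for crit_id in model.criteria:
        if crit_id not in profile.assignments:
            skipped.append(crit_id)
            continue
        per[crit_id] = model.scales[crit_id].score(profile.assignments[crit_id])
    if skipped:
        warnings.warn(
            f"sector {model.sector_id!r}: no level assigned for {skipped}; skipped",
            stacklevel=2,
        )
    not_assessed = sorted(set(profile.assignments) - set(model.criteria))
    global_score = sum(model.weights.weights[c] * s for c, s in per.items())
    return EvaluationResult(
        sector_id=model.sector_id,
        case_id=profile.case_id,
        per_criterion=per,
        global_score=global_score,
        skipped=skipped,
        not_assessed=not_assessed,
    )


def classify(result: EvaluationResult, epsilon: float = ZERO_EPSILON) -> TriageResult:
    """Partition the evaluated criteria by the sign of their score.

    score < −ε → urgent, |score| ≤ ε → referral, score > ε → follow-up.
    Within each class criteria are ordered most negative first, mirroring
    the severity-ordered case reports.
    """
    urgent, referral, follow_up = [], [], []
    for crit_id in sorted(result.per_criterion, key=lambda c: result.per_criterion[c]):
        s = result.per_criterion[crit_id]
        if s < -epsilon:
            urgent.append(crit_id)
        elif s > epsilon:
            follow_up.append(crit_id)
        else:
            referral.append(crit_id)
    return TriageResult(
        urgent=urgent,
        referral=referral,
        follow_up=follow_up,
        scores=dict(result.per_criterion),
        not_assessed=list(result.not_assessed),
    )


#: Default service options per triage class, applied when the routing table
#: has no entry for a (criterion, class) pair.
DEFAULT_ROUTING: dict[str, list[str]] = {
    "urgent": ["healthcare (immediate)", "social protection", "mental health"],
    "referral": ["scheduled referral within the protection network"],
    "follow_up": ["periodic follow-up and monitoring"],
}


@dataclass
class RoutedPlan:
    options: dict[str, tuple[str, list[str]]]  # criterion -> (class, services)


def route(
    triage: TriageResult,
    routing: dict | None = None,
    defaults: dict[str, list[str]] | None = None,
) -> RoutedPlan:
    """Attach configured service options to each triaged criterion.

    ``routing`` maps triage class → {criterion id → [services]}; any pair
    without an entry falls back to the class-level default.  Routing never
    errors: an empty table simply yields the defaults throughout.
    """
    routing = routing or {}
    defaults = defaults or DEFAULT_ROUTING
    options: dict[str, tuple[str, list[str]]] = {}
    for cls in ("urgent", "referral", "follow_up"):
        overrides = routing.get(cls, {}) or {}
        for crit_id in getattr(triage, cls):
            services = overrides.get(crit_id, defaults.get(cls, []))
            options[crit_id] = (cls, list(services))
    return RoutedPlan(options=options)
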