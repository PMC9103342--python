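"""Swing weighting: criterion importance from MACBETH judgments over swings.

The elicitation question is the classic swing one: with a child at the
neutral level on every criterion, which single criterion would you raise to
its good level first?  Repeating the question orders the criteria by swing
attractiveness (ties allowed — criteria the unit treats "without
distinction").  The swings are then judged like any MACBETH stimuli against
a reference stimulus representing "all criteria stay neutral", which
anchors the weight scale at zero; the resulting raw scores, normalized to
sum 1, are the criterion weights of the additive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .macbeth import JudgmentMatrix, solve_basic_scale

_SUM_TOL = 1e-9


@dataclass
class SwingRanking:
    """Ordered tie-groups of criterion ids, most attractive swing first."""

    groups: list[list[str]]

    def criteria(self) -> list[str]:
        return [c for g in self.groups for c in g]

    def position(self, criterion: str) -> int:
        """Printed (flattened) 1-based position; tied criteria occupy
        consecutive positions in group order, as severity tables print them."""
        return self.criteria().index(criterion) + 1

    def group_position(self, criterion: str) -> int:
        """Tie-aware 1-based position: members of a tie-group share it."""
        for gi, g in enumerate(self.groups):
            if criterion in g:
                return gi + 1
        raise KeyError(criterion)

    def validate(self, criteria: set[str] | None = None) -> list[str]:
        v: list[str] = []
        flat = self.criteria()
        if len(set(flat)) != len(flat):
            v.append("ranking: duplicated criterion")
        if criteria is not None:
            missing = criteria - set(flat)
            extra = set(flat) - criteria
            if missing:
                v.append(f"ranking: missing criteria {sorted(missing)}")
            if extra:
                v.append(f"ranking: unknown criteria {sorted(extra)}")
        return v


@dataclass
class WeightVector:
    """Normalized non-negative weights over a sector's criteria subset."""

    weights: dict[str, float]
    ranking: SwingRanking | None = None

    def validate(self) -> list[str]:
        v: list[str] = []
        if any(w < 0 for w in self.weights.values()):
            v.append("weights: negative weight")
        total = sum(self.weights.values())
        if abs(total - 1.0) > _SUM_TOL:
            v.append(f"weights: sum {total!r} != 1")
        if self.ranking is not None:
            for g in self.ranking.groups:
                vals = {round(self.weights[c], 12) for c in g if c in self.weights}
                if len(vals) > 1:
                    v.append(f"weights: tie-group {g} carries unequal weights {sorted(vals)}")
        return v


def ranking_from_choices(
    choice_sequence: list[str | list[str]], criteria: set[str]
) -> SwingRanking:
    """Build a ranking from the recorded choice order.

    Each element of the sequence is either one criterion id or a list of
    ids chosen simultaneously (a tie-group).  The flattened sequence must
    be a permutation of ``criteria``.
    """
    groups: list[list[str]] = []
    for choice in choice_sequence:
        groups.append([choice] if isinstance(choice, str) else list(choice))
    ranking = SwingRanking(groups=groups)
    flat = ranking.criteria()
    if len(set(flat)) != len(flat):
        dupes = sorted({c for c in flat if flat.count(c) > 1})
        raise ValueError(f"criteria chosen more than once: {dupes}")
    missing = criteria - set(flat)
    extra = set(flat) - criteria
    if missing or extra:
        raise ValueError(
            f"choice sequence is not a permutation of the criteria "
            f"(missing {sorted(missing)}, unknown {sorted(extra)})"
        )
    return ranking


def compute_weights(
    ranking: SwingRanking,
    swing_judgments: JudgmentMatrix,
    reference: str = "all_neutral",
) -> WeightVector:
    """Normalized weights from MACBETH judgments over the criterion swings.

    The matrix's stimuli must be the ranking's criteria in flattened order
    followed by the all-neutral reference (ranked last, scored 0 by the
    basic scale's worst-anchor convention); tied swings must be joined by
    null judgments so their raw scores — and hence weights — coincide
    exactly.  weight_i = raw_i / Σ raw_j.
    """
    expected = ranking.criteria() + [reference]
    if swing_judgments.stimuli != expected:
        raise ValueError(
            f"swing matrix stimuli {swing_judgments.stimuli} must be the ranked "
            f"criteria followed by the reference ({expected})"
        )
    raw = solve_basic_scale(swing_judgments)
    total = sum(raw.scores[c] for c in ranking.criteria())
    if total <= 0:
        raise ValueError("all swing scores are zero; weights undefined")
    weights = {c: raw.scores[c] / total for c in ranking.criteria()}
    # exact tie-group equality: share the group value (guards float residue)
    for g in ranking.groups:
        if len(g) > 1:
            shared = sum(weights[c] for c in g) / len(g)
            for c in g:
                weights[c] = shared
    return WeightVector(weights=weights, ranking=ranking)
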