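"""Decision-conference aggregation across protection-network sectors.

Sector models are combined descriptively, not re-derived: the group
ranking places each criterion at its modal position across the sector
rankings (positions counted only where a sector evaluates the criterion),
cross-sector scale statistics summarise how far the sectors' value scales
diverge level by level, and a compatibility check flags any group-ranking
pair that reverses an order all sectors agreed on.  The group's own scales
and weights come out of a human decision conference and therefore enter
this package as inputs, never as computed aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .macbeth import AnchoredValueScale
from .weighting import SwingRanking


@dataclass
class GroupRanking:
    order: list[str]  # positions 1..n
    provenance: list[SwingRanking] = field(default_factory=list)

    def position(self, criterion: str) -> int:
        return self.order.index(criterion) + 1


@dataclass
class ScaleStats:
    """Per-level cross-sector mean and sample standard deviation."""

    criterion: str | None
    mean: dict[str, float]
    stdev: dict[str, float | None]  # None when a single sector supplies the level
    n_sectors: dict[str, int]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def aggregate_rankings(sector_rankings: list[SwingRanking]) -> GroupRanking:
    """Modal-position aggregation of sector rankings.

    Each criterion's positions across the sectors that rank it are tallied
    (printed, flattened positions; tied criteria occupy consecutive
    columns as the sector tables print them).  The criterion is assigned
    its most frequent position — the smallest such position if several are
    equally frequent — and criteria are ordered by modal position, ties
    broken by lower mean position, then by first appearance in the input.
    """
    if not sector_rankings:
        raise ValueError("need at least one sector ranking")
    positions: dict[str, list[int]] = {}
    first_seen: dict[str, int] = {}
    counter = 0
    for ranking in sector_rankings:
        for crit in ranking.criteria():
            positions.setdefault(crit, []).append(ranking.position(crit))
            if crit not in first_seen:
                first_seen[crit] = counter
                counter += 1

    def modal(pos: list[int]) -> int:
        counts: dict[int, int] = {}
        for p in pos:
            counts[p] = counts.get(p, 0) + 1
        best = max(counts.values())
        return min(p for p, c in counts.items() if c == best)

    order = sorted(
        positions,
        key=lambda c: (modal(positions[c]), float(np.mean(positions[c])), first_seen[c]),
    )
    return GroupRanking(order=order, provenance=list(sector_rankings))


def scale_stats(scales_by_sector: list[AnchoredValueScale]) -> ScaleStats:
    """Arithmetic mean and sample (n−1) stdev per level across sectors.

    Values are reported to 2 decimals, round half up.  A level supplied by
    a single sector has an undefined stdev, reported as missing (None).
    The sample convention is the one the cross-sector summary rows of the
    severity tables follow.
    """
    if not scales_by_sector:
        raise ValueError("no scales supplied")
    criterion = scales_by_sector[0].criterion
    levels: list[str] = []
    for sc in scales_by_sector:
        for lid in sc.scores:
            if lid not in levels:
                levels.append(lid)
    mean: dict[str, float] = {}
    stdev: dict[str, float | None] = {}
    n_sectors: dict[str, int] = {}
    for lid in levels:
        vals = [sc.scores[lid] for sc in scales_by_sector if lid in sc.scores]
        n_sectors[lid] = len(vals)
        mean[lid] = _round2(float(np.mean(vals)))
        stdev[lid] = _round2(float(np.std(vals, ddof=1))) if len(vals) >= 2 else None
    return ScaleStats(criterion=criterion, mean=mean, stdev=stdev, n_sectors=n_sectors)


@dataclass
class CompatibilityReport:
    contradictions: list[tuple[str, str, str]]  # (first, second, explanation)

    @property
    def compatible(self) -> bool:
        return not self.contradictions


def check_group_compatibility(
    sector_rankings: list[SwingRanking],
    group_ranking: SwingRanking,
) -> CompatibilityReport:
    """Flag group-ranking pairs that reverse a unanimous sector order.

    A pair (x, y) is unanimously ordered when every sector ranking both
    places x strictly above y — a sector that ties them breaks unanimity.
    The report is empty when the conference result is compatible with the
    individual judgments.  Tie-aware group positions are used throughout.
    """
    flags: list[tuple[str, str, str]] = []
    group_crit = group_ranking.criteria()
    for xi, x in enumerate(group_crit):
        for y in group_crit[xi + 1 :]:
            votes = []
            for ranking in sector_rankings:
                crit = set(ranking.criteria())
                if x in crit and y in crit:
                    px, py = ranking.group_position(x), ranking.group_position(y)
                    votes.append(-1 if px < py else (1 if px > py else 0))
            if len(votes) < 2:  # "unanimous across sectors" needs ≥ 2 voters
                continue
            gx, gy = group_ranking.group_position(x), group_ranking.group_position(y)
            if all(v == -1 for v in votes) and gx > gy:
                flags.append((x, y, f"all {len(votes)} sectors rank {x!r} above {y!r}; group reverses"))
            elif all(v == 1 for v in votes) and gx < gy:
                flags.append((y, x, f"all {len(votes)} sectors rank {y!r} above {x!r}; group reverses"))
    return CompatibilityReport(contradictions=flags)
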