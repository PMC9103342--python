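"""MACBETH: cardinal value scales from qualitative difference judgments.

MACBETH (Measuring Attractiveness by a Categorical Based Evaluation
Technique) asks an expert only *qualitative* questions: for a pair of
stimuli (performance levels, or criterion swings) ranked by attractiveness,
how large is the difference — null, very weak, weak, moderate, strong,
very strong or extreme?  A linear program then converts the judgment set
into a cardinal scale, or proves that no scale is compatible with the
judgments (inconsistency).

The LP convention used here is the standard basic-MACBETH one.  With the
stimuli indexed best (0) to worst (n−1) and v_i their values:

* v_{n-1} = 0;
* a pair (i, j) judged in category k ≥ 1 forces v_i − v_j ≥ k (category
  thresholds s_k = k);
* a null (k = 0) judgment forces v_i = v_j;
* for two judged pairs p, q with cat(p) > cat(q), the differences must be
  separated: diff(p) ≥ diff(q) + (cat(p) − cat(q));
* consecutive pairs left unjudged still respect the ranking: v_i ≥ v_{i+1}.

Categories act as closed lower bounds; inter-pair consistency comes from
the separation constraints, not from upper-bound thresholds.  The basic
scale is the LP optimum minimizing v_0 with ties between optimal vertices
broken by lexicographically minimizing (v_0, v_1, …) through sequential
re-solves, so output is reproducible across solver versions.  Any two
positive threshold choices give affinely related scales, and the final
good = 100 / neutral = 0 anchoring removes that freedom entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .value_model import Descriptor

CATEGORY_LABELS = ("null", "VW", "W", "M", "ST", "VST", "E")
CATEGORY_NAMES = {
    "null": "null",
    "VW": "very weak",
    "W": "weak",
    "M": "moderate",
    "ST": "strong",
    "VST": "very strong",
    "E": "extreme",
}
MAX_CATEGORY = 6

#: Feasibility tolerance for the float LP and for anchored-score equality.
ZERO_EPSILON = 1e-9
_LP_TOL = 1e-7


class InconsistentJudgmentsError(ValueError):
    """Raised when a scale is requested for an infeasible judgment matrix."""


def category_ordinal(label: str | int) -> int:
    """Map a category label (or ordinal) to its ordinal 0..6."""
    if isinstance(label, int):
        if not 0 <= label <= MAX_CATEGORY:
            raise ValueError(f"category ordinal {label} outside 0..{MAX_CATEGORY}")
        return label
    try:
        return CATEGORY_LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown judgment category {label!r}") from None


def category_label(k: int) -> str:
    return CATEGORY_LABELS[category_ordinal(k)]


@dataclass
class JudgmentMatrix:
    """Qualitative judgments over a preference-ranked stimulus list.

    ``stimuli`` is ordered most attractive first.  Each judgment is a
    triple (i, j, k): stimulus index i is preferred to index j (i < j) and
    their attractiveness difference falls in category k.
    """

    stimuli: list[str]
    judgments: list[tuple[int, int, int]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ValueError("duplicate stimulus ids")
        norm: list[tuple[int, int, int]] = []
        seen: set[tuple[int, int]] = set()
        for i, j, k in self.judgments:
            if not (0 <= i < j < len(self.stimuli)):
                raise ValueError(f"judgment pair ({i}, {j}) must satisfy 0 <= i < j < n")
            if (i, j) in seen:
                raise ValueError(f"pair ({i}, {j}) judged more than once")
            seen.add((i, j))
            norm.append((i, j, category_ordinal(k)))
        self.judgments = norm

    @property
    def n(self) -> int:
        return len(self.stimuli)

    def judged(self) -> dict[tuple[int, int], int]:
        return {(i, j): k for i, j, k in self.judgments}


@dataclass
class RawScale:
    """Basic MACBETH scale: worst stimulus at 0, scores weakly decreasing."""

    scores: dict[str, float]

    def as_array(self, stimuli: list[str]) -> np.ndarray:
        return np.array([self.scores[s] for s in stimuli], dtype=float)


@dataclass
class ConsistencyReport:
    feasible: bool
    certificate: list[str] = field(default_factory=list)


@dataclass
class CategoryInterval:
    """Category interval implied for an unjudged pair by transitivity."""

    lo: int
    hi: int

    @property
    def empty(self) -> bool:
        return self.lo > self.hi


class UndeterminedPairError(LookupError):
    """No chain of judged pairs connects the requested pair."""


def elicitation_plan(n_stimuli: int) -> list[tuple[int, int]]:
    """Pairs the protocol asks about: worst-vs-all, then consecutive pairs.

    This is the "last column and main diagonal" questioning pattern; the
    two families overlap in (n−2, n−1), so the plan holds 2n−3 pairs.
    """
    if n_stimuli < 2:
        raise ValueError("need at least 2 stimuli")
    plan = [(i, n_stimuli - 1) for i in range(n_stimuli - 1)]
    plan += [(i, i + 1) for i in range(n_stimuli - 1) if (i, i + 1) not in plan]
    return plan


def implied_category_interval(
    matrix: JudgmentMatrix, pair: tuple[int, int]
) -> CategoryInterval:
    """Interval of categories transitivity implies for an unjudged pair.

    Every chain of judged pairs i → … → j with categories c_1..c_m bounds
    the pair to [max(c), min(6, Σc)]; chains through different routes are
    intersected.  An empty intersection is returned as evidence of
    inconsistency, not raised.
    """
    i0, j0 = pair
    judged = matrix.judged()
    if (i0, j0) in judged:
        raise ValueError(f"pair {pair} is directly judged")
    if not (0 <= i0 < j0 < matrix.n):
        raise ValueError(f"pair {pair} must satisfy 0 <= i < j < n")
    # judged pairs always go best → worse, so the graph is a DAG on indices
    out_edges: dict[int, list[tuple[int, int]]] = {}
    for (a, b), k in judged.items():
        out_edges.setdefault(a, []).append((b, k))

    intervals: list[tuple[int, int]] = []

    def walk(node: int, cats: list[int]) -> None:
        if node == j0:
            if len(cats) >= 2:  # a single edge would be a direct judgment
                intervals.append((max(cats), min(MAX_CATEGORY, sum(cats))))
            return
        for nxt, k in out_edges.get(node, []):
            if nxt <= j0:
                walk(nxt, cats + [k])

    walk(i0, [])
    if not intervals:
        raise UndeterminedPairError(f"no chain of judgments connects {pair}")
    lo = max(iv[0] for iv in intervals)
    hi = min(iv[1] for iv in intervals)
    return CategoryInterval(lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# LP assembly


def _lp_constraints(matrix: JudgmentMatrix):
    """Build (A_ub, b_ub, A_eq, b_eq, tags) for the scale LP.

    Inequalities are expressed as A_ub @ v <= b_ub.  ``tags`` holds one
    human-readable description per row (ub rows first, then eq rows),
    used for infeasibility certificates.
    """
    n = matrix.n
    sid = matrix.stimuli
    judged = matrix.judged()

    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    ub_tags: list[str] = []
    A_eq: list[np.ndarray] = []
    b_eq: list[float] = []
    eq_tags: list[str] = []

    def row(pos: int, neg: int) -> np.ndarray:
        r = np.zeros(n)
        r[pos] += 1.0
        r[neg] -= 1.0
        return r

    # (a) worst stimulus fixed at zero
    r = np.zeros(n)
    r[n - 1] = 1.0
    A_eq.append(r)
    b_eq.append(0.0)
    eq_tags.append(f"v({sid[n-1]}) = 0 (worst anchor)")

    for (i, j), k in sorted(judged.items()):
        if k == 0:
            A_eq.append(row(i, j))
            b_eq.append(0.0)
            eq_tags.append(f"v({sid[i]}) = v({sid[j]}) (null judgment)")
        else:
            A_ub.append(-row(i, j))
            b_ub.append(-float(k))
            ub_tags.append(
                f"v({sid[i]}) - v({sid[j]}) >= {k} ({category_label(k)} judgment)"
            )

    # (d) separation between differently judged pairs
    pairs = sorted(judged.items())
    for (p, kp), (q, kq) in itertools.permutations(pairs, 2):
        if kp > kq:
            r = row(p[0], p[1]) - row(q[0], q[1])
            A_ub.append(-r)
            b_ub.append(-float(kp - kq))
            ub_tags.append(
                f"diff({sid[p[0]]},{sid[p[1]]}) >= diff({sid[q[0]]},{sid[q[1]]})"
                f" + {kp - kq} ({category_label(kp)} vs {category_label(kq)})"
            )

    # (e) ranking order on unjudged consecutive pairs
    for i in range(n - 1):
        if (i, i + 1) not in judged:
            A_ub.append(-row(i, i + 1))
            b_ub.append(0.0)
            ub_tags.append(f"v({sid[i]}) >= v({sid[i+1]}) (ranking order)")

    return A_ub, b_ub, A_eq, b_eq, ub_tags + eq_tags


def _solve(c, A_ub, b_ub, A_eq, b_eq):
    return linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(None, None)] * len(c),
        method="highs",
    )


def _feasible(A_ub, b_ub, A_eq, b_eq, n: int) -> bool:
    res = _solve(np.zeros(n), A_ub, b_ub, A_eq, b_eq)
    return res.status != 2  # 2 = infeasible


def check_consistency(matrix: JudgmentMatrix) -> ConsistencyReport:
    """LP feasibility of the judgment set.

    When infeasible, the certificate is an irreducible infeasible subset of
    the judgment-derived constraints found by deletion filtering: each
    remaining constraint is necessary for the contradiction.
    """
    A_ub, b_ub, A_eq, b_eq, tags = _lp_constraints(matrix)
    n = matrix.n
    if _feasible(A_ub, b_ub, A_eq, b_eq, n):
        return ConsistencyReport(feasible=True)

    # deletion filter over all rows (ub rows first, then eq rows)
    n_ub = len(A_ub)
    keep = list(range(len(tags)))
    for idx in list(keep):
        trial = [t for t in keep if t != idx]
        t_ub = [A_ub[t] for t in trial if t < n_ub]
        t_bub = [b_ub[t] for t in trial if t < n_ub]
        t_eq = [A_eq[t - n_ub] for t in trial if t >= n_ub]
        t_beq = [b_eq[t - n_ub] for t in trial if t >= n_ub]
        if not _feasible(t_ub, t_bub, t_eq, t_beq, n):
            keep = trial  # still infeasible without it: drop for good
    return ConsistencyReport(feasible=False, certificate=[tags[t] for t in keep])


def solve_basic_scale(matrix: JudgmentMatrix) -> RawScale:
    """Minimal scale compatible with the judgments, deterministically chosen.

    Minimizes v(best), then lexicographically each subsequent value at the
    optimum.  Raises :class:`InconsistentJudgmentsError` on infeasibility.
    """
    A_ub, b_ub, A_eq, b_eq, _ = _lp_constraints(matrix)
    n = matrix.n
    A_eq = list(A_eq)
    b_eq = list(b_eq)
    values: list[float] = []
    for var in range(n - 1):  # v_{n-1} already pinned to 0
        c = np.zeros(n)
        c[var] = 1.0
        res = _solve(c, A_ub, b_ub, A_eq, b_eq)
        if res.status == 2:
            raise InconsistentJudgmentsError(
                "judgment matrix admits no compatible scale; run check_consistency"
            )
        if res.status != 0:
            raise RuntimeError(f"LP solver failed with status {res.status}: {res.message}")
        opt = float(res.x[var])
        # snap values that are numerically integral (thresholds are integers)
        if abs(opt - round(opt)) < _LP_TOL:
            opt = float(round(opt))
        values.append(opt)
        pin = np.zeros(n)
        pin[var] = 1.0
        A_eq.append(pin)
        b_eq.append(opt)
    values.append(0.0)
    return RawScale(scores=dict(zip(matrix.stimuli, values)))


@dataclass
class AnchoredValueScale:
    """Cardinal value scale with good = 100 and neutral = 0 exactly.

    Scores above 100 are better than good; scores below 0 mark an
    emergency on that criterion.
    """

    scores: dict[str, float]
    good_level: str
    neutral_level: str
    criterion: str | None = None

    def score(self, level_id: str) -> float:
        try:
            return self.scores[level_id]
        except KeyError:
            raise LookupError(
                f"level {level_id!r} not in scale for criterion {self.criterion!r}"
            ) from None

    def validate(
        self, descriptor: Descriptor | None = None, where: str = "scale"
    ) -> list[str]:
        v: list[str] = []
        for role, lid, want in (
            ("good", self.good_level, 100.0),
            ("neutral", self.neutral_level, 0.0),
        ):
            if lid not in self.scores:
                v.append(f"{where}: {role} anchor {lid!r} missing from scale")
            elif abs(self.scores[lid] - want) > ZERO_EPSILON:
                v.append(f"{where}: {role} anchor scores {self.scores[lid]}, expected {want}")
        if descriptor is not None:
            want_ids = set(descriptor.level_ids())
            if set(self.scores) != want_ids:
                v.append(f"{where}: scale levels {sorted(self.scores)} != descriptor levels")
            else:
                ordered = sorted(self.scores, key=descriptor.rank)
                vals = [self.scores[lid] for lid in ordered]
                if any(a <= b for a, b in zip(vals, vals[1:])):
                    v.append(f"{where}: scores not strictly decreasing with severity rank")
        return v


def anchor_scale(
    raw: RawScale,
    good: str,
    neutral: str,
    criterion: str | None = None,
) -> AnchoredValueScale:
    """Affine rescale so that the good stimulus hits 100 and neutral hits 0.

    w(x) = 100 · (raw(x) − raw(neutral)) / (raw(good) − raw(neutral)).
    The anchors come out exact (100.0 / 0.0, no rounding), the order of
    stimuli is preserved, and the output is invariant to any positive
    affine transform of the raw scale.
    """
    g = raw.scores[good]
    u = raw.scores[neutral]
    span = g - u
    if span <= 0:
        raise ValueError(
            f"good stimulus {good!r} (raw {g}) must score strictly above "
            f"neutral {neutral!r} (raw {u})"
        )
    scores = {s: 100.0 * (x - u) / span for s, x in raw.scores.items()}
    scores[good] = 100.0
    scores[neutral] = 0.0
    return AnchoredValueScale(
        scores=scores, good_level=good, neutral_level=neutral, criterion=criterion
    )
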