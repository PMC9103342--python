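# Methods

## Problem and model structure

The package supports referral decisions for child/adolescent victims of
sexual violence inside an intersectoral protection network. The decision
model is a value tree: one strategic objective (guarantee health, safety
and protection), five areas of concern (family aspects, threats, physical,
emotional and psychological changes) and eight leaf criteria, each
operationalised by a descriptor — an ordered list of performance levels
from least to most severe with two designated reference levels. **Good**
and **neutral** are methodological anchors, not value judgments about the
violence itself: neutral is the threshold below which a criterion is an
emergency, and good separates urgent territory from an accomplished state.
Coding a narrative case into descriptor levels is a clinical judgment made
by humans; the package only resolves structured label/id assignments
(case-insensitive exact match) and refuses anything ambiguous.

## MACBETH scale construction

Experts answer only qualitative questions: for a preference-ranked pair of
stimuli, the difference in attractiveness is null, very weak, weak,
moderate, strong, very strong or extreme (ordinals 0–6). The elicitation
plan follows the protocol of judging the worst stimulus against all others
plus every consecutive pair (2n−3 questions); remaining pairs are bounded
by transitivity: a chain with categories c₁..c_m implies the interval
[max c, min(6, Σc)], chains through different routes are intersected, and
an empty intersection is returned as inconsistency evidence.

A judgment set is converted to a scale by linear programming with the
conventional thresholds s_k = k and inter-pair separation δ = 1:

* v(worst) = 0;
* category k ≥ 1 on pair (i, j): v_i − v_j ≥ k;
* null judgments: v_i = v_j;
* cat(p) > cat(q): diff(p) ≥ diff(q) + (cat(p) − cat(q));
* unjudged consecutive pairs: v_i ≥ v_{i+1}.

Categories are closed lower bounds only; consistency comes from the
separation constraints. Any positive threshold choice yields an affinely
related scale, and anchoring (good → 100, neutral → 0, exact by
construction) removes that freedom, so the convention does not affect any
anchored output. Feasibility is decided by the same LP (HiGHS via
scipy.optimize.linprog, feasibility tolerance 1e−9); when infeasible, a
deletion filter reduces the constraint set to an irreducible infeasible
subset reported as the certificate. The reported scale is the optimum
minimizing v(best), with ties among optimal vertices broken by
lexicographically minimizing (v₀, v₁, …) through sequential re-solves with
pinned prefixes — LP values at integral constraint data come out integral
and are snapped at 1e−7, so output is reproducible across solver versions.
Float arithmetic is used throughout; rational arithmetic is unnecessary at
these problem sizes.

## Swing weighting

Criteria are ordered by repeatedly asking which single criterion one would
raise from neutral to good, everything else staying neutral; simultaneous
choices form tie-groups. The swings plus an "all criteria stay neutral"
reference stimulus (ranked last, hence scored 0) are judged like any
MACBETH stimuli; weights are the raw swing scores normalized to sum 1.
Tied swings are joined by null judgments, and the implementation
additionally shares the exact group value across a tie-group to keep
equality bit-exact under float division. Weights are scale-free
(multiplying all raw scores by α > 0 changes nothing) and a sector that
declines some criteria simply gets weights over its subset, renormalized;
cross-sector global scores must not be compared across different supports.

## Evaluation and triage

Evaluation is the additive model: per-criterion score = anchored-scale
lookup at the assigned level; global score = weighted sum. The global
score is reported for longitudinal monitoring but plays no role in
classification — triage is per criterion by sign, with ε = 1e−9 as the
zero band (anchored neutral scores are exactly 0.0 by construction; the
band only absorbs float residue from user-supplied re-anchored scales).
Criteria without an assignment are skipped with a warning; criteria a
sector does not model are reported "not assessed", never silently
classified. Routing attaches configured service options per
(criterion, class), falling back to class-level defaults (urgent →
immediate healthcare, social protection and mental health services).
Because scales decrease with severity rank, improving a single criterion's
level can only raise its score, so treatment progress moves criteria
monotonically from urgent toward follow-up.

## Group aggregation

Sector models are aggregated descriptively. The group ranking assigns each
criterion its modal printed position across the sector rankings (positions
counted only where the sector models the criterion); when several
positions are equally frequent the smallest is taken, and ordering ties
break by lower mean position, then by first appearance in the input — the
modal step is the conference rule, the two tie-breaks are this package's
own deterministic completion. Cross-sector scale statistics use the
arithmetic mean and the *sample* (n−1) standard deviation, reported to two
decimals round-half-up; that convention reproduces the Bauru summary cells
exactly, while the population formula does not. The compatibility check
flags any pair whose group order reverses an order that at least two
sectors ranking both criteria unanimously agree on; a sector that ties the
pair breaks unanimity. The group's own scales and weights are inputs from
the human decision conference, never computed aggregates — in the Bauru
fixture the group scale row visibly differs from the mean row, which is
expected.

## Delphi / DPSIR bookkeeping

Free-text reports are coded into keywords upstream, preserving anonymity;
the module ingests only codes. Tallies are exact frequency counts per
namespace (source / referral / goal), descending by count then code. The
seven stage-2 questions map fixedly onto DPSIR (Q1 → Drivers, Q2 →
Pressures, Q3–Q5 → State, Q6 → Impact, Q7 → Response); bucketing never
drops a code and a code mentioned under two questions appears in both
buckets. Consensus defaults to unanimity ("full consensus" reading) with a
configurable fraction threshold.

## Packaged Bauru fixture

The bundle transcribes the published model: all eight descriptors, the
four sector and one group bodily-injury value scales, the sector and group
swing rankings with their tie-groups, and the five published weight values
(0.3505, 0.1578 twice, 0.2728, 0.3636, and the 4 × 0.1404 group tie). The
bodily-injury descriptor carries a fifth, supplementary "very serious"
level because the five-column scales require it even though the descriptor
table lists four. Everything else is a clearly marked synthetic
placeholder constrained by the published typical-case scores, the anchors
and monotonicity: the other criteria's scales, the remaining weights, the
stage-2 keyword file and the routing overrides. Two published oddities are
preserved rather than repaired: Sector II's threat scale scores a death
threat 0 (equal to neutral), which violates strict monotonicity and is
surfaced as a load-time warning; and the typical case's pregnancy
evaluation was never reported, so the packaged profile omits it and
evaluation skips it with a warning.

## Synthetic generator

Property tests and the acceptance run use a seeded generator that emulates
an expert judging from a latent integer scale: gaps between consecutive
stimuli are drawn uniformly from {0..max_category} (a zero gap produces a
null judgment), only the elicitation-plan pairs are emitted, and each
pair's category is min(max_category, difference). The latent scale
satisfies every LP constraint, so "consistent" mode is feasible by
construction; "perturbed" mode bumps one judgment's category by ±2
(clipped to 1..6), producing a mix of feasible and infeasible matrices.
The generator emulates judgment structure only — it does not model expert
response styles, category compression at scale ends, or correlated
judgment errors, so passing property tests demonstrates correctness of the
machinery, not robustness to real elicitation noise.

## Verification choices and problem sizes

The consistency checker is validated against an exhaustive integer-scale
search over [0, 60]ⁿ (a brute-force oracle independent of the LP code) on
500 seeded matrices with n ≤ 4 and categories ≤ 3, half consistent and
half perturbed; solved scales are substituted back into every constraint
at 1e−9, and anchoring is checked for exactness and affine invariance on
the same stream. These sizes keep the whole suite under a quarter minute
while exercising every constraint family; larger n only grows the LP,
whose structure does not change.

## Known limitations

* The published sector scales (other than bodily injury) and most weights
  were never printed, so the fixture's placeholders are internally
  consistent but not the study's true values; analyses depending on them
  are illustrative.
* Group scales/weights being conference inputs means the package cannot
  re-derive them; `aggregate_rankings` covers only the ranking layer.
* Interval (multi-category) judgments are produced by transitivity
  analysis but not accepted as elicitation input, matching the protocol.
* No longitudinal storage: dynamic monitoring is supported only in the
  sense that re-evaluation after a level change moves scores monotonically.
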