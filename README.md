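# macbeth-triage

Multi-criteria severity triage for protection networks attending child and
adolescent victims of sexual violence.

Professionals in a protection network (health services, social protection,
child protective services) must decide, case by case, which demands need
immediate treatment, which can wait for a scheduled referral, and which
only need periodic monitoring — and must do so consistently across sectors
with very different training. This package implements a decision framework
for that problem: severity criteria organised in a value tree, cardinal
value scales built from qualitative expert judgments with the MACBETH
method, swing weights, an additive value model, and a per-criterion triage
rule, together with the group-aggregation and Delphi/DPSIR bookkeeping
that surround the model in practice. A fully worked model for the
protection network of Bauru (SP, Brazil) ships as a packaged fixture.

## The model

Each criterion *i* (bodily injuries, genital injuries, STIs, pregnancy,
depression, phobic anxiety disorder, threats, family aspects) carries a
descriptor: ordered performance levels with two reference levels, **good**
and **neutral**. MACBETH turns qualitative attractiveness-difference
judgments (null, very weak, weak, moderate, strong, very strong, extreme)
over pairs of levels into a cardinal scale via a linear program: a pair
judged in category *k* ≥ 1 must differ by at least *k*, null judgments tie
their stimuli, and pairs judged in higher categories must keep a larger
difference than pairs judged in lower ones. The minimal such scale,
affinely re-anchored so that

v_i(good) = 100,  v_i(neutral) = 0,

gives the per-criterion value function. Swing weights w_i (Σ w_i = 1) come
from MACBETH judgments over the swings "raise criterion *i* from neutral
to good, all else neutral", and a case *x* scores

V(x) = Σ_i w_i · v_i(x_i).

Triage is per criterion, by sign: v_i(x_i) < 0 → **urgent** (the case is
below the neutral threshold — an emergency on that criterion), = 0 →
**referral** (can wait), > 0 → **follow-up** (monitor periodically).

## Worked example

Triage the packaged typical case (serious bodily injuries, genital bruise,
STI diagnosis, moderate depression and phobic anxiety, death threat, no
protective family figure) under the Sector I model:

```
$ macbeth-triage triage --sector sector_I \
      --case src/macbeth_triage/fixtures/typical_case.json
criterion,level,score,class,options
bodily_injury,serious,-100.00,urgent,healthcare (immediate); social protection; mental health
family_aspect,no_protective_figure,-90.91,urgent,healthcare (immediate); social protection; mental health
threat,death,-50.00,urgent,healthcare (immediate); social protection; mental health
stis,diagnosis,0.00,referral,STI testing and treatment at a reference service
depression,moderate,0.00,referral,scheduled referral within the protection network
phobic_anxiety,moderate,0.00,referral,scheduled referral within the protection network
genital_injury,bruise_hematoma,100.00,follow_up,outpatient wound review
```

Three criteria sit below the neutral threshold (negative scores) and need
immediate intervention; three sit exactly at neutral and become referrals;
the genital injury is at the good level (100) and only needs follow-up.
Cross-sector dispersion of a value scale:

```
$ macbeth-triage stats --criterion bodily_injury
level,mean,stdev,n_sectors
no_injury,257.31,88.03,4
mild,100.00,0.00,4
moderate,0.00,0.00,4
serious,-68.75,37.50,4
very_serious,-171.88,157.58,4
```

The anchored levels (mild = good, moderate = neutral) are identical in
every sector by construction; the unanchored levels show how much the four
sectors' severity judgments diverge. The same operations are available as
library calls (`macbeth_triage.evaluate`, `classify`, `scale_stats`, …);
other subcommands: `validate`, `scale`, `weights`, `evaluate`,
`group-rank`, `tally`, `simulate`, `report`.

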