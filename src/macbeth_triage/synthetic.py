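"""Seeded synthetic judgment matrices and case profiles for property tests.

The generator emulates an expert answering the elicitation protocol from a
latent cardinal scale: it draws an integer witness scale, bins each asked
pair's difference into the qualitative categories, and emits judgments for
exactly the protocol's question plan (worst-vs-all plus consecutive
pairs).  By construction the witness satisfies every LP constraint, so
"consistent" mode is guaranteed feasible.  "perturbed" mode additionally
bumps one random judgment's category by ±2 (clipped to 1..6), which may or
may not break feasibility — useful for exercising the consistency checker
on both outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .macbeth import MAX_CATEGORY, JudgmentMatrix, elicitation_plan
from .value_model import CaseProfile, ValueTree


@dataclass
class SyntheticSpec:
    n_stimuli: int
    max_category: int = MAX_CATEGORY
    mode: str = "consistent"  # or "perturbed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise ValueError("need at least 2 stimuli")
        if not 1 <= self.max_category <= MAX_CATEGORY:
            raise ValueError(f"max_category must be in 1..{MAX_CATEGORY}")
        if self.mode not in ("consistent", "perturbed"):
            raise ValueError(f"unknown mode {self.mode!r}")


def generate_synthetic_judgments(spec: SyntheticSpec) -> JudgmentMatrix:
    """Judgment matrix over stimuli s0 (best) … s{n-1} (worst).

    Categories are min(max_category, witness difference); a zero gap
    between consecutive stimuli yields a null (tie) judgment.  The same
    seed always returns the same matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_stimuli
    # witness scale: worst at 0, gaps in {0..max_category} (0 = tied pair)
    gaps = rng.integers(0, spec.max_category + 1, size=n - 1)
    if gaps.sum() == 0:
        gaps[rng.integers(0, n - 1)] = 1  # avoid a fully degenerate scale
    values = np.concatenate([np.cumsum(gaps[::-1])[::-1], [0]])

    judgments: list[tuple[int, int, int]] = []
    for i, j in elicitation_plan(n):
        diff = int(values[i] - values[j])
        judgments.append((i, j, min(spec.max_category, diff)))

    label = f"synthetic(seed={spec.seed}, mode={spec.mode})"
    if spec.mode == "perturbed":
        idx = int(rng.integers(0, len(judgments)))
        i, j, k = judgments[idx]
        bump = int(rng.choice([-2, 2]))
        k_new = int(np.clip(k + bump, 1, MAX_CATEGORY))
        judgments[idx] = (i, j, k_new)
        label += f", bumped ({i},{j}) {k}->{k_new}"

    stimuli = [f"s{i}" for i in range(n)]
    return JudgmentMatrix(stimuli=stimuli, judgments=judgments, label=label)


def generate_synthetic_case(
    tree: ValueTree, seed: int = 0, case_id: str = "synthetic_case"
) -> CaseProfile:
    """Uniformly random level assignment for every criterion of the tree."""
    rng = np.random.default_rng(seed)
    assignments = {
        c.id: c.descriptor.levels[int(rng.integers(0, len(c.descriptor.levels)))].id
        for c in tree.criteria
    }
    return CaseProfile(
        case_id=case_id, assignments=assignments, provenance=f"synthetic (seed={seed})"
    )
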