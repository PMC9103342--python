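"""Brute-force integer-scale oracle, independent of the LP solver.

Feasibility of a judgment matrix is decided by exhaustive search over
integer scales v ∈ [0, vmax]^n with the worst stimulus pinned at 0,
checking every constraint family of the scale model directly.  Vectorised
with numpy so the n = 4 grid (61³ points) stays cheap.
"""

from __future__ import annotations

import numpy as np

from macbeth_triage.macbeth import JudgmentMatrix


def brute_force_feasible(matrix: JudgmentMatrix, vmax: int = 60) -> bool:
    n = matrix.n
    judged = matrix.judged()
    free = n - 1  # v_{n-1} = 0
    if free == 0:
        return True
    axes = [np.arange(vmax + 1, dtype=np.int32)] * free
    grids = np.meshgrid(*axes, indexing="ij")
    v = [g.ravel() for g in grids] + [np.zeros(grids[0].size, dtype=np.int32)]

    ok = np.ones(v[0].size, dtype=bool)
    for (i, j), k in judged.items():
        d = v[i] - v[j]
        ok &= (d == 0) if k == 0 else (d >= k)
    pairs = sorted(judged.items())
    for (p, kp) in pairs:
        for (q, kq) in pairs:
            if kp > kq:
                ok &= (v[p[0]] - v[p[1]]) >= (v[q[0]] - v[q[1]]) + (kp - kq)
    for i in range(n - 1):
        if (i, i + 1) not in judged:
            ok &= v[i] >= v[i + 1]
    return bool(ok.any())


def brute_force_minimal_scale(matrix: JudgmentMatrix, vmax: int = 60):
    """Lexicographically minimal feasible integer scale, or None."""
    n = matrix.n
    judged = matrix.judged()
    free = n - 1
    axes = [np.arange(vmax + 1, dtype=np.int32)] * free
    grids = np.meshgrid(*axes, indexing="ij")
    v = [g.ravel() for g in grids] + [np.zeros(grids[0].size, dtype=np.int32)]
    ok = np.ones(v[0].size, dtype=bool)
    for (i, j), k in judged.items():
        d = v[i] - v[j]
        ok &= (d == 0) if k == 0 else (d >= k)
    pairs = sorted(judged.items())
    for (p, kp) in pairs:
        for (q, kq) in pairs:
            if kp > kq:
                ok &= (v[p[0]] - v[p[1]]) >= (v[q[0]] - v[q[1]]) + (kp - kq)
    for i in range(n - 1):
        if (i, i + 1) not in judged:
            ok &= v[i] >= v[i + 1]
    if not ok.any():
        return None
    idx = np.flatnonzero(ok)
    cand = np.stack([v[i][idx] for i in range(n)], axis=1)
    order = np.lexsort(tuple(cand[:, i] for i in range(n - 1, -1, -1)))
    return cand[order[0]].tolist()
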