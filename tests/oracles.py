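"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit loops and textbook formulas, kept
deliberately separate from the package's vectorized code paths. The
decontamination oracle shares the package's documented permutation stream
(one ``numpy.random.default_rng(seed)``, genes in row order, degenerate genes
skipped, ``n_scrambles`` permutations per gene) so null values are comparable
one-for-one.
"""

from __future__ import annotations

import numpy as np


def pearson_loops(x, y) -> float:
    """Textbook Pearson correlation with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    return num / (dx * dy) ** 0.5


def decontam_chain_bruteforce(frame, marker_ids, seed, n_scrambles=1):
    """Full C -> R -> scrambled-null -> Z chain on a genes-x-samples DataFrame.

    Returns (C, R, null_values, Z) as plain Python containers. Markers with
    all-zero expression are dropped, as in the package.
    """
    genes = list(frame.index)
    samples = list(frame.columns)
    n = len(samples)

    fractions = {}
    for g in marker_ids:
        row = [float(frame.loc[g, s]) for s in samples]
        mx = max(row)
        if mx == 0:
            continue
        fractions[g] = [v / mx for v in row]
    C = [sum(fractions[g][j] for g in fractions) / len(fractions) for j in range(n)]

    marker_set = set(marker_ids)
    scored = [g for g in genes if g not in marker_set]
    R, degenerate = {}, {}
    for g in scored:
        x = [float(frame.loc[g, s]) for s in samples]
        degenerate[g] = max(x) == min(x)
        R[g] = 0.0 if degenerate[g] else pearson_loops(x, C)

    rng = np.random.default_rng(seed)
    null = []
    for g in scored:
        if degenerate[g]:
            continue
        x = [float(frame.loc[g, s]) for s in samples]
        for _ in range(n_scrambles):
            perm = rng.permutation(n)
            null.append(pearson_loops([x[j] for j in perm], C))

    mean = sum(null) / len(null)
    sd = (sum((v - mean) ** 2 for v in null) / (len(null) - 1)) ** 0.5
    Z = {g: (R[g] - mean) / sd for g in scored if not degenerate[g]}
    return C, R, null, Z


def bh_stepup_bruteforce(p):
    """Benjamini-Hochberg step-up by its definition: sort, scale, enforce
    monotonicity from the largest p down, cap at 1."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [p[order[k]] * m / (k + 1) for k in range(m)]
    for k in range(m - 2, -1, -1):
        q_sorted[k] = min(q_sorted[k], q_sorted[k + 1])
    q = [0.0] * m
    for k, i in enumerate(order):
        q[i] = min(q_sorted[k], 1.0)
    return q
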