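"""Definition-level reference implementations, independent of the package.

These oracles favour transparency over speed: exact rational arithmetic for
the hypergeometric enumeration, a literal step-up loop for the BH
adjustment, and a literal interval scan for insertion assignment.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration with exact rational probabilities.

    All tables with the observed margins are enumerated; the p-value is the
    exact sum of the probabilities of tables no more probable than the
    observed one (method of small p-values), converted to float at the end.
    """
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or m == 0 or b + d == 0:
        return 1.0
    total = comb(n1 + n2, m)
    probs = {}
    for x in range(max(0, m - n2), min(n1, m) + 1):
        probs[x] = Fraction(comb(n1, x) * comb(n2, m - x), total)
    obs = probs[a]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= obs)))


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the definition: fcpv_i = min over p_(j) >= p_(i)
    of min(1, m * p_(j) / j), evaluated literally in O(m^2)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * ranked[j] / (j + 1)) for j in range(m) if ranked[j] >= ranked[i]
        ]
        out[i] = min(candidates)
    res = np.empty(m)
    res[order] = out
    return res


def assign_insertions_literal(insertions, models) -> dict[str, int]:
    """Sense-insertion counts per gene by literal scanning, with the
    multi-gene-overlap exclusion applied per base."""
    counts = {m.gene_id: 0 for m in models}
    for chrom, pos, orient in insertions:
        owners = [
            m
            for m in models
            if m.chrom == chrom and m.region_start <= pos < m.region_end
        ]
        if len(owners) == 1 and owners[0].strand == orient:
            counts[owners[0].gene_id] += 1
    return counts


def ranksum_exact_small(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    from itertools import combinations

    x = list(x)
    y = list(y)
    pooled = x + y
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    all_ranks = [ranks[v] for v in pooled]
    sums = [sum(c) for c in combinations(all_ranks, len(x))]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(sums)
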