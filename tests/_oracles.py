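"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities with the most literal possible
procedure (explicit loops, exhaustive enumeration) and stay independent
of the package's implementation paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def literal_running_sum_es(ordered_genes, gene_set) -> float:
    """Step-by-step unweighted KS running sum over an already-ordered list.

    Hit: +1/G, miss: -1/(N-G); returns the signed deviation of maximal
    absolute value, preferring the positive extremum on exact ties.
    Computed in exact rational arithmetic so magnitude ties are decided
    correctly.
    """
    gene_set = set(gene_set)
    n = len(ordered_genes)
    g = sum(1 for x in ordered_genes if x in gene_set)
    assert 0 < g < n
    rs = Fraction(0)
    best_max = None
    best_min = None
    for x in ordered_genes:
        if x in gene_set:
            rs += Fraction(1, g)
        else:
            rs -= Fraction(1, n - g)
        best_max = rs if best_max is None else max(best_max, rs)
        best_min = rs if best_min is None else min(best_min, rs)
    return float(best_max) if best_max >= -best_min else float(best_min)


def exhaustive_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Enumerates every assignment of the pooled (tie-free) values to the
    first group and computes 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(pooled, n1):
        u = sum(ranks[v] for v in combo) - n1 * (n1 + 1) / 2
        us.append(u)
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
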