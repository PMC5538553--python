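"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own dynamic programs: likelihoods are
computed by exhaustive enumeration of ancestral states, pair probabilities by
exhaustive enumeration of secondary structures, and tail probabilities by
direct summation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_column_likelihood(tree, obs_map, model) -> float:
    """Sum over all ancestral-state assignments at internal nodes."""
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    leaf_state = {}
    for name, node in tree.leaf_names.items():
        sym = obs_map.get(name)
        leaf_state[node] = model.encode(sym) if sym is not None else -1
    n = model.n_states
    P = {v: model.transition_matrix(float(tree.blen[v])) for v in range(tree.n_nodes) if v != tree.root}
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internal)):
        states = dict(zip(internal, assign))
        w = model.pi[states[tree.root]]
        for v in internal:
            for ch in tree.children[v]:
                if ch in states:
                    w *= P[ch][states[v], states[ch]]
                else:
                    s = leaf_state[ch]
                    w *= 1.0 if s < 0 else P[ch][states[v], s]
        total += w
    return total


def enumerate_structures(pairs_available):
    """All non-crossing subsets of candidate pairs (i<j, 1-based)."""
    yield []
    for k, (i, j) in enumerate(pairs_available):
        inner = [(a, b) for (a, b) in pairs_available if i < a and b < j]
        outer = [(a, b) for (a, b) in pairs_available[k + 1 :] if a > j]
        for s1 in enumerate_structures(inner):
            for s2 in enumerate_structures(outer):
                yield [(i, j)] + s1 + s2


def enumeration_bpp(seq: str, em) -> np.ndarray:
    """Base-pair probabilities by exhaustive structure enumeration."""
    n = len(seq)
    candidates = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + em.h + 1, n + 1)
        if em.pair_weight(seq[i - 1], seq[j - 1]) > 0
    ]
    Z = 0.0
    acc = np.zeros((n, n))
    for struct in enumerate_structures(candidates):
        w = 1.0
        for i, j in struct:
            w *= em.pair_weight(seq[i - 1], seq[j - 1])
        Z += w
        for i, j in struct:
            acc[i - 1, j - 1] += w
    return acc / Z


def binom_sf(q: int, n: int, p: float) -> float:
    """Exact P(X >= q) for X ~ Binomial(n, p) by direct log-space summation."""
    logs = [
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log(1 - p)
        for k in range(q, n + 1)
    ]
    m = max(logs)
    return math.exp(m) * sum(math.exp(l - m) for l in logs)


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p-value: P(upper-left cell >= a) with margins fixed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def pmf(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(ntot, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(a, hi + 1))


def bh_by_hand(pvals):
    """Step-up BH applied literally to a list of p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        q[i] = val
        prev = val
    return q


def jc_distance(p_diff: float) -> float:
    return -0.75 * math.log(1 - 4 * p_diff / 3)


def dinuc_counts(seq: str):
    from collections import Counter

    return Counter(seq), Counter(a + b for a, b in zip(seq, seq[1:]))


def all_dinucleotide_shuffles(seq: str) -> set[str]:
    """Every distinct permutation of seq with the same first character and
    dinucleotide count multiset (brute force; short sequences only)."""
    mono, dinuc = dinuc_counts(seq)
    out = set()
    for perm in set(itertools.permutations(seq)):
        s = "".join(perm)
        if s[0] != seq[0]:
            continue
        m2, d2 = dinuc_counts(s)
        if m2 == mono and d2 == dinuc:
            out.add(s)
    return out
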