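"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations -- double loops, full enumeration of label
assignments, direct combinatorial sums -- kept separate from the package so
they can serve as ground truth for the optimized code paths.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np


def ks_statistic_naive(a, b) -> float:
    """Max |F_a - F_b| by direct counting at every pooled value."""
    a, b = list(a), list(b)
    best = 0.0
    for t in a + b:
        fa = sum(1 for x in a if x <= t) / len(a)
        fb = sum(1 for x in b if x <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best


def ks_exact_p_naive(a, b) -> float:
    """P(D >= D_obs) over all C(n1+n2, n1) assignments of pooled values."""
    a, b = list(a), list(b)
    pooled = a + b
    d_obs = ks_statistic_naive(a, b)
    n = len(pooled)
    hits = total = 0
    for idx in combinations(range(n), len(a)):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if ks_statistic_naive(ga, gb) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def u_statistic_naive(a, b) -> float:
    """Mann-Whitney U of group a: #(a_i > b_j) + 0.5 #(a_i == b_j)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_p_naive(a, b) -> float:
    """Two-sided exact p: P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|)."""
    a, b = list(a), list(b)
    pooled = a + b
    center = len(a) * len(b) / 2.0
    dev_obs = abs(u_statistic_naive(a, b) - center)
    n = len(pooled)
    hits = total = 0
    for idx in combinations(range(n), len(a)):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(u_statistic_naive(ga, gb) - center) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def average_ranks_naive(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_naive(x, y) -> float:
    """Rank (average ties) then Pearson."""
    rx = average_ranks_naive(list(x))
    ry = average_ranks_naive(list(y))
    return float(np.corrcoef(rx, ry)[0, 1])


def hypergeom_upper_naive(k, set_size, hits_total, background) -> float:
    """P(X >= k) by direct combinatorial summation."""
    denom = math.comb(background, set_size)
    total = 0
    for i in range(k, min(set_size, hits_total) + 1):
        total += math.comb(hits_total, i) * math.comb(background - hits_total, set_size - i)
    return total / denom


def bh_naive(pvals) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def pairwise_diff_freqs_naive(tail_lengths, max_diff) -> dict[int, float]:
    """Double-loop enumeration of all unordered distinct tag pairs."""
    tl = list(tail_lengths)
    counts: Counter = Counter()
    n_pairs = 0
    for i in range(len(tl)):
        for j in range(i + 1, len(tl)):
            counts[abs(tl[i] - tl[j])] += 1
            n_pairs += 1
    return {d: counts.get(d, 0) / n_pairs for d in range(max_diff + 1)}


def scan_sites_naive(seq: str, site_strings: dict[str, str]) -> list[tuple[str, int]]:
    """All-offsets substring scan with the most-specific-type precedence.

    Re-derives the reporting rule from scratch: record every occurrence of
    every site string, then drop 7mers subsumed by an 8mer at the same locus
    and 6mers lying inside any 7/8mer occurrence at the same locus.
    """
    occ: dict[str, list[int]] = {t: [] for t in site_strings}
    for t, s in site_strings.items():
        for i in range(len(seq) - len(s) + 1):
            if seq[i : i + len(s)] == s:
                occ[t].append(i)
    out: list[tuple[str, int]] = [("8mer", i) for i in occ["8mer"]]
    eight = set(occ["8mer"])
    out += [("7mer-m8", i) for i in occ["7mer-m8"] if i not in eight]
    out += [("7mer-A1", i) for i in occ["7mer-A1"] if i - 1 not in eight]
    # a 6mer at i sits inside a 7mer-A1 at i, a 7mer-m8 at i-1 or an 8mer at i-1
    shadow = set(occ["7mer-A1"]) | {i + 1 for i in occ["7mer-m8"]} | {i + 1 for i in eight}
    out += [("6mer", i) for i in occ["6mer"] if i not in shadow]
    return sorted(out, key=lambda ti: (ti[1], ti[0]))


def classify_naive(seq: str, utr: tuple[int, int], site_strings: dict[str, str]) -> str:
    """Site / no-site / excluded labels straight from the definitions."""
    start, end = utr

    def occurrences(s):
        return [i for i in range(len(seq) - len(s) + 1) if seq[i : i + len(s)] == s]

    long_in_utr = any(
        start <= i and i + len(site_strings[t]) <= end
        for t in ("8mer", "7mer-m8", "7mer-A1")
        for i in occurrences(site_strings[t])
    )
    long_anywhere = any(occurrences(site_strings[t]) for t in ("8mer", "7mer-m8", "7mer-A1"))
    six_in_utr = any(
        start <= i and i + 6 <= end for i in occurrences(site_strings["6mer"])
    )
    if long_in_utr:
        return "site"
    if not long_anywhere and not six_in_utr:
        return "no_site"
    return "excluded"
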