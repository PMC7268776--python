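"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and the vectorized style) of the
package: plain-Python loops, exact rational arithmetic where feasible, and
direct definitions, so that agreement is evidence rather than tautology.
"""
from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def oracle_tau(xs) -> float:
    """Direct evaluation of the specificity index definition."""
    xs = list(xs)
    x_max = max(xs)
    total = 0.0
    for x in xs:
        total += 1.0 - math.log2(x + 1.0) / math.log2(x_max + 1.0)
    return total / (len(xs) - 1)


def oracle_tsg_calls(matrix, top_frac=0.20, min_fpkm=1.0, rank_k=3):
    """Brute-force reapplication of the three calling filters.

    ``matrix`` is a pandas gene x tissue DataFrame without all-zero rows.
    Returns the set of (gene, tissue) calls.
    """
    genes = list(matrix.index)
    tissues = list(matrix.columns)
    taus = {g: oracle_tau(matrix.loc[g].tolist()) for g in genes}
    ordered = sorted(taus.values())
    rank = max(1, math.ceil((1.0 - top_frac) * len(ordered)))
    threshold = ordered[rank - 1]
    calls = set()
    for g in genes:
        if taus[g] < threshold:
            continue
        row = matrix.loc[g]
        for t in tissues:
            x = row[t]
            if x < min_fpkm:
                continue
            n_greater = sum(1 for t2 in tissues if row[t2] > x)
            if n_greater < rank_k:
                calls.add((g, t))
    return calls


def oracle_hypergeom_upper(k, K, n, N) -> float:
    """P(X >= k) by exact rational enumeration over draw counts."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def oracle_bh(pvals):
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for pos in range(m - 1, -1, -1):
        i = indexed[pos]
        val = min(prev, pvals[i] * m / (pos + 1))
        adjusted[i] = val
        prev = val
    return adjusted


def oracle_wilcoxon_one_sided(a, b, alternative="a_greater") -> float:
    """Exact one-sided rank-sum p by enumerating all rank assignments.

    Tie-free inputs only.  Returns P(rank-sum of the favoured sample >=
    observed) over all C(n+m, n) equally likely assignments.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    fav = a if alternative == "a_greater" else b
    observed = sum(ranks[v] for v in fav)
    n_fav = len(fav)
    total = 0
    hits = 0
    for combo in combinations(range(1, len(pooled) + 1), n_fav):
        total += 1
        if sum(combo) >= observed:
            hits += 1
    return hits / total


def oracle_centralities(adj):
    """Degree, betweenness and closeness by explicit all-pairs BFS.

    ``adj`` maps node -> set of neighbours (undirected).  Betweenness sums
    sigma_st(v)/sigma_st over unordered pairs {s, t} with s != v != t;
    closeness is r_v / sum of distances to reachable vertices (0 when
    isolated).
    """
    nodes = sorted(adj)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sg = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(adj[u]):
                    if w not in d:
                        d[w] = d[u] + 1
                        sg[w] = 0
                        nxt.append(w)
                    if d[w] == d[u] + 1:
                        sg[w] += sg[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = sg

    degree = {v: len(adj[v]) for v in nodes}
    betweenness = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    betweenness[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    closeness = {}
    for v in nodes:
        reach = [u for u in dist[v] if u != v]
        total = sum(dist[v][u] for u in reach)
        closeness[v] = len(reach) / total if total > 0 else 0.0
    return degree, betweenness, closeness
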