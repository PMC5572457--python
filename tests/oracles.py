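"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain Python against the mathematical
definitions (full running-sum walks, exhaustive enumeration, union-find)
so the package's vectorized implementations can be cross-checked without
sharing any code path with them.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------- KS / GSEA

def running_sum_es(positions, n: int) -> float:
    """KS enrichment score by walking every rank of the list (O(n)).

    ``positions`` are the 1-based ranks of the gene-set members. Exact
    rational arithmetic keeps ties in |running sum| exact, so the extremum
    reached earliest in the walk wins deterministically.
    """
    from fractions import Fraction

    hits = set(int(p) for p in positions)
    s = len(hits)
    if s == 0 or s >= n:
        raise ValueError("need a non-empty proper subset")
    inc = Fraction(1, s)
    dec = Fraction(1, n - s)
    best = Fraction(0)
    cur = Fraction(0)
    for r in range(1, n + 1):
        cur += inc if r in hits else -dec
        if abs(cur) > abs(best):
            best = cur
    return float(best)


def es_oracle(ranked, genes) -> float:
    """Enrichment score of a gene collection in a RankedList, by full walk."""
    rank_of = {g: i + 1 for i, g in enumerate(ranked.genes)}
    positions = [rank_of[g] for g in genes if g in rank_of]
    return running_sum_es(positions, len(ranked.genes))


def directed_tes_oracle(target, query, p: int) -> float:
    es_up = es_oracle(target, query.genes[:p])
    es_down = es_oracle(target, query.genes[-p:])
    return 1.0 - (es_up - es_down) / 2.0


def trans_distance_oracle(a, b, p: int) -> float:
    return (directed_tes_oracle(a, b, p) + directed_tes_oracle(b, a, p)) / 2.0


# ------------------------------------------------------------- rank algebra

def footrule_oracle(a, b) -> int:
    ra = {g: i + 1 for i, g in enumerate(a.genes)}
    rb = {g: i + 1 for i, g in enumerate(b.genes)}
    return sum(abs(ra[g] - rb[g]) for g in ra)


def borda_oracle(a, b) -> tuple[str, ...]:
    ra = {g: i + 1 for i, g in enumerate(a.genes)}
    rb = {g: i + 1 for i, g in enumerate(b.genes)}
    return tuple(sorted(ra, key=lambda g: (ra[g] + rb[g], g)))


# ----------------------------------------------------------- hypergeometric

def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation."""
    total = math.comb(N, n)
    upper = min(K, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, upper + 1)) / total


# ---------------------------------------------------------------- graph ops

def giant_component_oracle(nodes, edges) -> set[tuple[int, int]]:
    """(node count, edge count) candidates for the largest component.

    Computed via union-find. ``edges`` is an iterable of (a, b) pairs;
    isolated nodes are ignored, matching the package's giant-component
    convention. When several components tie for the maximal node count, all
    their (node, edge) pairs are returned, since "the" giant component is
    then an arbitrary choice among them.
    """
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    touched = set()
    edge_list = list(edges)
    for a, b in edge_list:
        touched.add(a)
        touched.add(b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    if not touched:
        return {(0, 0)}
    comps: dict = {}
    for v in touched:
        comps.setdefault(find(v), set()).add(v)
    top = max(len(c) for c in comps.values())
    out = set()
    for comp in comps.values():
        if len(comp) == top:
            n_edges = sum(1 for a, b in edge_list if a in comp and b in comp)
            out.add((top, n_edges))
    return out
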