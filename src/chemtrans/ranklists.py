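"""Ranked-list algebra: Spearman footrule, Borda merging, and hierarchical
merging of replicate rankings into a prototype ranked list (PRL).

A ranked list is a total ordering (ranks 1..n, rank 1 = most up-regulated)
of a fixed gene universe shared by every list in one analysis. The PRL of a
drug is obtained by repeatedly merging the two closest lists (smallest
Spearman footrule distance) with the Borda rule until a single consensus
list remains — a minimum-distance agglomeration in the style of Kruskal's
algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UniverseMismatchError(ValueError):
    """Two ranked lists do not share the same gene universe."""

    def __init__(self, only_a: set[str], only_b: set[str]):
        self.only_a = only_a
        self.only_b = only_b
        msg = "ranked lists have different gene universes"
        if only_a:
            msg += f"; {len(only_a)} genes only in first (e.g. {sorted(only_a)[:5]})"
        if only_b:
            msg += f"; {len(only_b)} genes only in second (e.g. {sorted(only_b)[:5]})"
        super().__init__(msg)


@dataclass(frozen=True)
class RankedList:
    """A bijective assignment of ranks 1..n to a gene universe.

    Parameters
    ----------
    genes : tuple of str
        Gene identifiers in rank order: ``genes[0]`` has rank 1 (most
        up-regulated), ``genes[-1]`` rank n (most down-regulated).
    """

    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("empty ranked list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in ranked list")

    @classmethod
    def from_ranks(cls, rank_of: dict[str, int]) -> "RankedList":
        """Build from a gene→rank map; ranks must be a bijection onto 1..n."""
        n = len(rank_of)
        ranks = sorted(rank_of.values())
        if ranks != list(range(1, n + 1)):
            raise ValueError("ranks are not a bijection onto 1..n (ties or gaps)")
        ordered = sorted(rank_of, key=rank_of.__getitem__)
        return cls(tuple(ordered))

    @classmethod
    def from_scores(cls, genes: list[str] | tuple[str, ...], scores) -> "RankedList":
        """Rank genes by descending score; ties broken by gene identifier."""
        scores = np.asarray(scores, dtype=float)
        if len(genes) != scores.shape[0]:
            raise ValueError("genes and scores length mismatch")
        order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
        return cls(tuple(genes[i] for i in order))

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.genes)

    def ranks(self) -> dict[str, int]:
        """Gene → rank (1-based)."""
        return {g: i + 1 for i, g in enumerate(self.genes)}

    def rank_array(self, gene_order: tuple[str, ...]) -> np.ndarray:
        """Ranks as an int array aligned to ``gene_order``."""
        r = self.ranks()
        return np.array([r[g] for g in gene_order], dtype=np.int64)

    def reversed(self) -> "RankedList":
        return RankedList(tuple(reversed(self.genes)))


def _check_universe(a: RankedList, b: RankedList) -> None:
    if a.genes == b.genes:
        return
    ua, ub = a.universe, b.universe
    if ua != ub:
        raise UniverseMismatchError(set(ua - ub), set(ub - ua))


def footrule_distance(a: RankedList, b: RankedList) -> int:
    """Spearman footrule: sum over genes of |rank_a - rank_b|.

    A metric on permutations of the shared universe; 0 iff the lists are
    identical, maximal (n^2/2 for even n) when one list reverses the other.
    """
    _check_universe(a, b)
    ra = a.rank_array(a.genes)  # identity: 1..n
    rb = b.rank_array(a.genes)
    return int(np.abs(ra - rb).sum())


def borda_merge(a: RankedList, b: RankedList) -> RankedList:
    """Merge two ranked lists by the Borda rule (sum of ranks, re-rank ascending).

    Ties in the rank sum are broken by lexicographic gene identifier, so the
    result is deterministic and symmetric in its inputs.
    """
    _check_universe(a, b)
    ra, rb = a.ranks(), b.ranks()
    genes = sorted(a.universe)
    order = sorted(genes, key=lambda g: (ra[g] + rb[g], g))
    return RankedList(tuple(order))


@dataclass(frozen=True)
class PRL:
    """Prototype ranked list: consensus ranking merged from replicate profiles.

    ``merge_order`` records each pairwise merge event as
    (id_a, id_b, merged_id, footrule_distance); for k members there are
    exactly k - 1 events.
    """

    merged: RankedList
    members: tuple[str, ...]
    merge_order: tuple[tuple[str, str, str, int], ...] = field(default_factory=tuple)


def build_prl(profiles: list[RankedList], ids: list[str] | None = None) -> PRL:
    """Hierarchically merge profiles into a single consensus ranking.

    At each step the two surviving lists with the smallest footrule distance
    are merged with :func:`borda_merge` and replace the pair; the process
    repeats until one list remains. Ties in the pair selection are broken on
    the lexicographically smallest (id_a, id_b) pair.
    """
    if not profiles:
        raise ValueError("build_prl requires at least one profile")
    if ids is None:
        ids = [f"profile_{i}" for i in range(len(profiles))]
    if len(ids) != len(profiles):
        raise ValueError("ids and profiles length mismatch")
    for p in profiles[1:]:
        _check_universe(profiles[0], p)

    alive: dict[str, RankedList] = dict(zip(ids, profiles))
    members = tuple(ids)
    events: list[tuple[str, str, str, int]] = []
    # distances between all surviving pairs, recomputed only for merged nodes
    dist: dict[tuple[str, str], int] = {}

    def key(x: str, y: str) -> tuple[str, str]:
        return (x, y) if x <= y else (y, x)

    names = sorted(alive)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            dist[(x, y)] = footrule_distance(alive[x], alive[y])

    counter = 0
    while len(alive) > 1:
        (x, y), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = borda_merge(alive[x], alive[y])
        new_id = f"__merge_{counter}"
        counter += 1
        events.append((x, y, new_id, d))
        del alive[x], alive[y]
        dist = {k: v for k, v in dist.items() if x not in k and y not in k}
        for other, lst in alive.items():
            dist[key(other, new_id)] = footrule_distance(lst, merged)
        alive[new_id] = merged

    (final,) = alive.values()
    return PRL(merged=final, members=members, merge_order=tuple(events))
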