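"""Kolmogorov–Smirnov (GSEA-style) enrichment scores on ranked lists and the
derived pairwise transcriptional distance.

The enrichment score of a gene set S in a ranked list walks the list from
rank 1 to n accumulating +1/|S| at each hit and -1/(n-|S|) at each miss and
returns the signed deviation of maximal absolute value, in [-1, 1]. The
transcriptional distance between two profiles cross-enriches the top-p and
bottom-p genes of each profile in the other and averages the two directed
dissimilarities, giving a value in [0, 2]: 0 for identical rankings, 2 when
one ranking reverses the other, with ~1 for unrelated rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chemtrans.ranklists import PRL, RankedList, _check_universe

#: distances below this are called "transcriptionally similar" (network /
#: signature significance threshold)
SIMILARITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))

    def intersect(self, universe: frozenset[str]) -> "GeneSet":
        return GeneSet(self.name, self.genes & universe)


def default_p(n: int, p: int | None = None) -> int:
    """Number of top/bottom genes used by the transcriptional distance.

    Defaults to 250 for genome-scale universes and scales down as n/10 for
    small universes so that 2p <= n always holds.
    """
    if p is not None:
        return p
    return max(1, min(250, n // 10))


def _es_from_positions(positions: np.ndarray, n: int) -> float:
    """Signed-extremum KS statistic given the sorted 1-based hit ranks."""
    s = positions.shape[0]
    if s == 0 or s >= n:
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    hit = 1.0 / s
    miss = 1.0 / (n - s)
    # running sum only changes slope at hits; evaluate extrema analytically:
    # just before hit i (i = 1..s, rank r_i): value = (i-1)*hit - (r_i - i + 1 - 1)*miss
    # just after hit i:                       value = i*hit - (r_i - i)*miss
    i = np.arange(1, s + 1, dtype=float)
    r = positions.astype(float)
    after = i * hit - (r - i) * miss
    before = (i - 1) * hit - (r - i) * miss
    # candidates in walk order (start, then just-before/just-after each hit) so
    # that ties in |value| resolve to the extremum reached earliest in the list,
    # exactly as a left-to-right running-sum walk would
    candidates = np.empty(2 * s + 1)
    candidates[0] = 0.0
    candidates[1::2] = before
    candidates[2::2] = after
    mags = np.abs(candidates)
    # distinct extrema differ by >= 1/(s * (n - s)), far above this tolerance;
    # it only collapses float-rounding noise between mathematically equal ties
    idx = int(np.argmax(mags >= mags.max() - 1e-12))
    return float(candidates[idx])


def enrichment_score(ranked: RankedList, gene_set: GeneSet) -> float:
    """Unweighted KS enrichment score of ``gene_set`` in ``ranked``, in [-1, 1].

    +1 when the set occupies the top |S| ranks, -1 when it occupies the
    bottom |S| ranks; antisymmetric under list reversal.
    """
    genes = gene_set.genes & ranked.universe
    if not genes or len(genes) >= ranked.n:
        raise ValueError(
            f"gene set {gene_set.name!r} is empty or covers the whole universe after intersection"
        )
    rank_of = ranked.ranks()
    positions = np.sort(np.array([rank_of[g] for g in genes], dtype=np.int64))
    return _es_from_positions(positions, ranked.n)


@dataclass(frozen=True)
class TranscriptionalDistance:
    value: float
    p_top_bottom: int


def _directed_tes(target: RankedList, query: RankedList, p: int) -> float:
    """TES(target | query) = 1 - (ES_up - ES_down)/2.

    ES_up enriches the top-p genes of the query in the target ranking,
    ES_down the bottom-p genes. 0 for identical rankings, 2 for reversed.
    """
    rank_of = target.ranks()
    n = target.n
    up = np.sort(np.array([rank_of[g] for g in query.genes[:p]], dtype=np.int64))
    down = np.sort(np.array([rank_of[g] for g in query.genes[-p:]], dtype=np.int64))
    es_up = _es_from_positions(up, n)
    es_down = _es_from_positions(down, n)
    return 1.0 - (es_up - es_down) / 2.0


def transcriptional_distance(a: RankedList, b: RankedList, p: int | None = None) -> TranscriptionalDistance:
    """Symmetric GSEA-based dissimilarity between two profiles, in [0, 2]."""
    _check_universe(a, b)
    p = default_p(a.n, p)
    if p < 1 or 2 * p > a.n:
        raise ValueError(f"p={p} invalid: need 1 <= p and 2p <= n={a.n}")
    value = (_directed_tes(a, b, p) + _directed_tes(b, a, p)) / 2.0
    return TranscriptionalDistance(value=value, p_top_bottom=p)


def pairwise_distance_matrix(prls: list[PRL] | list[RankedList], p: int | None = None):
    """Symmetric matrix of transcriptional distances, zero diagonal.

    Accepts PRLs or bare ranked lists; returns an (m, m) float array.
    """
    lists = [x.merged if isinstance(x, PRL) else x for x in prls]
    if len(lists) < 2:
        raise ValueError("need at least two profiles")
    for lst in lists[1:]:
        _check_universe(lists[0], lst)
    m = len(lists)
    n = lists[0].n
    p = default_p(n, p)
    if p < 1 or 2 * p > n:
        raise ValueError(f"p={p} invalid: need 1 <= p and 2p <= n={n}")
    # integer-encode genes once: gene_idx[k] of list i = universe index of the
    # gene at rank k+1; rank_of[i][u] = rank of universe-gene u in list i
    gene_to_int = {g: k for k, g in enumerate(sorted(lists[0].universe))}
    idx = np.array([[gene_to_int[g] for g in lst.genes] for lst in lists], dtype=np.int64)
    rank_of = np.empty_like(idx)
    arange = np.arange(1, n + 1, dtype=np.int64)
    for i in range(m):
        rank_of[i, idx[i]] = arange

    def tes(i: int, j: int) -> float:
        """TES(list i | list j)."""
        up = np.sort(rank_of[i, idx[j, :p]])
        down = np.sort(rank_of[i, idx[j, -p:]])
        return 1.0 - (_es_from_positions(up, n) - _es_from_positions(down, n)) / 2.0

    out = np.zeros((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            d = (tes(i, j) + tes(j, i)) / 2.0
            out[i, j] = out[j, i] = d
    return out
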