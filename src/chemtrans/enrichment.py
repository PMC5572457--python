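"""Enrichment analyses over the drug network.

Three flavours:

* descriptor enrichment — for each physicochemical descriptor, drugs are
  ranked by descending value and the KS/GSEA enrichment score of a rich
  club's member set is computed, with an empirical permutation p-value and
  Benjamini-Hochberg FDR across descriptors;
* ATC community enrichment — exact hypergeometric upper-tail test for
  over-representation of an ATC code (at a chosen level) inside a community,
  BH-adjusted across all (community, code) tests;
* drug-set enrichment (DSEA-lite) — the member drugs' consensus ranking is
  scored against each gene set, with size-matched random gene sets providing
  the empirical null. This is a simplified consensus-profile variant of drug
  set enrichment analysis, not a reimplementation of the full method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chemtrans.gsea import GeneSet, _es_from_positions
from chemtrans.network import Community
from chemtrans.ranklists import PRL, RankedList, build_prl


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _empirical_p(observed_abs: float, null_abs: np.ndarray) -> float:
    """(b + 1) / (R + 1) permutation p-value on |ES| (never exactly zero)."""
    b = int((null_abs >= observed_abs).sum())
    return (b + 1) / (len(null_abs) + 1)


def descriptor_enrichment(
    descriptors: pd.DataFrame,
    club_members: set[str],
    permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """KS enrichment of a rich club in every descriptor's drug ranking.

    For each descriptor column, all drugs are sorted by descending value and
    the enrichment score of ``club_members`` in that ranking is computed; a
    positive score means the club's drugs concentrate at high values.
    The p-value is the empirical tail probability of |ES| over random member
    sets of the same size; q is BH across descriptors.

    Returns a DataFrame with columns descriptor, es, p, q.
    """
    if permutations < 100:
        raise ValueError("need at least 100 permutations")
    ids = list(descriptors.index.astype(str))
    members = {str(m) for m in club_members}
    if not members or not members <= set(ids):
        missing = members - set(ids)
        raise ValueError(f"club members not in descriptor matrix: {sorted(missing)[:5]}")
    if members == set(ids):
        raise ValueError("club covers the entire compound universe")
    n = len(ids)
    s = len(members)
    rng = np.random.default_rng(seed)
    member_mask = np.array([i in members for i in ids])

    # random member sets shared across descriptors
    perm_idx = np.array([rng.choice(n, size=s, replace=False) for _ in range(permutations)])

    rows = []
    for col in descriptors.columns:
        vals = descriptors[col].to_numpy(dtype=float)
        # descending by value; ties broken by drug id for determinism
        order = np.lexsort((np.array(ids), -vals))
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(1, n + 1)
        obs = _es_from_positions(np.sort(ranks[member_mask]), n)
        null = np.array([
            abs(_es_from_positions(np.sort(ranks[perm_idx[r]]), n))
            for r in range(permutations)
        ])
        rows.append({"descriptor": col, "es": obs, "p": _empirical_p(abs(obs), null)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class ATCEnrichmentResult:
    community_id: int
    atc_code: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = float("nan")


def truncate_atc(code: str, level: int) -> str:
    """Prefix of an ATC code at a hierarchy level (1..5).

    Level boundaries follow the WHO format: 1 char (anatomical), 3
    (therapeutic), 4 (pharmacological), 5 (chemical subgroup), 7 (compound).
    """
    cuts = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
    if level not in cuts:
        raise ValueError("ATC level must be in 1..5")
    return code[: cuts[level]]


def atc_community_enrichment(
    communities: list[Community],
    atc: dict[str, set[str]],
    level: int = 4,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ATC codes in communities.

    The universe N is the set of annotated drugs across all communities
    (drugs without any ATC code are excluded). For each code present in a
    community, p = P(X >= k) for X ~ Hypergeom(N, K, n); BH FDR is applied
    across all (community, code) tests. A community counts as enriched if
    any of its codes reaches q < 0.05.
    """
    annotated = {d for d, codes in atc.items() if codes}
    all_members = set().union(*(c.members for c in communities))
    universe = sorted(all_members & annotated)
    if not universe:
        raise ValueError("no annotated drugs in the communities")
    N = len(universe)
    code_counts: dict[str, int] = {}
    level_codes = {d: {truncate_atc(c, level) for c in atc.get(d, set())} for d in universe}
    for d in universe:
        for c in level_codes[d]:
            code_counts[c] = code_counts.get(c, 0) + 1

    rows = []
    for comm in communities:
        members = sorted(set(comm.members) & set(universe))
        n = len(members)
        if n == 0:
            continue
        local: dict[str, int] = {}
        for d in members:
            for c in level_codes[d]:
                local[c] = local.get(c, 0) + 1
        for code, k in sorted(local.items()):
            K = code_counts[code]
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append({"community_id": comm.id, "atc_code": code,
                         "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def dsea(
    drug_prls: list[PRL] | list[RankedList],
    gene_sets: list[GeneSet],
    permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus-profile drug-set enrichment (DSEA-lite).

    The drug set's rankings are merged into one consensus ranking; each gene
    set is scored against it by the KS enrichment score, with an empirical
    p-value from size-matched random gene sets and BH adjustment across
    sets. Reported by descending |ES|.
    """
    lists = [x.merged if isinstance(x, PRL) else x for x in drug_prls]
    if len(lists) < 2:
        raise ValueError("need at least two drug profiles")
    consensus = build_prl(lists).merged
    universe = consensus.universe
    usable = [gs.intersect(universe) for gs in gene_sets]
    usable = [gs for gs in usable if 0 < len(gs.genes) < consensus.n]
    if not usable:
        raise ValueError("all gene sets empty (or full) after intersection with the universe")
    rng = np.random.default_rng(seed)
    n = consensus.n
    rank_of = consensus.ranks()
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for gs in usable:
        positions = np.sort(np.array([rank_of[g] for g in gs.genes], dtype=np.int64))
        obs = _es_from_positions(positions, n)
        size = len(gs.genes)
        if size not in null_cache:
            null_cache[size] = np.array([
                abs(_es_from_positions(
                    np.sort(rng.choice(n, size=size, replace=False) + 1), n))
                for _ in range(permutations)
            ])
        rows.append({"gene_set": gs.name, "es": obs,
                     "p": _empirical_p(abs(obs), null_cache[size])})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.reindex(out["es"].abs().sort_values(ascending=False).index).reset_index(drop=True)
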