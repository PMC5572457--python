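"""Structural-transcriptional coherence of drug pairs.

Every drug pair lives in a plane whose axes are the structural distance and
the transcriptional distance between the two compounds. Significance
thresholds on each axis split the plane into four quadrants:

* I  — structurally similar, transcriptionally different (incoherent);
* II — similar on both axes (coherent);
* III — structurally different, transcriptionally similar (incoherent);
* IV — different on both axes (coherent; the vast majority of random pairs).

The PPV machinery benchmarks a distance against shared therapeutic
annotation: pairs are sorted ascending by distance and the cumulative
positive predictive value of "shares an ATC code at level L" is traced down
the ranking. The TV-split benchmark contrasts the transcriptional distance's
PPV within the low-TV (reliable) and high-TV (noisy) halves of a compendium
against a shuffled baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chemtrans.enrichment import truncate_atc
from chemtrans.gsea import pairwise_distance_matrix
from chemtrans.ranklists import PRL, RankedList


QUADRANTS = ("I", "II", "III", "IV")


def classify_quadrant(d_struct: float, d_trans: float,
                      t_struct: float, t_trans: float) -> str:
    """Quadrant of one drug pair given both distances and both thresholds."""
    if d_struct < 0 or d_trans < 0:
        raise ValueError("distances must be nonnegative")
    if t_struct <= 0 or t_trans <= 0:
        raise ValueError("thresholds must be positive")
    struct_close = d_struct <= t_struct
    trans_close = d_trans <= t_trans
    if struct_close and not trans_close:
        return "I"
    if struct_close and trans_close:
        return "II"
    if not struct_close and trans_close:
        return "III"
    return "IV"


@dataclass(frozen=True)
class PairRecord:
    drug_a: str
    drug_b: str
    d_struct: float
    d_trans: float
    quadrant: str
    shares_atc: bool | None = None


def pair_records(
    struct: pd.DataFrame,
    trans: pd.DataFrame,
    t_struct: float,
    t_trans: float,
    atc: dict[str, set[str]] | None = None,
    atc_level: int = 4,
) -> list[PairRecord]:
    """All unordered drug pairs shared by both distance matrices, classified.

    ``struct`` and ``trans`` are square DataFrames indexed by drug id. When
    ATC annotation is given, shares_atc flags whether the two drugs' level-L
    code sets intersect (None if either drug is unannotated).
    """
    ids = sorted(set(struct.index) & set(trans.index))
    if len(ids) < 2:
        raise ValueError("fewer than two drugs shared by the two matrices")
    codes = None
    if atc is not None:
        codes = {d: {truncate_atc(c, atc_level) for c in atc[d]}
                 for d in ids if atc.get(d)}
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ds = float(struct.at[a, b])
            dt = float(trans.at[a, b])
            shares = None
            if codes is not None:
                if a in codes and b in codes:
                    shares = bool(codes[a] & codes[b])
            out.append(PairRecord(a, b, ds, dt,
                                  classify_quadrant(ds, dt, t_struct, t_trans), shares))
    return out


def quadrant_fractions(pairs: list[PairRecord]) -> dict[str, float]:
    """Fraction of pairs in each quadrant; fractions sum to 1."""
    if not pairs:
        raise ValueError("no pairs")
    counts = {q: 0 for q in QUADRANTS}
    for p in pairs:
        counts[p.quadrant] += 1
    total = len(pairs)
    return {q: counts[q] / total for q in QUADRANTS}


def ppv_curve(pairs: list[PairRecord], by: str = "d_trans") -> pd.DataFrame:
    """Cumulative PPV of ATC sharing down the ascending-distance ranking.

    Pairs where either drug lacks annotation (shares_atc is None) are
    dropped. Returns a DataFrame with columns rank, distance, ppv; PPV at
    full depth equals the base rate of ATC-sharing pairs.
    """
    annotated = [p for p in pairs if p.shares_atc is not None]
    if not annotated:
        raise ValueError("no annotated pairs")
    annotated.sort(key=lambda p: (getattr(p, by), p.drug_a, p.drug_b))
    tp = np.cumsum([p.shares_atc for p in annotated])
    ranks = np.arange(1, len(annotated) + 1)
    return pd.DataFrame({
        "rank": ranks,
        "distance": [getattr(p, by) for p in annotated],
        "ppv": tp / ranks,
    })


def _random_baseline(pairs: list[PairRecord], n_shuffles: int, seed: int) -> pd.DataFrame:
    """Mean cumulative PPV over seeded random orderings of the pairs."""
    annotated = [p for p in pairs if p.shares_atc is not None]
    flags = np.array([p.shares_atc for p in annotated], dtype=float)
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, len(flags) + 1)
    acc = np.zeros(len(flags))
    curves = np.empty((n_shuffles, len(flags)))
    for s in range(n_shuffles):
        perm = rng.permutation(len(flags))
        curves[s] = np.cumsum(flags[perm]) / ranks
    acc = curves.mean(axis=0)
    lo = np.quantile(curves, 0.025, axis=0)
    hi = np.quantile(curves, 0.975, axis=0)
    return pd.DataFrame({"rank": ranks, "ppv": acc, "ppv_lo": lo, "ppv_hi": hi})


def tv_split_benchmark(
    prls: dict[str, PRL | RankedList],
    tv_table: pd.DataFrame,
    atc: dict[str, set[str]],
    atc_level: int = 4,
    p: int | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """PPV of the transcriptional distance within low-TV and high-TV halves.

    The compendium is split at the median TV; within each half the pairwise
    transcriptional distance matrix is computed, pairs are ranked ascending,
    and the cumulative PPV of shared level-L ATC codes is traced, together
    with a mean-of-shuffles random baseline (95% band included). Returns
    {"low": ..., "high": ..., "random_low": ..., "random_high": ...}.
    """
    from chemtrans.tv import partition_by_tv

    drugs = [d for d in tv_table.index if d in prls]
    if len(drugs) != len(tv_table):
        missing = set(tv_table.index) - set(drugs)
        raise ValueError(f"TV table drugs without profiles: {sorted(missing)[:5]}")
    low, high = partition_by_tv(tv_table.loc[drugs])

    out: dict[str, pd.DataFrame] = {}
    for name, subset in (("low", low), ("high", high)):
        ids = sorted(subset)
        dm = pairwise_distance_matrix([prls[d] for d in ids], p)
        df = pd.DataFrame(dm, index=ids, columns=ids)
        records = pair_records(df, df, t_struct=1.0, t_trans=1.0,
                               atc=atc, atc_level=atc_level)
        out[name] = ppv_curve(records, by="d_trans")
        out[f"random_{name}"] = _random_baseline(records, n_shuffles, seed)
    return out


def shared_pathway_fraction(
    pairs: list[tuple[str, str]],
    targets: dict[str, set[str]],
    pathways: list,
) -> float:
    """Fraction of drug pairs whose molecular targets co-occur in a pathway.

    A pair counts when some pathway gene set contains at least one target of
    each drug. Pairs where either drug lacks target annotation are excluded
    from the denominator.
    """
    annotated = [(a, b) for a, b in pairs if targets.get(a) and targets.get(b)]
    if not annotated:
        raise ValueError("no pairs with annotated targets")
    sets = [frozenset(gs.genes) if hasattr(gs, "genes") else frozenset(gs) for gs in pathways]
    hits = 0
    for a, b in annotated:
        ta, tb = targets[a], targets[b]
        if any((ta & s) and (tb & s) for s in sets):
            hits += 1
    return hits / len(annotated)
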