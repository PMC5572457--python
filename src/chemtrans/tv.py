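"""Transcriptional Variability (TV): per-drug replicate concordance scoring
and TV-based partitioning of a drug compendium.

Given M >= 2 replicate transcriptional responses to a drug in one cell line,
TV is the median of the M(M-1)/2 pairwise transcriptional distances (for
M = 2, the single pairwise distance). TV near 0 means the drug induces a
consistent, reliable transcriptional response; TV at or above the
significance threshold (0.8 by default) marks a weak, uninformative one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chemtrans.gsea import SIMILARITY_THRESHOLD, pairwise_distance_matrix
from chemtrans.ranklists import RankedList


def count_within_pairs(m: int) -> int:
    """Number of within-drug replicate pairs, M(M-1)/2."""
    if m < 2:
        raise ValueError("TV requires at least two replicate profiles")
    return m * (m - 1) // 2


def tv_score(replicates: list[RankedList], p: int | None = None) -> float:
    """TV of one drug: median pairwise transcriptional distance of its replicates.

    For exactly two replicates this is the single pairwise distance (the
    median, maximum and mean all coincide).
    """
    m = len(replicates)
    if m < 2:
        raise ValueError("TV undefined: need at least two replicate profiles")
    dm = pairwise_distance_matrix(replicates, p)
    pairs = dm[np.triu_indices(m, k=1)]
    return float(np.median(pairs))


def tv_table(
    profiles: dict[str, list[RankedList]],
    p: int | None = None,
    cell_line: str | dict[str, str] = "MCF7",
    allow_mixed_cell_lines: bool = False,
) -> pd.DataFrame:
    """TV per drug over a compendium of replicate profiles.

    Parameters
    ----------
    profiles : dict drug_id -> list of RankedList
        Only drugs with >= 2 replicates appear in the output.
    cell_line : str or dict drug_id -> str
        Cell line annotation. TV values are not comparable across cell
        lines, so a per-drug map with more than one distinct line is
        rejected unless ``allow_mixed_cell_lines``.

    Returns
    -------
    DataFrame indexed by drug_id with columns tv, n_replicates, n_pairs,
    cell_line.
    """
    if isinstance(cell_line, dict):
        lines = set(cell_line.values())
        if len(lines) > 1 and not allow_mixed_cell_lines:
            raise ValueError(
                f"profiles span multiple cell lines {sorted(lines)}; "
                "TV values are not comparable across cell types "
                "(pass allow_mixed_cell_lines=True to override)"
            )
        line_of = cell_line
    else:
        line_of = {d: cell_line for d in profiles}

    rows = []
    for drug, reps in sorted(profiles.items()):
        m = len(reps)
        if m < 2:
            continue
        rows.append(
            {
                "drug_id": drug,
                "tv": tv_score(reps, p),
                "n_replicates": m,
                "n_pairs": count_within_pairs(m),
                "cell_line": line_of.get(drug, ""),
            }
        )
    if not rows:
        raise ValueError("no drug has >= 2 replicate profiles")
    return pd.DataFrame(rows).set_index("drug_id")


def partition_by_tv(
    table: pd.DataFrame,
    threshold_mode: str = "median",
    fixed_value: float = SIMILARITY_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Split drugs into (low_tv, high_tv) sets.

    ``median`` mode splits at the median TV into equal-size halves (up to
    ties; drugs exactly at the median go to the high/weak side). ``fixed``
    mode splits at ``fixed_value``; TV >= threshold is classed high/weak.
    """
    if table.empty:
        raise ValueError("empty TV table")
    tv = table["tv"]
    if threshold_mode == "median":
        thr = float(tv.median())
    elif threshold_mode == "fixed":
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    low = set(table.index[tv < thr])
    high = set(table.index[tv >= thr])
    return low, high
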