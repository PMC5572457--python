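"""Consensus toxicity-signature analysis.

A set of drugs known to share an off-target stress response (here:
lysosomotropic / phospholipidosis-inducing compounds) is merged into a
single consensus ranking ("signature node"). Ranking every other compound
in the compendium by its transcriptional distance to this node flags
signature-positive drugs — compounds likely to elicit the same stress
response. Because the response is concentration-dependent, profiles can be
split into LOW and HIGH concentration strata before comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from chemtrans.gsea import SIMILARITY_THRESHOLD, transcriptional_distance
from chemtrans.ranklists import PRL, RankedList, build_prl


@dataclass(frozen=True)
class ConsensusSignature:
    node: PRL
    members: tuple[str, ...]
    threshold: float = SIMILARITY_THRESHOLD


def build_consensus(member_prls: dict[str, PRL | RankedList],
                    threshold: float = SIMILARITY_THRESHOLD) -> ConsensusSignature:
    """Merge member drugs' consensus rankings into one signature node."""
    if not member_prls:
        raise ValueError("consensus requires at least one member")
    ids = sorted(member_prls)
    lists = [member_prls[d].merged if isinstance(member_prls[d], PRL) else member_prls[d]
             for d in ids]
    node = build_prl(lists, ids=ids)
    return ConsensusSignature(node=node, members=tuple(ids), threshold=threshold)


def rank_by_signature_distance(
    sig: ConsensusSignature,
    compendium: dict[str, PRL | RankedList],
    p: int | None = None,
) -> pd.DataFrame:
    """Distance of every non-member compound to the signature node.

    Returns a DataFrame sorted ascending by distance with columns drug_id,
    distance, positive (strictly below the significance threshold).
    Signature members accidentally included in the compendium are skipped
    with a warning.
    """
    members = set(sig.members)
    rows = []
    for drug, prof in sorted(compendium.items()):
        if drug in members:
            warnings.warn(f"signature member {drug!r} passed in compendium; excluded")
            continue
        lst = prof.merged if isinstance(prof, PRL) else prof
        d = transcriptional_distance(sig.node.merged, lst, p).value
        rows.append({"drug_id": drug, "distance": d, "positive": d < sig.threshold})
    if not rows:
        raise ValueError("compendium contains no non-member drugs")
    return (pd.DataFrame(rows)
            .sort_values(["distance", "drug_id"], kind="stable")
            .reset_index(drop=True))


def split_by_concentration(
    profiles: list[tuple[float, RankedList]],
    cutoff_uM: float = 1.0,
) -> tuple[PRL | None, PRL | None, bool]:
    """LOW/HIGH concentration consensus rankings for one drug.

    Profiles at concentrations < cutoff go to the LOW stratum, >= cutoff to
    HIGH; each stratum is merged into a PRL. If a stratum is empty the other
    is still returned and the final flag is False.

    Returns (low_prl, high_prl, both_strata_present).
    """
    if not profiles:
        raise ValueError("no profiles")
    low = [r for c, r in profiles if c < cutoff_uM]
    high = [r for c, r in profiles if c >= cutoff_uM]
    low_prl = build_prl(low) if low else None
    high_prl = build_prl(high) if high else None
    complete = bool(low and high)
    if not complete:
        warnings.warn("one concentration stratum is empty; returning the available one")
    return low_prl, high_prl, complete
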