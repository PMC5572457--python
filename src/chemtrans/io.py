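"""Readers and writers for the interchange formats plus pipeline configuration.

Formats: replicate profiles TSV (drug_id, replicate_id, concentration_uM,
gene_id, rank), ranked lists TSV (gene_id, rank), square matrices CSV with
id header row/column, gene sets GMT, ATC annotations TSV (drug_id,
atc_code; one row per code), descriptor matrices CSV, config YAML and run
manifests JSON. Gene identifiers are opaque strings; ranks are 1-based.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from chemtrans.gsea import GeneSet
from chemtrans.network import DistanceMatrix, DrugNetwork
from chemtrans.ranklists import RankedList
from chemtrans.synth import ProfileRecord


# ---------------------------------------------------------------- profiles

PROFILE_COLUMNS = ["drug_id", "replicate_id", "concentration_uM", "gene_id", "rank"]


def write_profiles(records: list[ProfileRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for rank, gene in enumerate(rec.ranking.genes, start=1):
            rows.append((rec.drug_id, rec.replicate_id, rec.concentration_uM, gene, rank))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[ProfileRecord]:
    """Parse and validate a profiles TSV into per-replicate ranked lists.

    Each replicate's ranks must be a bijection onto 1..n and every replicate
    must share the same gene universe; violations are rejected with the
    offending replicate named.
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "replicate_id": str,
                                            "gene_id": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profiles file lacks columns {missing}")
    dup = df.duplicated(subset=["replicate_id", "gene_id"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"duplicate (replicate, gene) entries at lines {lines}")
    records: list[ProfileRecord] = []
    universe: frozenset[str] | None = None
    for (drug, rep), grp in df.groupby(["drug_id", "replicate_id"], sort=True):
        try:
            ranking = RankedList.from_ranks(dict(zip(grp["gene_id"], grp["rank"])))
        except ValueError as e:
            raise ValueError(f"replicate {rep!r}: {e}") from e
        if universe is None:
            universe = ranking.universe
        elif ranking.universe != universe:
            raise ValueError(f"replicate {rep!r} has a different gene universe")
        conc = float(grp["concentration_uM"].iloc[0])
        records.append(ProfileRecord(str(drug), str(rep), conc, ranking))
    if not records:
        raise ValueError("no profiles found")
    return records


# ------------------------------------------------------------ ranked lists

def write_ranked_list(ranking: RankedList, path: str | Path) -> None:
    pd.DataFrame({"gene_id": ranking.genes,
                  "rank": range(1, ranking.n + 1)}).to_csv(path, sep="\t", index=False)


def read_ranked_list(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return RankedList.from_ranks(dict(zip(df["gene_id"], df["rank"])))


# ---------------------------------------------------------------- matrices

def write_matrix(dm: DistanceMatrix | pd.DataFrame, path: str | Path) -> None:
    df = dm.to_frame() if isinstance(dm, DistanceMatrix) else dm
    df.to_csv(path)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_frame(df)


def read_descriptors(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.columns.duplicated().any():
        raise ValueError("duplicate descriptor names")
    if df.isna().any().any():
        raise ValueError("descriptor matrix contains missing values")
    return df


# --------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: per line, set name, description, then member genes."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected >= 3 fields")
            name = parts[0]
            if name in names:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            names.add(name)
            sets.append(GeneSet(name, frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


# --------------------------------------------------------------------- ATC

def read_atc(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_id", "atc_code"} <= set(df.columns):
        raise ValueError("ATC file needs columns drug_id, atc_code")
    out: dict[str, set[str]] = {}
    for drug, code in zip(df["drug_id"], df["atc_code"]):
        out.setdefault(drug, set()).add(code)
    return out


def write_atc(atc: dict[str, set[str]], path: str | Path) -> None:
    rows = [(d, c) for d in sorted(atc) for c in sorted(atc[d])]
    pd.DataFrame(rows, columns=["drug_id", "atc_code"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- networks

def write_network(net: DrugNetwork, edges_path: str | Path,
                  nodes: pd.DataFrame | None = None,
                  nodes_path: str | Path | None = None) -> None:
    net.edges.to_csv(edges_path, sep="\t", index=False)
    if nodes is not None and nodes_path is not None:
        nodes.to_csv(nodes_path, sep="\t")


# ------------------------------------------------------------------ config

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; round-trips losslessly through YAML."""

    p_top_bottom: int | None = None
    density: float = 0.05
    tv_threshold: float = 0.8
    trans_threshold: float = 0.8
    struct_threshold: float | None = None  # None: use the density cutoff distance
    atc_level: int = 4
    permutations: int = 1000
    seed: int = 0
    concentration_cutoff_uM: float = 1.0
    min_community_size: int = 3
    simulation: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        for name in ("tv_threshold", "trans_threshold", "concentration_cutoff_uM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.struct_threshold is not None and self.struct_threshold <= 0:
            raise ValueError("struct_threshold must be positive")
        if not 1 <= self.atc_level <= 5:
            raise ValueError("atc_level must lie in 1..5")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
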