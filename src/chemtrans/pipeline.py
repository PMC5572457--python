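"""End-to-end orchestration of the structural/transcriptional drug analysis.

Stages: simulate (or ingest) -> per-drug consensus rankings (PRLs) ->
transcriptional variability -> distance matrices -> density-thresholded
networks -> communities and rich clubs -> ATC / descriptor / gene-set
enrichments -> coherence quadrants -> TV-split PPV benchmark -> consensus
signature analysis -> descriptor-based classifier. Any stage failure aborts
with the stage name; outputs are plain TSV/CSV/JSON tables plus a manifest.
"""

from __future__ import annotations

import platform
from pathlib import Path

import numpy as np
import pandas as pd

import chemtrans
from chemtrans import io as ctio
from chemtrans.coherence import pair_records, quadrant_fractions, tv_split_benchmark
from chemtrans.enrichment import atc_community_enrichment, descriptor_enrichment, dsea
from chemtrans.gsea import GeneSet, pairwise_distance_matrix
from chemtrans.network import (DistanceMatrix, build_rich_clubs, detect_communities,
                               giant_component, threshold_by_density)
from chemtrans.physchem import train_pld_classifier
from chemtrans.ranklists import build_prl
from chemtrans.signature import build_consensus, rank_by_signature_distance, split_by_concentration
from chemtrans.synth import SimulationConfig, SyntheticDataset, simulate
from chemtrans.tv import tv_table


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, manifest: dict):
    try:
        result = fn()
    except Exception as e:  # noqa: BLE001 - report stage and re-raise
        raise StageError(name, e) from e
    manifest["stages"].append(name)
    return result


def build_drug_prls(dataset: SyntheticDataset) -> dict:
    """Consensus ranking per drug from its replicate profiles."""
    by_drug = dataset.profiles_by_drug()
    return {d: build_prl(reps, ids=[f"{d}_rep{i}" for i in range(len(reps))])
            for d, reps in sorted(by_drug.items())}


def synthetic_gene_sets(dataset: SyntheticDataset, n_random: int = 20,
                        seed: int = 0) -> list[GeneSet]:
    """Planted lysosomotropic gene set plus size-matched random sets."""
    rng = np.random.default_rng([seed, 104729])  # decouple from the generator's stream
    genes = sorted(dataset.profiles[0].ranking.universe)
    size = len(dataset.pld_genes)
    sets = [GeneSet("planted_lysosomotropic", dataset.pld_genes)]
    for i in range(n_random):
        members = rng.choice(len(genes), size=size, replace=False)
        sets.append(GeneSet(f"random_set_{i:02d}", frozenset(genes[j] for j in members)))
    return sets


def run_pipeline(config: ctio.PipelineConfig, outdir: str | Path,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Execute every stage on a synthetic (or supplied) dataset.

    Returns a report bundle: a dict of in-memory results; all tables are
    also written under ``outdir`` together with a run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": chemtrans.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "density": config.density,
            "tv_threshold": config.tv_threshold,
            "trans_threshold": config.trans_threshold,
            "atc_level": config.atc_level,
            "p_top_bottom": config.p_top_bottom,
            "permutations": config.permutations,
        },
        "stages": [],
    }
    report: dict = {}

    def simulate_stage():
        if dataset is not None:
            return dataset
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        return simulate(sim_cfg)

    ds = _stage("simulate", simulate_stage, manifest)
    ctio.write_profiles(ds.profiles, outdir / "profiles.tsv")
    ds.descriptors.to_csv(outdir / "descriptors.csv")
    ctio.write_matrix(ds.structural, outdir / "structural_distances.csv")
    ctio.write_atc(ds.atc, outdir / "atc.tsv")
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t")

    prls = _stage("prl", lambda: build_drug_prls(ds), manifest)
    report["prls"] = prls

    tv = _stage("tv", lambda: tv_table(ds.profiles_by_drug(), p=config.p_top_bottom),
                manifest)
    tv.to_csv(outdir / "tv.tsv", sep="\t")
    report["tv"] = tv

    def trans_matrix_stage():
        ids = sorted(prls)
        m = pairwise_distance_matrix([prls[d] for d in ids], config.p_top_bottom)
        return pd.DataFrame(m, index=ids, columns=ids)

    trans_df = _stage("distance", trans_matrix_stage, manifest)
    trans_df.to_csv(outdir / "transcriptional_distances.csv")
    report["transcriptional_distances"] = trans_df

    def network_stage():
        struct_net = threshold_by_density(ds.structural, config.density)
        trans_net = threshold_by_density(
            DistanceMatrix(tuple(trans_df.index), trans_df.to_numpy()), config.density)
        return struct_net, trans_net

    struct_net, trans_net = _stage("network", network_stage, manifest)
    ctio.write_network(struct_net, outdir / "structural_network.tsv")
    ctio.write_network(trans_net, outdir / "transcriptional_network.tsv")
    report["structural_network"] = struct_net
    report["transcriptional_network"] = trans_net
    report["giant_component"] = giant_component(struct_net)

    def cluster_stage():
        comms = detect_communities(ds.structural, min_size=config.min_community_size,
                                   seed=config.seed)
        clubs = build_rich_clubs(comms, ds.structural, seed=config.seed)
        return comms, clubs

    communities, rich_clubs = _stage("cluster", cluster_stage, manifest)
    nodes = []
    club_of = {cid: rc.id for rc in rich_clubs for cid in rc.community_ids}
    for c in communities:
        for m in sorted(c.members):
            nodes.append({"drug_id": m, "community_id": c.id,
                          "is_exemplar": m == c.exemplar,
                          "rich_club_id": club_of[c.id]})
    pd.DataFrame(nodes).set_index("drug_id").to_csv(outdir / "node_attributes.tsv", sep="\t")
    report["communities"] = communities
    report["rich_clubs"] = rich_clubs

    atc_enr = _stage("enrich_atc",
                     lambda: atc_community_enrichment(communities, ds.atc,
                                                      level=config.atc_level),
                     manifest)
    atc_enr.to_csv(outdir / "atc_enrichment.tsv", sep="\t", index=False)
    report["atc_enrichment"] = atc_enr

    def descriptor_stage():
        frames = []
        drugs_of_comm = {c.id: c.members for c in communities}
        for rc in rich_clubs:
            members = set().union(*(drugs_of_comm[cid] for cid in rc.community_ids))
            if len(members) < 2 or len(members) >= len(ds.descriptors):
                continue
            df = descriptor_enrichment(ds.descriptors, members,
                                       permutations=config.permutations,
                                       seed=config.seed)
            df.insert(0, "rich_club_id", rc.id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    desc_enr = _stage("enrich_descriptors", descriptor_stage, manifest)
    desc_enr.to_csv(outdir / "descriptor_enrichment.tsv", sep="\t", index=False)
    report["descriptor_enrichment"] = desc_enr

    def quadrant_stage():
        t_struct = (config.struct_threshold if config.struct_threshold is not None
                    else struct_net.threshold_distance)
        records = pair_records(ds.structural.to_frame(), trans_df,
                               t_struct=t_struct, t_trans=config.trans_threshold,
                               atc=ds.atc, atc_level=config.atc_level)
        return records, quadrant_fractions(records), t_struct

    pairs, fractions, t_struct = _stage("quadrants", quadrant_stage, manifest)
    pd.Series(fractions).to_csv(outdir / "quadrant_fractions.tsv", sep="\t",
                                header=["fraction"])
    report["pair_records"] = pairs
    report["quadrant_fractions"] = fractions
    report["struct_threshold"] = t_struct

    ppv = _stage("ppv",
                 lambda: tv_split_benchmark(prls, tv, ds.atc, atc_level=config.atc_level,
                                            p=config.p_top_bottom, seed=config.seed),
                 manifest)
    for name, df in ppv.items():
        df.to_csv(outdir / f"ppv_{name}.tsv", sep="\t", index=False)
    report["ppv"] = ppv

    def signature_stage():
        pld_drugs = sorted(ds.truth.index[ds.truth["is_pld"]])
        if not pld_drugs:
            return None
        members = pld_drugs[: max(1, len(pld_drugs) // 2)]
        sig = build_consensus({d: prls[d] for d in members},
                              threshold=config.trans_threshold)
        ranking = rank_by_signature_distance(
            sig, {d: prls[d] for d in prls if d not in set(members)},
            p=config.p_top_bottom)
        conc = []
        for d in pld_drugs:
            low, high, ok = split_by_concentration(
                ds.concentration_profiles(d), cutoff_uM=config.concentration_cutoff_uM)
            if ok:
                from chemtrans.gsea import transcriptional_distance
                conc.append({
                    "drug_id": d,
                    "d_low": transcriptional_distance(sig.node.merged, low.merged,
                                                      config.p_top_bottom).value,
                    "d_high": transcriptional_distance(sig.node.merged, high.merged,
                                                       config.p_top_bottom).value,
                })
        return sig, ranking, pd.DataFrame(conc)

    sig_result = _stage("signature", signature_stage, manifest)
    if sig_result is not None:
        sig, sig_ranking, conc_df = sig_result
        sig_ranking.to_csv(outdir / "signature_distances.tsv", sep="\t", index=False)
        if not conc_df.empty:
            conc_df.to_csv(outdir / "signature_concentration.tsv", sep="\t", index=False)
        report["signature"] = sig
        report["signature_ranking"] = sig_ranking
        report["signature_concentration"] = conc_df

        def dsea_stage():
            members = [prls[d] for d in sig.members]
            return dsea(members, synthetic_gene_sets(ds, seed=config.seed),
                        permutations=config.permutations, seed=config.seed)

        dsea_res = _stage("dsea", dsea_stage, manifest)
        dsea_res.to_csv(outdir / "dsea.tsv", sep="\t", index=False)
        report["dsea"] = dsea_res

        def classify_stage():
            positives = set(sig_ranking.loc[sig_ranking["positive"], "drug_id"])
            positives |= set(sig.members)
            if not positives or positives >= set(ds.descriptors.index):
                return None
            return train_pld_classifier(ds.descriptors, positives, seed=config.seed)

        clf = _stage("classify", classify_stage, manifest)
        if clf is not None:
            clf.importances.to_csv(outdir / "classifier_importances.tsv", sep="\t",
                                   header=["importance"])
            manifest["oob_error"] = clf.oob_error
            report["classifier"] = clf

    ctio.write_manifest(manifest, outdir / "manifest.json")
    report["manifest"] = manifest
    return report
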