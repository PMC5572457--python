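"""Synthetic compendium generator with planted ground truth.

Emulates the statistical structure of a connectivity-map style dataset so
that every downstream stage has a parameter-recovery test:

* drug classes sharing a latent transcriptional prototype, with per-drug
  responsiveness rho controlling replicate concordance (rho = 1: replicates
  identical; rho = 0: replicates are independent random rankings);
* a planted lysosomotropic gene set pushed towards the top of the rankings
  of signature-carrying (PLD) drugs, with weight lambda; when concentration
  simulation is enabled, a fraction of replicates are LOW-concentration and
  do not receive the signature bump;
* descriptor matrices in which CAD-flagged drugs draw LogP and pKa from
  high-mean distributions, the rest being nuisance descriptors;
* class-correlated structural distances (within-class closer than
  between-class) and one level-4 ATC code per class.

Replicate rankings come from a Gaussian latent-score model: the score of
gene g in replicate r of drug d (class c) is

    rho_d * z_c[g] + (1 - rho_d) * eps_r[g] + lambda * 1{PLD, HIGH} * u[g]

ranked descending with ties broken by gene identifier. u is the indicator
of the planted gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from chemtrans.network import DistanceMatrix
from chemtrans.ranklists import RankedList

LOW_CONCENTRATION_UM = 0.1
HIGH_CONCENTRATION_UM = 10.0

CAD_LOGP_MEAN, CAD_PKA_MEAN = 4.5, 8.5
NONCAD_LOGP_MEAN, NONCAD_PKA_MEAN = 1.5, 6.5
DESCRIPTOR_SIGMA = 0.3
#: hydrophobicity-family descriptors correlated with the CAD label, emulating
#: the strongly inter-correlated lipophilicity blocks of 3D molecular
#: descriptor suites (one label-linked effect spreads over several columns)
CD_FAMILY = ("CD3", "CD4", "CD5", "CD6")
CD_CAD_MEAN, CD_SIGMA = 2.0, 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic compendium.

    ``responsiveness`` may be a single rho applied to every drug or a map
    drug_id -> rho; rho in [0, 1] scales how much of a replicate's latent
    score comes from the class prototype rather than fresh noise.
    """

    n_genes: int = 1000
    n_classes: int = 5
    drugs_per_class: int = 8
    replicates_per_drug: int = 4
    responsiveness: float | dict[str, float] = 0.8
    pld_fraction: float = 0.25
    pld_geneset_size: int = 50
    signature_weight: float = 2.0
    cad_fraction: float = 0.30
    n_descriptors: int = 128
    seed: int = 0
    simulate_concentrations: bool = False
    low_concentration_fraction: float = 0.25
    second_atc_fraction: float = 0.1
    within_class_distance: float = 0.3
    between_class_distance: float = 0.7
    structural_noise: float = 0.05

    def __post_init__(self):
        for name in ("n_genes", "n_classes", "drugs_per_class",
                     "replicates_per_drug", "pld_geneset_size", "n_descriptors"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_genes < 2 or self.n_classes < 1 or self.drugs_per_class < 1:
            raise ValueError("sizes must be positive")
        if self.replicates_per_drug < 2:
            raise ValueError("replicates_per_drug must be >= 2 (TV needs two profiles)")
        if not 0 <= self.pld_fraction <= 1 or not 0 <= self.cad_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.pld_geneset_size >= self.n_genes or self.pld_geneset_size < 1:
            raise ValueError("pld_geneset_size must lie in 1..n_genes-1")
        if self.signature_weight < 0:
            raise ValueError("signature_weight must be nonnegative")
        if self.n_descriptors < 2:
            raise ValueError("n_descriptors must be >= 2 to host LogP and pKa")
        rhos = (self.responsiveness.values()
                if isinstance(self.responsiveness, dict) else [self.responsiveness])
        if any(not 0 <= r <= 1 for r in rhos):
            raise ValueError("every responsiveness rho must lie in [0, 1]")

    @property
    def n_drugs(self) -> int:
        return self.n_classes * self.drugs_per_class

    def drug_ids(self) -> list[str]:
        return [f"drug_{i:04d}" for i in range(self.n_drugs)]

    def rho_of(self, drug: str) -> float:
        if isinstance(self.responsiveness, dict):
            return float(self.responsiveness[drug])
        return float(self.responsiveness)


@dataclass
class ProfileRecord:
    drug_id: str
    replicate_id: str
    concentration_uM: float
    ranking: RankedList


@dataclass
class SyntheticDataset:
    """Profiles, descriptors, structural distances, ATC codes + planted truth."""

    config: SimulationConfig
    profiles: list[ProfileRecord]
    descriptors: pd.DataFrame
    structural: DistanceMatrix
    atc: dict[str, set[str]]
    truth: pd.DataFrame  # index drug_id; columns class_label, rho, is_pld, is_cad
    pld_genes: frozenset[str] = field(default_factory=frozenset)

    def profiles_by_drug(self) -> dict[str, list[RankedList]]:
        out: dict[str, list[RankedList]] = {}
        for rec in self.profiles:
            out.setdefault(rec.drug_id, []).append(rec.ranking)
        return out

    def concentration_profiles(self, drug: str) -> list[tuple[float, RankedList]]:
        return [(rec.concentration_uM, rec.ranking)
                for rec in self.profiles if rec.drug_id == drug]


def _gene_universe(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _plant_truth(config: SimulationConfig) -> pd.DataFrame:
    drugs = config.drug_ids()
    classes = np.repeat(np.arange(config.n_classes), config.drugs_per_class)
    n = config.n_drugs
    n_pld = int(round(config.pld_fraction * n))
    n_cad = max(int(round(config.cad_fraction * n)), n_pld)
    # PLD drugs are spread across classes (structurally unrelated carriers):
    # round-robin over classes, then fill remaining CAD slots from non-PLD drugs
    rr = []
    for k in range(config.drugs_per_class):
        for c in range(config.n_classes):
            rr.append(c * config.drugs_per_class + k)
    pld_idx = set(rr[:n_pld])
    extra = [i for i in rr if i not in pld_idx]
    cad_idx = pld_idx | set(extra[: n_cad - n_pld])
    rows = []
    for i, d in enumerate(drugs):
        rows.append({
            "drug_id": d,
            "class_label": f"class_{classes[i]}",
            "rho": config.rho_of(d),
            "is_pld": i in pld_idx,
            "is_cad": i in cad_idx,
        })
    return pd.DataFrame(rows).set_index("drug_id")


def simulate_profiles(config: SimulationConfig) -> SyntheticDataset:
    """Generate replicate ranked lists plus planted truth (no descriptors yet).

    Deterministic given the config (seed included): identical configs yield
    bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config.n_genes)
    gene_arr = tuple(genes)
    truth = _plant_truth(config)
    pld_genes = frozenset(
        genes[i] for i in rng.choice(config.n_genes, size=config.pld_geneset_size,
                                     replace=False)
    )
    u = np.array([g in pld_genes for g in genes], dtype=float)
    prototypes = rng.standard_normal((config.n_classes, config.n_genes))

    profiles: list[ProfileRecord] = []
    for drug in config.drug_ids():
        row = truth.loc[drug]
        c = int(row["class_label"].split("_")[1])
        rho = float(row["rho"])
        n_low = (max(1, round(config.low_concentration_fraction
                              * config.replicates_per_drug))
                 if config.simulate_concentrations else 0)
        for r in range(config.replicates_per_drug):
            conc = LOW_CONCENTRATION_UM if r < n_low else HIGH_CONCENTRATION_UM
            eps = rng.standard_normal(config.n_genes)
            score = rho * prototypes[c] + (1 - rho) * eps
            if row["is_pld"] and conc >= 1.0:
                score = score + config.signature_weight * u
            ranking = RankedList.from_scores(gene_arr, score)
            profiles.append(ProfileRecord(drug, f"{drug}_rep{r}", conc, ranking))

    return SyntheticDataset(
        config=config,
        profiles=profiles,
        descriptors=pd.DataFrame(index=truth.index),
        structural=DistanceMatrix(tuple(truth.index),
                                  np.zeros((config.n_drugs, config.n_drugs))),
        atc={},
        truth=truth,
        pld_genes=pld_genes,
    )


def simulate_descriptors(config: SimulationConfig, truth: pd.DataFrame,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Descriptor matrix with CAD-shifted LogP / pKa and nuisance columns."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    is_cad = truth["is_cad"].to_numpy(dtype=bool)
    logp = np.where(is_cad,
                    rng.normal(CAD_LOGP_MEAN, DESCRIPTOR_SIGMA, n),
                    rng.normal(NONCAD_LOGP_MEAN, DESCRIPTOR_SIGMA, n))
    pka = np.where(is_cad,
                   rng.normal(CAD_PKA_MEAN, DESCRIPTOR_SIGMA, n),
                   rng.normal(NONCAD_PKA_MEAN, DESCRIPTOR_SIGMA, n))
    cols = {"LogP": logp, "pKa": pka}
    if config.n_descriptors >= 2 + len(CD_FAMILY) + 1:
        for name in CD_FAMILY:
            cols[name] = rng.normal(0.0, CD_SIGMA, n) + CD_CAD_MEAN * is_cad
    n_informative = len(cols)
    for j in range(config.n_descriptors - n_informative):
        cols[f"desc_{j + n_informative + 1:03d}"] = rng.standard_normal(n)
    return pd.DataFrame(cols, index=truth.index)


def simulate_structural_distances(config: SimulationConfig, truth: pd.DataFrame,
                                  rng: np.random.Generator | None = None) -> DistanceMatrix:
    """Class-correlated structural distance matrix in [0, 1]."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    labels = truth["class_label"].to_numpy()
    n = len(truth)
    same = labels[:, None] == labels[None, :]
    base = np.where(same, config.within_class_distance, config.between_class_distance)
    noise = rng.normal(0.0, config.structural_noise, (n, n)) if config.structural_noise > 0 else np.zeros((n, n))
    noise = np.triu(noise, 1)
    d = np.clip(base + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(truth.index), d)


def assign_atc(config: SimulationConfig, truth: pd.DataFrame,
               rng: np.random.Generator | None = None) -> dict[str, set[str]]:
    """One level-4 code per class; a fraction of drugs get a second code."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    class_code = {f"class_{c}": f"{chr(65 + c % 26)}{c + 1:02d}A{chr(65 + c % 26)}"
                  for c in range(config.n_classes)}
    atc: dict[str, set[str]] = {}
    drugs = list(truth.index)
    for i, d in enumerate(drugs):
        cls = truth.at[d, "class_label"]
        codes = {f"{class_code[cls]}{i % 100:02d}"}
        atc[d] = codes
    n_second = int(round(config.second_atc_fraction * len(drugs)))
    if n_second and config.n_classes > 1:
        chosen = rng.choice(len(drugs), size=n_second, replace=False)
        for i in chosen:
            d = drugs[i]
            own = truth.at[d, "class_label"]
            others = [c for c in class_code if c != own]
            other = others[int(rng.integers(len(others)))]
            atc[d].add(f"{class_code[other]}{(i + 50) % 100:02d}")
    return atc


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: profiles, descriptors, distances, ATC, truth."""
    ds = simulate_profiles(config)
    ds.descriptors = simulate_descriptors(config, ds.truth)
    ds.structural = simulate_structural_distances(config, ds.truth)
    ds.atc = assign_atc(config, ds.truth)
    return ds


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
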