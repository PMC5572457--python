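"""Synthetic compendium generator: determinism, planted structure, realism."""

import numpy as np
import pytest

from chemtrans.ranklists import footrule_distance
from chemtrans.synth import (CD_FAMILY, HIGH_CONCENTRATION_UM,
                             LOW_CONCENTRATION_UM, SimulationConfig, simulate,
                             simulate_profiles)


def _small(**kw):
    base = dict(n_genes=200, n_classes=3, drugs_per_class=4,
                replicates_per_drug=3, pld_geneset_size=20, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_drugs == 40
        assert len(cfg.drug_ids()) == 40

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            SimulationConfig(n_genes=10.5)
        with pytest.raises(ValueError, match="replicates"):
            SimulationConfig(replicates_per_drug=1)
        with pytest.raises(ValueError, match="rho"):
            SimulationConfig(responsiveness=1.5)
        with pytest.raises(ValueError, match="rho"):
            SimulationConfig(responsiveness={"drug_0000": -0.2})
        with pytest.raises(ValueError, match="pld_geneset_size"):
            SimulationConfig(n_genes=10, pld_geneset_size=10)
        with pytest.raises(ValueError, match="fraction"):
            SimulationConfig(pld_fraction=1.2)
        with pytest.raises(ValueError, match="signature_weight"):
            SimulationConfig(signature_weight=-1.0)


class TestDeterminism:
    def test_bit_identical_datasets(self):
        a = simulate(_small())
        b = simulate(_small())
        assert all(x.ranking.genes == y.ranking.genes
                   for x, y in zip(a.profiles, b.profiles))
        assert a.descriptors.equals(b.descriptors)
        assert np.array_equal(a.structural.values, b.structural.values)
        assert a.atc == b.atc
        assert a.pld_genes == b.pld_genes

    def test_seed_changes_output(self):
        a = simulate(_small(seed=0))
        b = simulate(_small(seed=1))
        assert a.profiles[0].ranking.genes != b.profiles[0].ranking.genes


class TestReplicateConcordance:
    def test_rho_one_identical_replicates(self):
        ds = simulate_profiles(_small(responsiveness=1.0, pld_fraction=0.0))
        for drug, reps in ds.profiles_by_drug().items():
            for r in reps[1:]:
                assert r.genes == reps[0].genes

    def test_rho_zero_matches_random_permutation_baseline(self):
        # expected footrule between two uniform random permutations is
        # (n^2 - 1) / 3; compare the generator against a Monte Carlo oracle
        n = 500
        ds = simulate_profiles(_small(n_genes=n, responsiveness=0.0,
                                      pld_fraction=0.0, pld_geneset_size=10))
        dists = []
        for reps in ds.profiles_by_drug().values():
            dists.append(footrule_distance(reps[0], reps[1]))
        rng = np.random.default_rng(0)
        mc = [int(np.abs(np.arange(n) - rng.permutation(n)).sum()) for _ in range(200)]
        expected = (n * n - 1) / 3
        assert np.mean(dists) == pytest.approx(expected, rel=0.05)
        assert np.mean(mc) == pytest.approx(expected, rel=0.05)

    def test_footrule_decreases_with_rho(self):
        means = []
        for rho in (0.0, 0.5, 0.9):
            ds = simulate_profiles(_small(responsiveness=rho, pld_fraction=0.0))
            d = [footrule_distance(reps[0], reps[1])
                 for reps in ds.profiles_by_drug().values()]
            means.append(np.mean(d))
        assert means[0] > means[1] > means[2]


class TestPlantedSignature:
    def test_pld_genes_pushed_up_for_pld_drugs(self):
        ds = simulate_profiles(_small(n_genes=500, pld_geneset_size=25))
        n = 500
        for rec in ds.profiles:
            ranks = rec.ranking.ranks()
            mean_rank = np.mean([ranks[g] for g in ds.pld_genes])
            if ds.truth.at[rec.drug_id, "is_pld"]:
                assert mean_rank < 0.3 * n
            else:
                assert abs(mean_rank - n / 2) < 0.2 * n

    def test_pld_subset_of_cad(self):
        ds = simulate(_small())
        t = ds.truth
        assert set(t.index[t["is_pld"]]) <= set(t.index[t["is_cad"]])

    def test_pld_spread_across_classes(self):
        ds = simulate(SimulationConfig(n_classes=4, drugs_per_class=4,
                                       pld_fraction=0.25, seed=0,
                                       n_genes=100, pld_geneset_size=10))
        pld_classes = ds.truth.loc[ds.truth["is_pld"], "class_label"]
        assert pld_classes.nunique() == 4  # one carrier per class


class TestConcentrations:
    def test_off_by_default_all_high(self):
        ds = simulate_profiles(_small())
        assert {rec.concentration_uM for rec in ds.profiles} == {HIGH_CONCENTRATION_UM}

    def test_low_fraction_of_replicates(self):
        cfg = _small(simulate_concentrations=True, replicates_per_drug=4,
                     low_concentration_fraction=0.25)
        ds = simulate_profiles(cfg)
        for drug, _ in ds.truth.iterrows():
            concs = [rec.concentration_uM for rec in ds.profiles
                     if rec.drug_id == drug]
            assert concs.count(LOW_CONCENTRATION_UM) == 1
            assert concs.count(HIGH_CONCENTRATION_UM) == 3

    def test_low_replicates_lack_signature_bump(self):
        cfg = _small(n_genes=500, pld_geneset_size=25, simulate_concentrations=True)
        ds = simulate_profiles(cfg)
        pld_drugs = set(ds.truth.index[ds.truth["is_pld"]])
        for rec in ds.profiles:
            if rec.drug_id not in pld_drugs:
                continue
            ranks = rec.ranking.ranks()
            mean_rank = np.mean([ranks[g] for g in ds.pld_genes])
            if rec.concentration_uM < 1.0:
                assert mean_rank > 0.3 * 500
            else:
                assert mean_rank < 0.3 * 500


class TestDescriptors:
    def test_shape_and_informative_columns(self):
        ds = simulate(_small())
        assert ds.descriptors.shape == (12, 128)
        for col in ("LogP", "pKa", *CD_FAMILY):
            assert col in ds.descriptors.columns

    def test_cad_tails(self):
        ds = simulate(SimulationConfig(seed=0))
        cad = ds.truth["is_cad"]
        assert ds.descriptors.loc[cad.values, "LogP"].min() > 3.0
        assert ds.descriptors.loc[~cad.values, "LogP"].max() < 3.0
        assert ds.descriptors.loc[cad.values, "pKa"].min() > 7.4


class TestStructuralAndATC:
    def test_structural_matrix_contract(self):
        ds = simulate(_small())
        v = ds.structural.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_noise_free_distances_exact(self):
        ds = simulate(_small(structural_noise=0.0))
        labels = ds.truth["class_label"].to_numpy()
        v = ds.structural.values
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert np.allclose(v[same & off], 0.3)
        assert np.allclose(v[~same], 0.7)

    def test_within_closer_than_between(self):
        ds = simulate(_small())
        labels = ds.truth["class_label"].to_numpy()
        v = ds.structural.values
        same = (labels[:, None] == labels[None, :]) & ~np.eye(len(labels), dtype=bool)
        assert v[same].mean() < v[~same & ~np.eye(len(labels), dtype=bool)].mean()

    def test_atc_one_code_per_drug_plus_seconds(self):
        cfg = _small(second_atc_fraction=0.25)
        ds = simulate(cfg)
        counts = sorted(len(c) for c in ds.atc.values())
        n_second = round(0.25 * cfg.n_drugs)
        assert counts.count(2) == n_second
        assert counts.count(1) == cfg.n_drugs - n_second

    def test_classmates_share_level4_code(self):
        from chemtrans.enrichment import truncate_atc
        ds = simulate(_small(second_atc_fraction=0.0))
        by_class = ds.truth.groupby("class_label").groups
        for drugs in by_class.values():
            prefixes = {truncate_atc(next(iter(ds.atc[d])), 4) for d in drugs}
            assert len(prefixes) == 1
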