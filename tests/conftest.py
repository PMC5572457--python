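"""Shared fixtures: small ranked lists and session-scoped synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from chemtrans.ranklists import RankedList
from chemtrans.synth import SimulationConfig, simulate


def random_ranked_list(rng: np.random.Generator, n: int) -> RankedList:
    genes = [f"g{i:03d}" for i in range(n)]
    perm = rng.permutation(n)
    return RankedList(tuple(genes[i] for i in perm))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_universe():
    return tuple(f"g{i:03d}" for i in range(10))


@pytest.fixture(scope="session")
def ds_default():
    """Default compendium: 5 MoA classes x 8 drugs, 4 replicates, rho = 0.8."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def ds_signature():
    """Signature-recovery compendium: 40 small classes x 2 drugs (20 PLD drugs)."""
    return simulate(SimulationConfig(n_classes=40, drugs_per_class=2, seed=0))


@pytest.fixture(scope="session")
def ds_concentration():
    """Same geometry with LOW/HIGH concentration strata simulated."""
    return simulate(SimulationConfig(n_classes=40, drugs_per_class=2,
                                     simulate_concentrations=True, seed=0))


@pytest.fixture(scope="session")
def ds_tv():
    """TV-recovery compendium: 40 responsive (rho=0.8) and 40 unresponsive drugs."""
    rhos = {f"drug_{i:04d}": (0.8 if i < 40 else 0.0) for i in range(80)}
    cfg = SimulationConfig(n_classes=5, drugs_per_class=16, responsiveness=rhos,
                           pld_fraction=0.0, cad_fraction=0.0, seed=0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def prls_signature(ds_signature):
    from chemtrans.pipeline import build_drug_prls
    return build_drug_prls(ds_signature)


@pytest.fixture(scope="session")
def prls_tv(ds_tv):
    from chemtrans.pipeline import build_drug_prls
    return build_drug_prls(ds_tv)


@pytest.fixture(scope="session")
def tv_table_tv(ds_tv):
    from chemtrans.tv import tv_table
    return tv_table(ds_tv.profiles_by_drug())
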