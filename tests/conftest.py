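"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

from gwaspathnet.config import SimulationConfig
from gwaspathnet.synthetic import simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A compact study with planted signal, shared by read-only tests."""
    cfg = SimulationConfig(
        n_cases=150, n_controls=150, n_genes=120, n_pathways=30,
        n_planted_pathways=3, network_nodes=160, pathway_min_size=10,
        pathway_max_size=40, rng_seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """A fully null study (odds ratio 1): no SNP is associated."""
    cfg = SimulationConfig(
        n_cases=150, n_controls=150, n_genes=150, n_pathways=40,
        n_planted_pathways=0, per_snp_odds_ratio=1.0, network_nodes=200,
        pathway_min_size=10, pathway_max_size=40, rng_seed=23)
    return simulate(cfg)


@pytest.fixture()
def toy_ranked():
    """4-gene ranked statistics with wr = (4, 3, 2, 1)."""
    return pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4"],
        "r": [4.0, 3.0, 2.0, 1.0],
        "w": [1.0, 1.0, 1.0, 1.0],
        "wr": [4.0, 3.0, 2.0, 1.0],
        "floored": [False] * 4,
    })
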