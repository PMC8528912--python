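"""Shared fixtures.

The expensive session fixtures (`default_sim`, `default_matrices`,
`default_clustering`) realize the package's reference study conditions —
the 12-genome, 3-genus x 2-species default simulation — and are computed
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from ogripan.ogri import compute_all_ogri
from ogripan.pangenome import all_vs_all_protein_hits, cluster_dataset
from ogripan.synthetic_clade import SimulationConfig, simulate_clade

SMALL_TREE = "((S1:0.005,S2:0.005):0.1,(S3:0.05,S4:0.05):0.1);"


@pytest.fixture(scope="session")
def small_sim():
    """Cheap 4-genome dataset for structural tests."""
    return simulate_clade(SimulationConfig(
        tree=SMALL_TREE, n_genes=30, gene_len_mean=120, rng_seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions: 12 genomes, 3 genera x 2 species."""
    return simulate_clade(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def default_matrices(default_sim):
    return compute_all_ogri(
        default_sim.data,
        indices=("ani", "aai", "ddh", "d2", "id16s", "tetra", "tzmd"),
    )


@pytest.fixture(scope="session")
def default_hits(default_sim):
    return all_vs_all_protein_hits(default_sim.data.proteomes)


@pytest.fixture(scope="session")
def default_clustering(default_sim, default_hits):
    pfs, profile = cluster_dataset(
        default_sim.data, default_sim.truth.lineage_map, _hits=default_hits)
    return pfs, profile


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
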