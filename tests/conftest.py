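"""Shared fixtures: small hand-built trees/matrices and simulation helpers."""

import numpy as np
import pytest

from ercnet.erc_core import ERCMatrix, erc_matrix
from ercnet.phylo_rates import (compute_average_vector,
                                normalize_relative_rates)
from ercnet.synthetic import (SimulationConfig, simulate_phylogeny,
                              simulate_rate_matrix)
from ercnet.topology import SpeciesTopology

#: 5-leaf reference tree; the two root-flanking edges jointly form one
#: unrooted branch, so lengths of 0.05 each give every canonical branch 0.1.
REF_NEWICK_5 = "((a,b),(c,(d,e)));"
REF_NEWICK_5_UNIFORM = ("((a:0.1,b:0.1):0.05,"
                        "(c:0.1,(d:0.1,e:0.1):0.1):0.05);")


@pytest.fixture(scope="session")
def topo5():
    return SpeciesTopology.from_newick(REF_NEWICK_5)


def build_erc(rho=0.0, n_genes=200, n_path=0, n_species=32, p_missing=0.2,
              seed=0, min_shared=10, **cfg_kwargs):
    """Simulate one dataset end to end in memory and return (ERCMatrix, truth)."""
    rng = np.random.default_rng(seed)
    pathways = (tuple(range(n_path)),) if n_path else ()
    rhos = (rho,) if n_path else ()
    phylo = simulate_phylogeny(n_species, rng=rng)
    cfg = SimulationConfig(n_species=n_species, n_genes=n_genes,
                           pathways=pathways, rho=rhos, p_missing=p_missing,
                           seed=0, **cfg_kwargs)
    matrix, truth = simulate_rate_matrix(phylo, cfg, rng=rng)
    avg = compute_average_vector(matrix)
    rel, _ = normalize_relative_rates(matrix, avg)
    return erc_matrix(rel, min_shared=min_shared), truth


def toy_erc(values, genes=None) -> ERCMatrix:
    """Hand-built symmetric ERC matrix; the upper triangle is authoritative."""
    values = np.asarray(values, dtype=float).copy()
    iu = np.tril_indices(values.shape[0], -1)
    values[iu] = values.T[iu]
    np.fill_diagonal(values, np.nan)
    g = values.shape[0]
    genes = tuple(genes) if genes else tuple(f"g{i}" for i in range(1, g + 1))
    counts = np.full((g, g), 60, dtype=np.int32)
    return ERCMatrix(genes=genes, values=values, counts=counts, meta={})


@pytest.fixture(scope="session")
def null_erc_500():
    """One rho=0 dataset at default generator conditions, reused across tests."""
    return build_erc(n_genes=500, seed=101)
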