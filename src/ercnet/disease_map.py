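"""Disease-disease network ("disease map") from between-group ERC.

Two diseases are linked when the mean ERC between their gene sets is
significantly elevated over pseudo-disease nulls: random gene-set pairs
size-matched to the two groups. Genes shared by both diseases are dropped
from both groups before forming cross pairs, so an edge can never be driven
by a gene's trivial correlation with itself. Edges are reported at a
q-value (FDR) threshold; clusters are the connected components of the
thresholded edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._sampling import null_cross_means
from .erc_core import ERCMatrix
from .errors import DegeneratePairError, InsufficientDataError
from .set_stats import (DEFAULT_MIN_GROUP, GeneGroup, PermutationP,
                        estimate_qvalues)

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_FDR = 0.05


@dataclass
class DiseaseEdge:
    """Between-disease ERC test result (shared genes excluded)."""

    disease_a: str
    disease_b: str
    n_genes_a: int
    n_genes_b: int
    n_cross_pairs: int
    mean_erc: float
    p: PermutationP
    q: float | None = None


def disease_pair_test(matrix: ERCMatrix, group_a: GeneGroup, group_b: GeneGroup,
                      n_perm: int = DEFAULT_N_PERM, seed=None,
                      rng: np.random.Generator | None = None) -> DiseaseEdge:
    """Permutation test of the mean cross-group ERC of two diseases.

    Shared genes are removed from BOTH groups. The null compares the
    observed mean to ``n_perm`` pseudo-disease pairs: random disjoint gene
    sets from the matrix universe sized like the post-drop groups; ties count
    for the null (>=).
    """
    if group_a.name == group_b.name:
        raise ValueError("a disease cannot be paired with itself")
    rng = rng if rng is not None else np.random.default_rng(seed)
    shared = set(group_a.genes) & set(group_b.genes)
    index = {g: i for i, g in enumerate(matrix.genes)}
    ia = [index[g] for g in group_a.genes if g not in shared and g in index]
    ib = [index[g] for g in group_b.genes if g not in shared and g in index]
    if not ia or not ib:
        raise DegeneratePairError(
            f"{group_a.name} / {group_b.name}: no unshared matrix-present "
            f"genes left ({len(shared)} shared)")
    cross = matrix.values[np.ix_(ia, ib)].ravel()
    cross = cross[np.isfinite(cross)]
    if cross.size == 0:
        raise InsufficientDataError(
            f"{group_a.name} / {group_b.name}: no defined cross pairs")
    observed = float(cross.mean())
    # sizes are sorted so that testing (A, B) and (B, A) consumes the random
    # stream identically: same seed => identical p either way round
    ka, kb = sorted((len(ia), len(ib)))
    null = null_cross_means(matrix.values, ka, kb, n_perm, rng)
    tally = int(np.count_nonzero(null >= observed))
    return DiseaseEdge(disease_a=group_a.name, disease_b=group_b.name,
                       n_genes_a=len(ia), n_genes_b=len(ib),
                       n_cross_pairs=int(cross.size), mean_erc=observed,
                       p=PermutationP(tally, n_perm))


@dataclass
class DiseaseMap:
    """FDR-thresholded disease network plus the full pair table."""

    nodes: list
    edges: list
    clusters: dict            # node -> connected-component id
    pair_table: pd.DataFrame  # every tested pair, significant or not
    skipped: list
    n_comparisons: int        # enumerated comparisons incl. self-pairings
    fdr_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))

    @property
    def summary(self) -> dict:
        pnum = self.pair_table["p_numeric"].to_numpy() if len(self.pair_table) else np.array([])
        return {
            "n_groups_compared": int((np.sqrt(8 * self.n_comparisons + 1) - 1) // 2),
            "n_comparisons": self.n_comparisons,
            "n_pairs_tested": len(self.pair_table),
            "n_p_below_5e-4": int((pnum <= 5e-4).sum()),
            "n_p_below_0.05": int((pnum <= 0.05).sum()),
            "n_edges": len(self.edges),
            "n_clusters": self.n_clusters,
            "fdr_threshold": self.fdr_threshold,
        }


def build_disease_map(matrix: ERCMatrix, groups, n_perm: int = DEFAULT_N_PERM,
                      fdr_threshold: float = DEFAULT_FDR, seed=None,
                      min_size: int = DEFAULT_MIN_GROUP,
                      qvalue_method: str = "storey") -> DiseaseMap:
    """Test every unordered pair of admissible disease groups.

    ``n_comparisons`` counts n(n+1)/2 enumerated comparisons (self-pairings
    included in the count only; they are never tested and never become
    edges). q-values are estimated over the full pair table and edges keep
    pairs with q <= ``fdr_threshold``; clusters are connected components.
    """
    admissible = []
    skipped = []
    for g in groups:
        k = len(matrix.gene_indices(g.genes))
        if k >= min_size:
            admissible.append(g)
        else:
            skipped.append((g.name, f"below minimum group size ({k} present)"))
    n = len(admissible)
    if n < 2:
        raise InsufficientDataError("need at least 2 admissible groups")
    n_comparisons = n * (n + 1) // 2

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    edges = []
    for (i, j), ss in zip(pairs, streams):
        try:
            edges.append(disease_pair_test(
                matrix, admissible[i], admissible[j], n_perm=n_perm,
                rng=np.random.default_rng(ss)))
        except (DegeneratePairError, InsufficientDataError) as exc:
            skipped.append((f"{admissible[i].name} / {admissible[j].name}",
                            str(exc)))
            log.info("skipping pair: %s", exc)
    if not edges:
        raise InsufficientDataError("no testable disease pairs")

    q, _eta0 = estimate_qvalues([e.p.fdr_value for e in edges],
                                method=qvalue_method)
    for e, qi in zip(edges, q):
        e.q = float(qi)
    edges.sort(key=lambda e: (e.p.fdr_value, -e.mean_erc, e.disease_a, e.disease_b))

    pair_table = pd.DataFrame([{
        "disease_a": e.disease_a, "disease_b": e.disease_b,
        "n_genes_a": e.n_genes_a, "n_genes_b": e.n_genes_b,
        "n_cross_pairs": e.n_cross_pairs, "mean_erc": e.mean_erc,
        "p": e.p.text, "p_numeric": e.p.fdr_value, "q": e.q,
    } for e in edges])

    significant = [e for e in edges if e.q <= fdr_threshold]
    graph = nx.Graph()
    for e in significant:
        graph.add_edge(e.disease_a, e.disease_b)
    components = sorted(nx.connected_components(graph),
                        key=lambda c: (-len(c), min(c)))
    clusters = {node: cid for cid, comp in enumerate(components)
                for node in sorted(comp)}
    return DiseaseMap(nodes=sorted(graph.nodes), edges=significant,
                      clusters=clusters, pair_table=pair_table,
                      skipped=skipped, n_comparisons=n_comparisons,
                      fdr_threshold=fdr_threshold)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_networkx(dmap: DiseaseMap) -> nx.Graph:
    graph = nx.Graph()
    for node in dmap.nodes:
        graph.add_node(node, cluster=int(dmap.clusters[node]))
    for e in dmap.edges:
        graph.add_edge(e.disease_a, e.disease_b, mean_erc=float(e.mean_erc),
                       p=float(e.p.fdr_value), q=float(e.q))
    return graph


def export_graph(dmap: DiseaseMap, path, fmt: str = "graphml") -> Path:
    """Write the disease map as GraphML or an edge-list TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_networkx(dmap), path)
    elif fmt == "tsv":
        pd.DataFrame([{
            "disease_a": e.disease_a, "disease_b": e.disease_b,
            "mean_erc": e.mean_erc, "p": e.p.text,
            "p_numeric": e.p.fdr_value, "q": e.q,
            "cluster": dmap.clusters[e.disease_a],
        } for e in dmap.edges]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
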