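"""Synthetic phylogenies and branch-length matrices with planted covariation.

The generator emulates the data a comparative-genomics pipeline would hand
to ERC: one branch-length vector per gene on a shared species tree, in which
genes of a common "pathway" carry correlated branch-specific rate
deviations.

Model: branch length of gene g on branch i is

    b[g, i] = t_i * mu_g * exp(sigma * d[g, i]),
    d[g, i] = sqrt(rho) * s[P(g), i] + sqrt(1 - rho) * e[g, i],

with t_i the branch time (log-normal), mu_g a per-gene rate multiplier
(log-normal), and s (one standard-normal factor per pathway per branch) and
e (per gene per branch) independent. The pairwise correlation of the
log-deviations d is exactly rho within a pathway and 0 across pathways, so
the planted covariation lives on branches — the axis ERC correlates over —
and the shared time component t_i is exactly what the projection
normalization removes in expectation. Multiplicative log-normal deviations
keep branch lengths positive.

Species are dropped per gene with a configurable probability to exercise the
presence masks; dropped species merge branches exactly as the loader's
pruning rules dictate, and written gene trees round-trip bit-exactly through
``phylo_rates.load_gene_trees``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ErcError
from .phylo_rates import BranchRateMatrix
from .set_stats import GeneGroup
from .topology import SpeciesTopology, _canonical

__all__ = [
    "SimulationConfig", "Phylogeny", "SimTruth", "simulate_phylogeny",
    "simulate_rate_matrix", "simulate_disease_groups",
    "make_benchmark_fixture", "BenchmarkBundle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic dataset.

    ``pathways`` are disjoint tuples of gene indices; ``rho`` gives each
    pathway's covariation strength in [0, 1). Defaults are sized like a small
    mammalian-scale study: ~60 branches (32 species), moderate rate
    dispersion (sigma 0.3), log-normal branch times with median 0.05
    substitutions/site, and a 0.2 per-species missingness rate per gene.
    """

    n_species: int = 32
    n_genes: int = 200
    pathways: tuple = ()
    rho: tuple = ()
    sigma: float = 0.3
    mu_meanlog: float = 0.0
    mu_sdlog: float = 0.4
    time_meanlog: float = math.log(0.05)
    time_sdlog: float = 0.6
    p_missing: float = 0.2
    min_kept_species: int = 4
    seed: int = 0
    # benchmark-bundle geometry
    n_groups: int = 10
    group_size: int = 5
    signal_fraction: float = 0.2
    decoys_per_window: int = 20
    window_bp: int = 1_000_000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        seen = set()
        for p in self.pathways:
            if seen & set(p):
                raise ValueError("a gene may belong to at most one pathway")
            seen |= set(p)
            if max(p, default=-1) >= self.n_genes:
                raise ValueError("pathway gene index out of range")
        if len(self.rho) != len(self.pathways):
            raise ValueError("one rho per pathway required")
        if any(not (0 <= r < 1) for r in self.rho):
            raise ValueError("rho must lie in [0, 1)")


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "name", "branch_idx")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []
        self.branch_idx = None  # canonical branch index; None for the
        #                         redundant second root-flank edge


def _leafset(node: _Node) -> frozenset:
    if node.name is not None:
        return frozenset([node.name])
    return frozenset().union(*(_leafset(c) for c in node.children))


@dataclass
class Phylogeny:
    """A simulated species tree: topology, branch times, writable structure."""

    topology: SpeciesTopology
    branch_times: np.ndarray  # aligned with topology.branch_ids
    root: _Node

    @property
    def newick(self) -> str:
        """Topology-only newick (no branch lengths)."""
        def render(node):
            if node.name is not None:
                return node.name
            return "(" + ",".join(render(c) for c in node.children) + ")"
        return render(self.root) + ";"


def simulate_phylogeny(n_species: int, seed=None,
                       rng: np.random.Generator | None = None,
                       time_meanlog: float = math.log(0.05),
                       time_sdlog: float = 0.6) -> Phylogeny:
    """Random rooted binary topology with log-normal branch times.

    Branch times are drawn once per canonical (unrooted) branch, so the two
    edges flanking the root jointly carry a single time.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nodes = [_Node(name=f"s{k:03d}") for k in range(1, n_species + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(children=[a, b]))
    root = nodes[0]

    taxa = _leafset(root)
    anchor = min(taxa)
    keys = {}

    def collect(node, is_root):
        below = _leafset(node)
        if not is_root and below != taxa:
            keys.setdefault(_canonical(below, taxa, anchor), None)
        for c in node.children:
            collect(c, False)

    collect(root, True)
    branch_ids = tuple(sorted(keys, key=lambda b: (len(b), b)))
    index = {b: i for i, b in enumerate(branch_ids)}

    assigned = set()

    def assign(node, is_root):
        if not is_root:
            below = _leafset(node)
            if below != taxa:
                key = _canonical(below, taxa, anchor)
                if key not in assigned:
                    node.branch_idx = index[key]
                    assigned.add(key)
        for c in node.children:
            assign(c, False)

    assign(root, True)

    topology = SpeciesTopology(species=tuple(sorted(taxa)),
                               branch_ids=branch_ids)
    times = rng.lognormal(mean=time_meanlog, sigma=time_sdlog,
                          size=len(branch_ids))
    return Phylogeny(topology=topology, branch_times=times, root=root)


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth behind a simulated rate matrix."""

    gene_ids: tuple
    pathway_of_gene: np.ndarray  # -1 for background genes
    mu: np.ndarray
    log_dev: np.ndarray          # the latent d[g, i] log-deviations
    b_full: np.ndarray           # lengths on every canonical branch, unmasked
    kept_species: tuple
    config: SimulationConfig
    phylogeny: Phylogeny

    def pathway_genes(self, p: int) -> list:
        return [g for g, lab in zip(self.gene_ids, self.pathway_of_gene)
                if lab == p]

    @property
    def background_genes(self) -> list:
        return [g for g, lab in zip(self.gene_ids, self.pathway_of_gene)
                if lab < 0]


def simulate_rate_matrix(phylo: Phylogeny, config: SimulationConfig,
                         rng: np.random.Generator | None = None):
    """Simulate the genes x branches matrix -> (BranchRateMatrix, SimTruth)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    topo = phylo.topology
    G, B, S = config.n_genes, topo.n_branches, topo.n_species

    pathway_of_gene = np.full(G, -1, dtype=int)
    for p, members in enumerate(config.pathways):
        pathway_of_gene[list(members)] = p

    mu = rng.lognormal(config.mu_meanlog, config.mu_sdlog, size=G)
    e = rng.standard_normal((G, B))
    d = e.copy()
    for p, members in enumerate(config.pathways):
        rho = config.rho[p]
        s = rng.standard_normal(B)
        idx = list(members)
        d[idx] = math.sqrt(rho) * s + math.sqrt(1.0 - rho) * e[idx]
    b_full = phylo.branch_times[None, :] * mu[:, None] * np.exp(config.sigma * d)

    species = list(topo.species)
    kept_species = []
    values = np.full((G, B), np.nan)
    min_keep = min(config.min_kept_species, S)
    for g in range(G):
        drop = rng.random(S) < config.p_missing
        if (S - drop.sum()) < min_keep:
            keep_idx = rng.choice(S, size=min_keep, replace=False)
            drop = np.ones(S, dtype=bool)
            drop[keep_idx] = False
        kept = frozenset(sp for sp, dr in zip(species, drop) if not dr)
        kept_species.append(kept)
        present = topo.present_branches(kept)
        values[g, present] = b_full[g, present]

    gene_ids = tuple(f"g{k:04d}" for k in range(1, G + 1))
    matrix = BranchRateMatrix(topology=topo, genes=gene_ids, values=values,
                              species_sets=tuple(kept_species))
    truth = SimTruth(gene_ids=gene_ids, pathway_of_gene=pathway_of_gene,
                     mu=mu, log_dev=d, b_full=b_full,
                     kept_species=tuple(kept_species),
                     config=config, phylogeny=phylo)
    return matrix, truth


# ---------------------------------------------------------------------------
# disease groups
# ---------------------------------------------------------------------------

def simulate_disease_groups(truth: SimTruth, n_groups: int, size: int,
                            signal_fraction: float, seed=None,
                            rng: np.random.Generator | None = None):
    """Random disease groups with ground-truth signal/null tags.

    Signal groups are drawn inside one pathway (pathways are cycled; members
    are dealt out without overlap while the pathway has capacity, wrapping
    with overlap only when exhausted); null groups are uniform draws from the
    whole gene universe.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_signal = int(round(signal_fraction * n_groups))
    if n_signal and not len(truth.config.pathways):
        raise ErcError("signal groups requested but no pathway was planted")
    pools = []
    for p in range(len(truth.config.pathways)):
        members = truth.pathway_genes(p)
        if n_signal and size > len(members):
            raise ErcError(f"group size {size} exceeds pathway size "
                           f"{len(members)}")
        pools.append(list(rng.permutation(members)))

    groups, labels = [], []
    cursor = [0] * max(len(pools), 1)
    for k in range(n_signal):
        p = k % len(pools)
        pool = pools[p]
        if cursor[p] + size <= len(pool):
            picked = pool[cursor[p]:cursor[p] + size]
            cursor[p] += size
        else:  # pathway exhausted: wrap with a fresh overlapping draw
            picked = [pool[i] for i in rng.choice(len(pool), size=size,
                                                  replace=False)]
        groups.append(GeneGroup(name=f"signal{k + 1:02d}",
                                genes=tuple(sorted(picked))))
        labels.append("signal")
    all_genes = list(truth.gene_ids)
    for k in range(n_groups - n_signal):
        picked = rng.choice(len(all_genes), size=size, replace=False)
        groups.append(GeneGroup(name=f"null{k + 1:02d}",
                                genes=tuple(sorted(all_genes[i] for i in picked))))
        labels.append("null")
    return groups, labels


# ---------------------------------------------------------------------------
# on-disk benchmark bundle
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _prune_render(node: _Node, keep: frozenset, b: np.ndarray):
    """Render a gene tree restricted to ``keep``, summing lengths over merged
    paths. Returns (newick fragment, canonical indices of the edge above)."""
    own = [node.branch_idx] if node.branch_idx is not None else []
    if node.name is not None:
        return (node.name, own) if node.name in keep else None
    survivors = [r for r in (_prune_render(c, keep, b) for c in node.children)
                 if r is not None]
    if not survivors:
        return None
    if len(survivors) == 1:
        frag, lst = survivors[0]
        return frag, lst + own
    parts = [f"{frag}:{_fmt(sum(b[i] for i in lst))}" for frag, lst in survivors]
    return "(" + ",".join(parts) + ")", own


def gene_tree_newick(phylo: Phylogeny, keep, b_row: np.ndarray) -> str:
    """Newick for one gene: the species tree pruned to ``keep``, with branch
    lengths taken from the gene's full canonical branch-length vector."""
    res = _prune_render(phylo.root, frozenset(keep), np.asarray(b_row))
    if res is None:
        raise ErcError("gene retains no species")
    frag, _ = res
    return frag + ";"


def make_annotation(gene_ids, targets, background, decoys_per_window: int,
                    window_bp: int) -> pd.DataFrame:
    """Synthetic gene coordinates: each target gene gets its own chromosome
    with ``decoys_per_window`` background genes placed inside its window;
    remaining genes land far apart on chr0."""
    need = decoys_per_window * len(targets)
    if need > len(background):
        raise ErcError(f"need {need} background genes for decoys, "
                       f"have {len(background)}")
    gene_len = 1000
    center = 10 * window_bp
    spacing = window_bp // (decoys_per_window + 2)
    rows = []
    pool = list(background)
    for t, target in enumerate(targets):
        rows.append((f"chr{t + 1}", center, center + gene_len, target))
        for k in range(decoys_per_window):
            side = 1 if k % 2 == 0 else -1
            offset = spacing * (k // 2 + 1) * side
            g = pool.pop(0)
            rows.append((f"chr{t + 1}", center + offset,
                         center + offset + gene_len, g))
    placed = {r[3] for r in rows}
    far = [g for g in gene_ids if g not in placed]
    for k, g in enumerate(far):
        pos = (k + 1) * 10 * window_bp
        rows.append(("chr0", pos, pos + gene_len, g))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    return df.set_index("gene")


@dataclass
class BenchmarkBundle:
    """Paths and in-memory truth for one on-disk synthetic benchmark."""

    out_dir: Path
    topology_path: Path
    tree_dir: Path
    groups_path: Path
    bed_path: Path
    truth_path: Path
    matrix: BranchRateMatrix
    truth: SimTruth
    groups: list
    labels: list
    annotation: pd.DataFrame


def make_benchmark_fixture(config: SimulationConfig, out_dir) -> BenchmarkBundle:
    """Write a complete synthetic input bundle: per-gene newick trees, the
    reference topology, GMT disease groups, a BED annotation and a truth
    record. The bundle is the input surface for end-to-end pipeline tests."""
    from .io import write_gmt  # local import to avoid a cycle

    out = Path(out_dir)
    tree_dir = out / "trees"
    tree_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    phylo = simulate_phylogeny(config.n_species, rng=rng,
                               time_meanlog=config.time_meanlog,
                               time_sdlog=config.time_sdlog)
    matrix, truth = simulate_rate_matrix(phylo, config, rng=rng)
    groups, labels = simulate_disease_groups(
        truth, config.n_groups, config.group_size, config.signal_fraction,
        rng=rng)

    topology_path = out / "topology.nwk"
    topology_path.write_text(phylo.newick + "\n")
    for g, gene in enumerate(truth.gene_ids):
        nwk = gene_tree_newick(phylo, truth.kept_species[g], truth.b_full[g])
        (tree_dir / f"{gene}.nwk").write_text(nwk + "\n")

    groups_path = out / "groups.gmt"
    write_gmt(groups, groups_path)

    targets = truth.pathway_genes(0) if len(config.pathways) else []
    annotation = make_annotation(truth.gene_ids, targets,
                                 truth.background_genes,
                                 config.decoys_per_window, config.window_bp)
    bed_path = out / "genes.bed"
    annotation.reset_index()[["chrom", "start", "end", "gene"]].to_csv(
        bed_path, sep="\t", header=False, index=False)

    truth_path = out / "truth.json"
    record = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "pathways": {str(p): truth.pathway_genes(p)
                     for p in range(len(config.pathways))},
        "group_labels": dict(zip((g.name for g in groups), labels)),
        "targets": targets,
    }
    record["config"]["pathways"] = [list(p) for p in config.pathways]
    truth_path.write_text(json.dumps(record, indent=1))

    return BenchmarkBundle(out_dir=out, topology_path=topology_path,
                           tree_dir=tree_dir, groups_path=groups_path,
                           bed_path=bed_path, truth_path=truth_path,
                           matrix=matrix, truth=truth, groups=groups,
                           labels=labels, annotation=annotation)
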