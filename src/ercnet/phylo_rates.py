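"""Branch-length matrices and projection normalization into relative rates.

A gene's evolutionary history is summarised as a vector of branch lengths
(amino-acid substitutions per site) over the canonical branches of the
reference species tree. Because all genes share the underlying species
divergence times, raw branch lengths are dominated by a common component.
The projection-operator normalization removes it: each gene's vector is
replaced by its residual after orthogonal projection onto the genome-average
branch-length vector, with inner products restricted to the branches the
gene actually has. What remains is the gene-specific rate deviation per
branch — the signal whose between-gene correlation is the ERC value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (EmptyResultError, FormatError, LabelError,
                     TopologyConflictError)
from .topology import (SpeciesTopology, branch_from_label, branch_label,
                       edge_bipartitions)

ORTHO_TOL = 1e-9


@dataclass
class BranchRateMatrix:
    """Genes x canonical branches matrix of branch lengths.

    ``values[g, i]`` is the branch length of gene ``g`` on branch ``i`` and is
    NaN where the branch is absent (species missing for that gene, or a
    pruned-path merge). ``species_sets[g]`` is the exact species set the gene
    covers — needed because a present species does not guarantee an intact
    pendant branch.
    """

    topology: SpeciesTopology
    genes: tuple
    values: np.ndarray
    species_sets: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), self.topology.n_branches):
            raise ValueError("matrix shape does not match genes x branches")
        if len(self.species_sets) != len(self.genes):
            raise ValueError("one species set required per gene")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise LabelError(f"gene {gene!r} not in matrix") from None


class RelativeRateMatrix(BranchRateMatrix):
    """Signed per-branch relative-rate deviations (projection residuals)."""


@dataclass
class AverageRateVector:
    """Per-branch mean branch length over contributing genes."""

    values: np.ndarray
    counts: np.ndarray

    @property
    def usable(self) -> np.ndarray:
        return self.counts > 0


def _gene_row(tree, topology: SpeciesTopology, source: str):
    bip = edge_bipartitions(tree, require_lengths=True, source=source)
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    alien = taxa - set(topology.species)
    if alien:
        raise LabelError(f"{source}: leaves not in reference species set: "
                         f"{sorted(alien)}")
    mapping = topology.restricted_mapping(taxa)
    row = np.full(topology.n_branches, np.nan)
    for key, length in bip.items():
        if key not in mapping:
            raise TopologyConflictError(
                f"{source}: split {key} conflicts with the reference topology")
        if not np.isfinite(length) or length < 0:
            raise FormatError(f"{source}: invalid branch length {length!r}")
        idxs = mapping[key]
        if len(idxs) == 1:  # merged paths carry no single-branch length
            row[idxs[0]] = length
    return row, taxa


def load_gene_trees(source, topology: SpeciesTopology) -> BranchRateMatrix:
    """Load one tree per gene and place branch lengths on canonical branches.

    ``source`` may be a directory of ``*.nwk``/``*.newick``/``*.tre`` files
    (filename stem = gene id), an iterable of file paths, or a single file
    holding several labelled trees (tree or root label = gene id). Output
    rows are sorted by gene id, so the matrix is bit-identical whatever the
    file order.
    """
    records: dict = {}

    def add(gene, tree, where):
        if gene in records:
            raise FormatError(f"{where}: duplicate gene id {gene!r}")
        records[gene] = _gene_row(tree, topology, where)

    src = Path(source) if isinstance(source, (str, Path)) else None
    if src is not None and src.is_dir():
        paths = sorted(p for p in src.iterdir()
                       if p.suffix in {".nwk", ".newick", ".tre", ".tree"})
        if not paths:
            raise EmptyResultError(f"no newick files in {src}")
    elif src is not None:
        paths = [src]
    else:
        paths = [Path(p) for p in source]

    for path in paths:
        try:
            trees = dendropy_tree_list(path)
        except FormatError:
            raise
        if len(trees) == 1:
            add(path.stem, trees[0], str(path))
        else:
            for k, tree in enumerate(trees):
                gene = tree.label or tree.seed_node.label
                if not gene:
                    raise FormatError(
                        f"{path}: tree #{k + 1} in a multi-tree file has no label")
                add(gene, tree, f"{path}#{gene}")

    genes = tuple(sorted(records))
    values = np.vstack([records[g][0] for g in genes])
    species_sets = tuple(records[g][1] for g in genes)
    return BranchRateMatrix(topology=topology, genes=genes, values=values,
                            species_sets=species_sets)


def dendropy_tree_list(path: Path):
    import dendropy

    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                      preserve_underscores=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse newick ({exc})") from exc
    if len(trees) == 0:
        raise FormatError(f"{path}: no trees found")
    return trees


def filter_min_species(matrix: BranchRateMatrix, min_species: int = 17):
    """Drop genes represented in fewer than ``min_species`` species.

    Returns ``(filtered_matrix, dropped)`` where ``dropped`` is a list of
    ``(gene, n_species)`` records for the removed genes.
    """
    if min_species < 2:
        raise ValueError("min_species must be >= 2")
    counts = np.array([len(s) for s in matrix.species_sets])
    keep = counts >= min_species
    dropped = [(g, int(c)) for g, c, k in zip(matrix.genes, counts, keep) if not k]
    if not keep.any():
        raise EmptyResultError(
            f"all {matrix.n_genes} genes fall below min_species={min_species}")
    out = BranchRateMatrix(
        topology=matrix.topology,
        genes=tuple(g for g, k in zip(matrix.genes, keep) if k),
        values=matrix.values[keep],
        species_sets=tuple(s for s, k in zip(matrix.species_sets, keep) if k),
    )
    return out, dropped


def transform_rates(matrix: BranchRateMatrix, kind: str = "none") -> BranchRateMatrix:
    """Optional variance-stabilising transform applied before normalization."""
    if kind == "none":
        return matrix
    if kind == "sqrt":
        values = np.sqrt(matrix.values)
    elif kind == "log1p":
        values = np.log1p(matrix.values)
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return BranchRateMatrix(topology=matrix.topology, genes=matrix.genes,
                            values=values, species_sets=matrix.species_sets)


def compute_average_vector(matrix: BranchRateMatrix) -> AverageRateVector:
    """Per-branch mean branch length over the genes that have the branch."""
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes to average")
    mask = matrix.mask
    counts = mask.sum(axis=0)
    sums = np.where(mask, matrix.values, 0.0).sum(axis=0)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AverageRateVector(values=values, counts=counts.astype(int))


def normalize_relative_rates(matrix: BranchRateMatrix, avg: AverageRateVector):
    """Project out the shared (genome-average) component of every gene.

    For gene ``g`` with present branches ``P``:
    ``r_g = b_g − (⟨b_g, a⟩_P / ⟨a, a⟩_P) · a`` so that ``⟨r_g, a⟩_P = 0``.

    Returns ``(RelativeRateMatrix, non_normalizable)`` where the second item
    lists genes whose present branches have no usable average entries (their
    rows are all-NaN in the output).
    """
    if avg.values.shape[0] != matrix.topology.n_branches:
        raise ValueError("average vector computed on a different branch system")
    a = np.where(avg.usable, avg.values, 0.0)
    work = matrix.mask & avg.usable[None, :]
    b = np.where(work, matrix.values, 0.0)
    num = (b * a[None, :]).sum(axis=1)
    den = (work * (a ** 2)[None, :]).sum(axis=1)
    ok = den > 0
    coef = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    resid = np.where(work, matrix.values - coef[:, None] * a[None, :], np.nan)
    resid[~ok] = np.nan
    non_normalizable = [g for g, good in zip(matrix.genes, ok) if not good]
    out = RelativeRateMatrix(topology=matrix.topology, genes=matrix.genes,
                             values=resid, species_sets=matrix.species_sets)
    return out, non_normalizable


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_rate_matrix(matrix: BranchRateMatrix, path, meta: dict | None = None):
    """Write a rate matrix as TSV: gene, species list, one column per branch.

    Branch columns are named by their canonical far-side leaf set joined with
    ``|``; empty cells mark absent branches. ``#``-prefixed header lines carry
    metadata.
    """
    path = Path(path)
    cols = [branch_label(b) for b in matrix.topology.branch_ids]
    df = pd.DataFrame(matrix.values, index=list(matrix.genes), columns=cols)
    df.insert(0, "species", [";".join(sorted(s)) for s in matrix.species_sets])
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index_label="gene", float_format="%.17g",
                  na_rep="")


def read_rate_matrix(path, topology: SpeciesTopology | None = None,
                     cls=BranchRateMatrix) -> BranchRateMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene",
                     float_precision="round_trip")
    species_sets = tuple(frozenset(s.split(";")) for s in df.pop("species"))
    branch_ids = tuple(branch_from_label(c) for c in df.columns)
    if topology is None:
        species = tuple(sorted(frozenset().union(*species_sets)))
        topology = SpeciesTopology(species=species, branch_ids=branch_ids)
    elif topology.branch_ids != branch_ids:
        raise FormatError(f"{path}: branch columns do not match the topology")
    return cls(topology=topology, genes=tuple(df.index), values=df.to_numpy(),
               species_sets=species_sets)
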