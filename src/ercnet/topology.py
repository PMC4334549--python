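"""Canonical branch coordinate system shared across per-gene trees.

Every branch of the (unrooted) reference species tree is identified by the
bipartition it induces on the full leaf set, canonicalised as the side that
does *not* contain the anchor species (the lexicographically smallest leaf
label). This makes branch identity independent of rooting and of the order
trees appear in input files.

Gene trees over a subset of the species map onto these canonical branches by
restriction: a reference branch whose bipartition, restricted to the gene's
species set, equals a gene-tree bipartition corresponds to that gene-tree
edge. When several reference branches collapse onto the same restricted
bipartition (a path created by pruning), the resulting gene-tree edge spans
multiple reference branches; its length is a sum of non-comparable pieces, so
it is treated as absent for that gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import dendropy

from .errors import FormatError, LabelError

#: A canonical branch identifier: sorted tuple of the leaf labels on the
#: far side of the branch (the side without the anchor species).
Branch = tuple


def _canonical(side: frozenset, taxa: frozenset, anchor: str) -> Branch:
    if anchor in side:
        side = taxa - side
    return tuple(sorted(side))


def parse_newick(source: str | Path, *, label: str = "") -> dendropy.Tree:
    """Parse a single newick tree from a file path or a literal string."""
    where = label or str(source)
    try:
        if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
            return dendropy.Tree.get(path=str(source), schema="newick",
                                     preserve_underscores=True)
        return dendropy.Tree.get(data=str(source), schema="newick",
                                 preserve_underscores=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # dendropy raises a zoo of parse errors
        raise FormatError(f"{where}: cannot parse newick ({exc})") from exc


def edge_bipartitions(tree: dendropy.Tree, *, require_lengths: bool,
                      source: str = "<tree>") -> dict[Branch, float]:
    """Map canonical bipartitions of ``tree`` to accumulated branch lengths.

    The tree is treated as unrooted: the two edges flanking a bifurcating
    root induce the same bipartition and their lengths add, which is exactly
    the length of the single unrooted branch they jointly represent.
    """
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError(f"{source}: unlabeled leaf")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        raise FormatError(f"{source}: duplicate leaf labels")
    taxa = frozenset(labels)
    if len(taxa) < 2:
        raise FormatError(f"{source}: fewer than two leaves")
    anchor = min(taxa)

    leafsets: dict = {}
    out: dict[Branch, float] = defaultdict(float)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(
                *(leafsets[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        below = leafsets[node]
        if below == taxa:
            continue
        length = node.edge.length
        if length is None:
            if require_lengths:
                raise FormatError(f"{source}: branch without a length")
            length = 0.0
        out[_canonical(below, taxa, anchor)] += float(length)
    return dict(out)


@dataclass(frozen=True)
class SpeciesTopology:
    """Reference species tree as an ordered set of canonical branches.

    ``branch_ids`` are ordered deterministically (by size, then
    lexicographically), so the branch coordinate system is identical no
    matter how or in what order the topology was read.
    """

    species: tuple
    branch_ids: tuple

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise FormatError("duplicate species labels in topology")
        if len(set(self.branch_ids)) != len(self.branch_ids):
            raise FormatError("duplicate branch identifiers in topology")

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, *, source: str = "<tree>") -> "SpeciesTopology":
        bip = edge_bipartitions(tree, require_lengths=False, source=source)
        species = tuple(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))
        branch_ids = tuple(sorted(bip, key=lambda b: (len(b), b)))
        return cls(species=species, branch_ids=branch_ids)

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTopology":
        return cls.from_tree(parse_newick(source), source=str(source))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_branches(self) -> int:
        return len(self.branch_ids)

    @cached_property
    def branch_index(self) -> dict:
        return {b: i for i, b in enumerate(self.branch_ids)}

    def restricted_mapping(self, subset) -> dict:
        """Map bipartitions of ``subset`` to the reference branches inducing them.

        Keys are canonical bipartitions of the restricted leaf set (far side
        relative to the subset's own anchor); values are lists of reference
        branch indices. A key with a single index identifies a branch that
        survives pruning intact; multiple indices mark a merged path.
        """
        subset = frozenset(subset)
        unknown = subset - set(self.species)
        if unknown:
            raise LabelError(
                f"species not in reference topology: {sorted(unknown)}")
        if len(subset) < 2:
            return {}
        anchor = min(subset)
        mapping: dict = defaultdict(list)
        for i, b in enumerate(self.branch_ids):
            inter = subset.intersection(b)
            if not inter or len(inter) == len(subset):
                continue
            if anchor in inter:
                key = tuple(sorted(subset.difference(b)))
            else:
                key = tuple(sorted(inter))
            mapping[key].append(i)
        return dict(mapping)

    def present_branches(self, subset) -> list:
        """Indices of reference branches with unambiguous data for a gene
        covering exactly ``subset`` of the species."""
        return sorted(idxs[0] for idxs in self.restricted_mapping(subset).values()
                      if len(idxs) == 1)


def branch_label(branch: Branch) -> str:
    """Human/TSV-facing name of a canonical branch."""
    return "|".join(branch)


def branch_from_label(label: str) -> Branch:
    return tuple(label.split("|"))
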