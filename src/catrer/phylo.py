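"""Rooted-tree data model, Newick I/O, pruning, and gene-tree/master alignment.

Branch identity convention: every branch is identified by its child node, and
internal nodes are identified by the set of tip labels below them (their
clade).  This makes branch bookkeeping robust to node-ordering differences
between Newick files that describe the same rooted topology.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "BranchIndex",
    "GeneTreeSet",
    "NewickError",
    "read_newick",
    "write_newick",
    "read_gene_trees",
    "prune_to_species",
    "map_gene_branches",
]


class NewickError(ValueError):
    """Malformed Newick input or violated tree invariant."""


@dataclass
class Phylogeny:
    """A rooted tree stored as parent/children arrays.

    Node ``i`` owns the branch connecting it to its parent; ``lengths[i]`` is
    that branch's length (``nan`` for the root, which has no branch).  Tips
    carry labels; internal nodes do not.
    """

    parent: np.ndarray          # int array, -1 at the root
    lengths: np.ndarray         # float array, nan at the root
    labels: dict[int, str]      # tip node -> label
    root: int
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i in range(n):
                p = int(self.parent[i])
                if p >= 0:
                    self.children[p].append(i)
        self._canonicalise()
        self.validate()

    # -- construction helpers -------------------------------------------------

    def _canonicalise(self) -> None:
        """Sort children by the smallest tip label in their subtree.

        Gives a deterministic traversal order for identical topologies
        regardless of the order nodes appeared in the input file.
        """
        key = {}
        for node in self._postorder_raw():
            if self.is_tip(node):
                key[node] = self.labels[node]
            else:
                key[node] = min(key[c] for c in self.children[node])
        for node in range(self.n_nodes):
            self.children[node].sort(key=lambda c: key[c])
        self._clades: dict[int, frozenset[str]] | None = None
        self._postorder: list[int] | None = None

    def _postorder_raw(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    # -- basic queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    @property
    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    @property
    def tip_labels(self) -> set[str]:
        return set(self.labels.values())

    def postorder(self) -> list[int]:
        """Canonical post-order traversal (children before parents)."""
        if self._postorder is None:
            self._postorder = self._postorder_raw()
        return self._postorder

    def clades(self) -> dict[int, frozenset[str]]:
        """Tip-label set below each node (the node's clade)."""
        if self._clades is None:
            out: dict[int, frozenset[str]] = {}
            for node in self.postorder():
                if self.is_tip(node):
                    out[node] = frozenset([self.labels[node]])
                else:
                    s: frozenset[str] = frozenset()
                    for c in self.children[node]:
                        s |= out[c]
                    out[node] = s
            self._clades = out
        return self._clades

    def total_length(self) -> float:
        return float(np.nansum(self.lengths))

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = np.zeros(self.n_nodes)
        best = 0.0
        for node in reversed(self.postorder()):
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.lengths[node]
            if self.is_tip(node):
                best = max(best, depth[node])
        return best

    def validate(self) -> None:
        n = self.n_nodes
        roots = [i for i in range(n) if self.parent[i] < 0]
        if roots != [self.root]:
            raise NewickError(f"tree must have exactly one root, found {roots}")
        tips = self.tips
        lab = [self.labels.get(t) for t in tips]
        if any(x is None for x in lab):
            raise NewickError("unlabeled tip")
        if len(set(lab)) != len(lab):
            dupes = sorted({x for x in lab if lab.count(x) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        nonroot = np.arange(n) != self.root
        if np.any(self.lengths[nonroot] < 0):
            raise NewickError("negative branch length")
        if np.any(np.isnan(self.lengths[nonroot])):
            raise NewickError("missing branch length on a non-root node")


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed parsing, own canonical writer)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.full(n, np.nan)
    labels: dict[int, str] = {}
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickError("branch length missing on a non-root edge")
            lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickError("unlabeled tip in Newick input")
            labels[i] = nd.taxon.label
    return Phylogeny(parent=parent, lengths=lengths, labels=labels, root=0)


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths.

    Internal labels and comments are ignored; the tree is used as rooted
    exactly as written (no re-rooting).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse error: {exc}") from exc
    tree = _from_dendropy(dtree)
    return tree


def write_newick(tree: Phylogeny, precision: int = 10) -> str:
    """Serialise with canonical child order and ``precision`` significant digits."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def rec(node: int) -> str:
        if tree.is_tip(node):
            core = tree.labels[node]
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[node]) + ")"
        if node == tree.root:
            return core
        return f"{core}:{fmt(float(tree.lengths[node]))}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Branch index
# ---------------------------------------------------------------------------

@dataclass
class BranchIndex:
    """Deterministic ordering of the master tree's branches.

    Branches are listed in canonical post-order and keyed by the child
    clade (tip-label set), so the index is stable across runs and across
    Newick files with shuffled node order.
    """

    clade_order: list[frozenset[str]]
    position: dict[frozenset[str], int]
    node_of: dict[frozenset[str], int]

    @classmethod
    def from_tree(cls, master: Phylogeny) -> "BranchIndex":
        clades = master.clades()
        order, pos, node_of = [], {}, {}
        for node in master.postorder():
            if node == master.root:
                continue
            c = clades[node]
            pos[c] = len(order)
            node_of[c] = node
            order.append(c)
        return cls(clade_order=order, position=pos, node_of=node_of)

    def __len__(self) -> int:
        return len(self.clade_order)

    def branch_ids(self) -> list[str]:
        """Human-readable branch identifiers (sorted tip labels joined by '|')."""
        return ["|".join(sorted(c)) for c in self.clade_order]


# ---------------------------------------------------------------------------
# Pruning and restriction
# ---------------------------------------------------------------------------

def prune_to_species(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict a tree to a subset of tips, summing lengths over collapsed paths."""
    keep = set(keep)
    unknown = keep - tree.tip_labels
    if unknown:
        raise NewickError(f"species not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise NewickError("pruning requires at least two species to keep")

    # new node records as (children, length, label)
    records: list[tuple[list[int], float, str | None]] = []

    def rec(node: int) -> int | None:
        length = float(tree.lengths[node]) if node != tree.root else np.nan
        if tree.is_tip(node):
            if tree.labels[node] not in keep:
                return None
            records.append(([], length, tree.labels[node]))
            return len(records) - 1
        kept = [k for k in (rec(c) for c in tree.children[node]) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # unary node: collapse, adding this branch's length to the child's
            child = kept[0]
            ch, clen, clab = records[child]
            records[child] = (ch, clen + length if not np.isnan(length) else clen, clab)
            return child
        records.append((kept, length, None))
        return len(records) - 1

    new_root = rec(tree.root)
    assert new_root is not None
    # if the old root collapsed into its single surviving child, that child is
    # the new root and its dangling branch length is dropped
    n = len(records)
    parent = np.full(n, -1, dtype=int)
    lengths = np.full(n, np.nan)
    labels: dict[int, str] = {}
    for i, (ch, length, lab) in enumerate(records):
        for c in ch:
            parent[c] = i
        if i != new_root:
            lengths[i] = length
        if lab is not None:
            labels[i] = lab
    return Phylogeny(parent=parent, lengths=lengths, labels=labels, root=new_root)


def same_topology(a: Phylogeny, b: Phylogeny) -> bool:
    """True when two rooted trees share tip set and clade structure."""
    if a.tip_labels != b.tip_labels:
        return False
    return set(a.clades().values()) == set(b.clades().values())


# ---------------------------------------------------------------------------
# Gene tree sets
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeSet:
    """Per-gene trees whose topology is the master restricted to present species."""

    trees: dict[str, Phylogeny]
    rejected: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees.items())


def validate_gene_tree(gene: Phylogeny, master: Phylogeny) -> str | None:
    """Return a rejection reason, or None when the gene tree is usable."""
    if len(gene.tips) < 3:
        return "fewer than 3 tips"
    extra = gene.tip_labels - master.tip_labels
    if extra:
        return f"tips not in master tree: {sorted(extra)}"
    restricted = prune_to_species(master, gene.tip_labels)
    if not same_topology(gene, restricted):
        return "topology conflicts with master restriction"
    return None


def read_gene_trees(stream: io.TextIOBase | str, master: Phylogeny) -> GeneTreeSet:
    """Read a ``gene_id<TAB>newick`` file, validating each tree against the master.

    Genes that fail validation are reported in ``rejected`` and skipped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    trees: dict[str, Phylogeny] = {}
    rejected: dict[str, str] = {}
    n_lines = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise NewickError(f"line {lineno}: expected 'gene_id<TAB>newick'")
        gene_id, newick = parts
        try:
            tree = read_newick(newick)
        except NewickError as exc:
            rejected[gene_id] = str(exc)
            continue
        reason = validate_gene_tree(tree, master)
        if reason is not None:
            rejected[gene_id] = reason
            continue
        trees[gene_id] = tree
    if n_lines == 0:
        raise NewickError("empty gene-tree file")
    return GeneTreeSet(trees=trees, rejected=rejected)


def write_gene_trees(genes: GeneTreeSet | Mapping[str, Phylogeny]) -> str:
    items = genes.trees.items() if isinstance(genes, GeneTreeSet) else genes.items()
    return "".join(f"{gid}\t{write_newick(t)}\n" for gid, t in items)


# ---------------------------------------------------------------------------
# Branch mapping
# ---------------------------------------------------------------------------

def map_gene_branches(
    gene: Phylogeny, master: Phylogeny, idx: BranchIndex
) -> np.ndarray:
    """Place a gene tree's branch lengths on the master branch index.

    Master branches absent from the gene tree (pruned away, or collapsed into
    a path) are ``nan``.  When pruning collapses a master path into a single
    gene branch, that branch's full length is attributed to the child-most
    master edge of the path, so the mapped vector conserves the gene tree's
    total length.
    """
    reason = validate_gene_tree(gene, master)
    if reason is not None:
        raise NewickError(f"gene tree not mappable: {reason}")
    gene_tips = gene.tip_labels
    # group master branches by their clade restricted to the gene's tips
    by_restriction: dict[frozenset[str], list[frozenset[str]]] = {}
    for clade in idx.clade_order:
        r = clade & gene_tips
        if r:
            by_restriction.setdefault(frozenset(r), []).append(clade)

    out = np.full(len(idx), np.nan)
    gclades = gene.clades()
    for node in gene.postorder():
        if node == gene.root:
            continue
        g = gclades[node]
        candidates = by_restriction.get(g)
        if not candidates:
            raise NewickError(f"gene branch {sorted(g)} has no master counterpart")
        # child-most edge on the collapsed path = smallest full clade
        target = min(candidates, key=len)
        out[idx.position[target]] = float(gene.lengths[node])
    return out
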