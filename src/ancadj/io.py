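"""Reading and writing trees, adjacencies and histories.

Formats
-------
* Species tree: Newick with labels on all nodes, plus a two-column TSV rank
  table (``node<TAB>rank``) giving the total order of internal nodes (root
  rank 0).  Only the order matters, not branch lengths.
* Reconciled gene trees: Newick with NHX-style bracket tags on every node:
  ``S=`` (species branch, or ``OUT`` for unsampled lineages), ``Ev=`` (one of
  ``Extant|Spec|SpecOut|Trans|Dup|Loss|NoEvent``) and ``ts=`` (time slice).
  An optional ``Fam=`` tag on the root names the family.
* Extant adjacencies: two tab-separated gene identifiers per line, ``#``
  comments allowed.
* Histories: three TSVs (adjacencies, events, summary) with sorted rows so
  output is byte-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy

from .model import (
    EVENTS, OUTSIDE, SPECIATION, SPECIATION_OUT,
    AdjacencyRecord, DatedSpeciesTree, EventRecord, GeneNode, History,
    ReconciledGeneTree, SpeciesNode, ValidationError, canonical_adjacency,
)

__all__ = [
    "InputBundle",
    "read_species_tree", "write_species_tree",
    "parse_gene_tree", "read_gene_trees", "write_gene_trees",
    "read_adjacencies", "write_adjacencies",
    "prune_outside_diversification", "normalize_gene_tree",
    "write_history", "read_history_tables",
    "read_bundle", "write_bundle",
]


@dataclass
class InputBundle:
    """Everything the reconstruction needs: a dated species tree, reconciled
    gene trees and the extant adjacencies."""

    species_tree: DatedSpeciesTree
    gene_trees: list[ReconciledGeneTree]
    adjacencies: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def _node_label(nd: dendropy.Node) -> str | None:
    if nd.taxon is not None:
        return nd.taxon.label
    return nd.label


def read_species_tree(newick_text: str, rank_table: str) -> DatedSpeciesTree:
    """Parse a rooted binary species tree and its internal-node rank table."""
    ranks: dict[str, int] = {}
    for lineno, line in enumerate(rank_table.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"rank table line {lineno}: expected 2 columns")
        name, rank = parts
        if name in ranks:
            raise ValidationError(f"rank table line {lineno}: duplicate node {name!r}")
        try:
            ranks[name] = int(rank)
        except ValueError:
            raise ValidationError(
                f"rank table line {lineno}: non-integer rank {rank!r}"
            ) from None

    dtree = _parse_newick(newick_text)
    seen_ranked: set[str] = set()

    def build(nd: dendropy.Node) -> SpeciesNode:
        label = _node_label(nd)
        if label is None:
            raise ValidationError("species tree has an unlabeled node")
        children = nd.child_nodes()
        if children and len(children) != 2:
            raise ValidationError(
                f"species node {label!r} is not binary ({len(children)} children)"
            )
        if children:
            if label not in ranks:
                raise ValidationError(f"internal node {label!r} missing from rank table")
            node = SpeciesNode(label, rank=ranks[label])
            seen_ranked.add(label)
        else:
            node = SpeciesNode(label)
        for ch in children:
            child = build(ch)
            child.parent = node
            node.children.append(child)
        return node

    root = build(dtree.seed_node)
    unused = set(ranks) - seen_ranked
    if unused:
        raise ValidationError(f"rank table names unknown nodes: {sorted(unused)}")
    return DatedSpeciesTree(root)


def write_species_tree(tree: DatedSpeciesTree) -> tuple[str, str]:
    """Serialize to (newick text, rank table text)."""

    def nwk(node: SpeciesNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(nwk(c) for c in node.children)
        return f"({inner}){node.name}"

    ranks = "\n".join(
        f"{n.name}\t{n.rank}"
        for n in sorted(tree.nodes.values(), key=lambda n: (n.rank is None, n.rank or 0))
        if not n.is_leaf
    )
    return nwk(tree.root) + ";", ranks + "\n"


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def parse_gene_tree(text: str, family: str) -> ReconciledGeneTree:
    """Parse an annotated Newick gene tree without structural validation.

    Tag order within the NHX block is free.  Unlabeled internal nodes get
    auto-generated identifiers.
    """
    dtree = _parse_newick(text)
    counter = 0

    def get(nd: dendropy.Node, key: str) -> str | None:
        v = nd.annotations.get_value(key)
        return None if v is None else str(v)

    fam = get(dtree.seed_node, "Fam") or family

    def build(nd: dendropy.Node) -> GeneNode:
        nonlocal counter
        label = _node_label(nd)
        if label is None:
            counter += 1
            label = f"{fam}.n{counter}"
        species = get(nd, "S")
        event = get(nd, "Ev")
        ts = get(nd, "ts")
        if species is None or event is None or ts is None:
            raise ValidationError(
                f"family {fam!r}, node {label!r}: missing S=/Ev=/ts= annotation"
            )
        if event not in EVENTS:
            raise ValidationError(
                f"family {fam!r}, node {label!r}: unknown event {event!r}"
            )
        try:
            slice_ = int(ts)
        except ValueError:
            raise ValidationError(
                f"family {fam!r}, node {label!r}: non-integer ts={ts!r}"
            ) from None
        node = GeneNode(label, event, species, slice_)
        for ch in nd.child_nodes():
            node.add_child(build(ch))
        return node

    return ReconciledGeneTree(build(dtree.seed_node), fam)


def _subtree_returns_inside(node: GeneNode) -> bool:
    return any(n.species != OUTSIDE for n in node.iter_subtree())


def normalize_gene_tree(tree: ReconciledGeneTree) -> ReconciledGeneTree:
    """Canonicalize outside-lineage bookkeeping, in place.

    Unary nodes outside the species tree are spliced out, so that a
    ``SpeciationOut``'s outgoing child is its ``Transfer`` re-entry directly;
    a ``SpeciationOut`` whose outgoing lineage never returns (dies outside)
    is itself spliced, leaving only the inside continuation.
    """
    changed = True
    while changed:
        changed = False
        for node in list(tree.iter_nodes()):
            if node.species == OUTSIDE and len(node.children) == 1:
                (child,) = node.children
                parent = node.parent
                if parent is None:
                    tree.root = child
                    child.parent = None
                else:
                    parent.children[parent.children.index(node)] = child
                    child.parent = parent
                node.children, node.parent = [], None
                changed = True
        for node in list(tree.iter_nodes()):
            if node.event != SPECIATION_OUT:
                continue
            away = [c for c in node.children if c.species != node.species]
            if len(away) == 1 and not _subtree_returns_inside(away[0]):
                inside = [c for c in node.children if c.species == node.species]
                if len(inside) != 1:
                    continue
                parent = node.parent
                keep = inside[0]
                if parent is None:
                    tree.root = keep
                    keep.parent = None
                else:
                    parent.children[parent.children.index(node)] = keep
                    keep.parent = parent
                node.children, node.parent = [], None
                changed = True
    return tree


def prune_outside_diversification(
    tree: ReconciledGeneTree,
) -> list[ReconciledGeneTree]:
    """Remove nodes that diversify outside the species tree, cutting the tree
    into independent pieces.

    A node diversifies outside when it is binary and mapped outside the
    species tree (``S=OUT``).  Each maximal remaining connected component
    containing at least one inside-tree node is returned as an independent
    tree (its root becoming a new origination); components living entirely
    outside are dropped.
    """
    bad = [
        n for n in tree.iter_nodes()
        if n.species == OUTSIDE and len(n.children) == 2
    ]
    if not bad:
        return [normalize_gene_tree(tree)]

    fragments: list[GeneNode] = [tree.root]
    bad_set = set(id(n) for n in bad)
    for node in bad:
        for child in list(node.children):
            child.detach()
            fragments.append(child)
        node.detach()

    pieces: list[ReconciledGeneTree] = []
    for i, frag in enumerate(fragments):
        if id(frag) in bad_set:
            continue
        # drop leading outside chain down to the first node that can root a
        # piece; unary OUT chains are handled by normalization below
        root = frag
        while root is not None and root.species == OUTSIDE:
            kids = [c for c in root.children if _subtree_returns_inside(c)]
            if len(kids) != 1:
                root = None
                break
            root = kids[0]
            root.detach()
        if root is None or not _subtree_returns_inside(root):
            continue
        root = _cleanup_arity(root)
        if root is None:
            continue
        piece = ReconciledGeneTree(root, f"{tree.family}.p{len(pieces) + 1}")
        normalize_gene_tree(piece)
        pieces.append(piece)
    return pieces


def _cleanup_arity(root: GeneNode) -> GeneNode | None:
    """Splice binary-event nodes left with one child after a removal."""
    changed = True
    while changed:
        changed = False
        for node in list(root.iter_subtree()):
            if node.event in (SPECIATION, SPECIATION_OUT) and len(node.children) == 1:
                (child,) = node.children
                parent = node.parent
                if parent is None:
                    root = child
                    child.parent = None
                else:
                    parent.children[parent.children.index(node)] = child
                    child.parent = parent
                node.children, node.parent = [], None
                changed = True
    return root


def read_gene_trees(
    newick_nhx_texts: list[str],
    species_tree: DatedSpeciesTree,
    prune: bool = False,
) -> list[ReconciledGeneTree]:
    """Parse, normalize and validate reconciled gene trees.

    With ``prune=True``, nodes diversifying outside the species tree are
    removed first (splitting trees into pieces); otherwise such nodes are a
    validation error.
    """
    trees: list[ReconciledGeneTree] = []
    for i, text in enumerate(newick_nhx_texts, start=1):
        tree = parse_gene_tree(text, family=f"F{i}")
        if prune:
            trees.extend(prune_outside_diversification(tree))
        else:
            trees.append(normalize_gene_tree(tree))
    for tree in trees:
        tree.validate(species_tree)
    return trees


def write_gene_trees(trees: list[ReconciledGeneTree]) -> str:
    """Serialize gene trees, one annotated Newick per line."""

    def nwk(node: GeneNode, is_root: bool, fam: str) -> str:
        tags = f"S={node.species}:Ev={node.event}:ts={node.slice_}"
        if is_root:
            tags += f":Fam={fam}"
        ann = f"[&&NHX:{tags}]"
        if node.is_leaf:
            return node.name + ann
        inner = ",".join(nwk(c, False, fam) for c in node.children)
        return f"({inner}){node.name}{ann}"

    return "".join(nwk(t.root, True, t.family) + ";\n" for t in trees)


# ---------------------------------------------------------------------------
# adjacencies
# ---------------------------------------------------------------------------

def build_gene_index(trees: list[ReconciledGeneTree]) -> dict[str, GeneNode]:
    """Map extant gene identifiers to their leaf nodes."""
    index: dict[str, GeneNode] = {}
    for tree in trees:
        for leaf in tree.extant_leaves():
            if leaf.name in index:
                raise ValidationError(f"gene identifier {leaf.name!r} is not unique")
            index[leaf.name] = leaf
    return index


def read_adjacencies(
    tsv_text: str, gene_trees: list[ReconciledGeneTree]
) -> list[tuple[str, str]]:
    """Read, canonicalize and deduplicate the extant adjacency table."""
    index = build_gene_index(gene_trees)
    out: dict[tuple[str, str], None] = {}
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"adjacency line {lineno}: expected 2 columns")
        g1, g2 = parts
        for g in (g1, g2):
            if g not in index:
                raise ValidationError(f"adjacency line {lineno}: unknown gene {g!r}")
        if index[g1].species != index[g2].species:
            raise ValidationError(
                f"adjacency line {lineno}: genes {g1!r} ({index[g1].species}) and "
                f"{g2!r} ({index[g2].species}) are in different species"
            )
        out[canonical_adjacency(g1, g2)] = None
    return list(out)


def write_adjacencies(adjacencies: list[tuple[str, str]]) -> str:
    return "".join(f"{a}\t{b}\n" for a, b in sorted(adjacencies))


# ---------------------------------------------------------------------------
# histories
# ---------------------------------------------------------------------------

_ADJ_HEADER = "species\tslice\tgene1\tgene2\tin_genome"
_EVT_HEADER = "kind\tspecies\tslice\tgene1\tgene2"


def write_history(history: History, path: str) -> None:
    """Write a history as three TSV files under directory ``path``:
    ``adjacencies.tsv``, ``events.tsv`` and ``summary.tsv``.  Rows are
    sorted, so the output is byte-reproducible."""
    os.makedirs(path, exist_ok=True)
    adj_rows = sorted(
        (r.species, r.slice_, r.gene1, r.gene2, int(r.in_genome))
        for r in history.adjacencies
    )
    with open(os.path.join(path, "adjacencies.tsv"), "w") as fh:
        fh.write(_ADJ_HEADER + "\n")
        for row in adj_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    evt_rows = sorted(
        (e.kind, e.species, e.slice_, e.gene1, e.gene2)
        for e in history.gains + history.breaks
    )
    with open(os.path.join(path, "events.tsv"), "w") as fh:
        fh.write(_EVT_HEADER + "\n")
        for row in evt_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(os.path.join(path, "summary.tsv"), "w") as fh:
        fh.write(f"total_cost\t{history.total_cost:g}\n")
        fh.write(f"n_gains\t{len(history.gains)}\n")
        fh.write(f"n_breaks\t{len(history.breaks)}\n")
        fh.write(f"n_adjacencies\t{len(history.adjacencies)}\n")


def read_history_tables(
    path: str,
) -> tuple[list[AdjacencyRecord], list[EventRecord]]:
    """Read back the adjacency and event tables written by
    :func:`write_history` (round-trip helper)."""
    adjacencies = []
    with open(os.path.join(path, "adjacencies.tsv")) as fh:
        header = fh.readline().strip()
        if header != _ADJ_HEADER:
            raise ValidationError(f"unexpected adjacency header {header!r}")
        for line in fh:
            sp, ts, g1, g2, ig = line.rstrip("\n").split("\t")
            adjacencies.append(AdjacencyRecord(sp, int(ts), g1, g2, bool(int(ig))))
    events = []
    with open(os.path.join(path, "events.tsv")) as fh:
        header = fh.readline().strip()
        if header != _EVT_HEADER:
            raise ValidationError(f"unexpected event header {header!r}")
        for line in fh:
            kind, sp, ts, g1, g2 = line.rstrip("\n").split("\t")
            events.append(EventRecord(kind, sp, int(ts), g1, g2))
    return adjacencies, events


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def write_bundle(bundle: InputBundle, path: str) -> None:
    """Write a full input bundle under directory ``path``."""
    os.makedirs(path, exist_ok=True)
    newick, ranks = write_species_tree(bundle.species_tree)
    with open(os.path.join(path, "species.nwk"), "w") as fh:
        fh.write(newick + "\n")
    with open(os.path.join(path, "ranks.tsv"), "w") as fh:
        fh.write(ranks)
    with open(os.path.join(path, "gene_trees.nwk"), "w") as fh:
        fh.write(write_gene_trees(bundle.gene_trees))
    with open(os.path.join(path, "adjacencies.tsv"), "w") as fh:
        fh.write(write_adjacencies(bundle.adjacencies))


def read_bundle(path: str, prune: bool = False) -> InputBundle:
    """Read a bundle written by :func:`write_bundle`."""
    with open(os.path.join(path, "species.nwk")) as fh:
        newick = fh.read()
    with open(os.path.join(path, "ranks.tsv")) as fh:
        ranks = fh.read()
    sptree = read_species_tree(newick, ranks)
    with open(os.path.join(path, "gene_trees.nwk")) as fh:
        texts = [line for line in fh.read().splitlines() if line.strip()]
    trees = read_gene_trees(texts, sptree, prune=prune)
    with open(os.path.join(path, "adjacencies.tsv")) as fh:
        adjacencies = read_adjacencies(fh.read(), trees)
    return InputBundle(sptree, trees, adjacencies)
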