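"""Time slices and branch subdivision.

Subdividing inserts unary ``NoEvent`` nodes wherever a gene lineage crosses a
slice boundary with nothing happening, so that after subdivision every
parent-child step within the species tree spans at most one boundary.  The
dynamic program then has a cell available in every slice a pair of lineages
lives through, which is where gains and breakages between events are charged
and how transfer arrivals are matched by slice.

No ``NoEvent`` nodes are synthesized outside the species tree: the lineage
between a ``SpeciationOut`` departure and its ``Transfer`` re-entry is
untracked, and the arrival may be any number of slices later.
"""

from __future__ import annotations

from .model import (
    NO_EVENT, SPECIATION_OUT,
    DatedSpeciesTree, GeneNode, ReconciledGeneTree,
    ValidationError,
)

__all__ = ["assign_slices", "subdivide", "splice_no_events"]


def assign_slices(tree: DatedSpeciesTree) -> dict[str, list[int]]:
    """Map every species branch to the contiguous slices it overlaps.

    The branch leading to node ``X`` overlaps ``rank(parent(X)) ..
    rank(X)-1`` (down to ``s-2`` for leaf branches); the root pseudo-branch
    overlaps nothing.  Internal node ``X`` itself sits at the boundary of
    rank ``rank(X)``.
    """
    return {name: list(tree.branch_slices(name)) for name in tree.nodes}


def _insertion_slices(parent: GeneNode, child: GeneNode) -> range:
    """Slices strictly between two nodes on the same lineage."""
    return range(parent.slice_ + 1, child.slice_)


def subdivide(
    tree: ReconciledGeneTree, species_tree: DatedSpeciesTree
) -> ReconciledGeneTree:
    """Insert ``NoEvent`` nodes so consecutive gene nodes are at most one
    slice apart (transfer excursions excepted).  Modifies ``tree`` in place
    and returns it."""
    counter = 0
    for node in list(tree.iter_nodes()):
        for child in list(node.children):
            if node.event == SPECIATION_OUT and child.species != node.species:
                continue  # outside excursion: untracked
            if child.slice_ < node.slice_:
                raise ValidationError(
                    f"family {tree.family!r}: node {child.name!r} in slice "
                    f"{child.slice_} below parent {node.name!r} in slice "
                    f"{node.slice_} (non-chronological)"
                )
            slices = _insertion_slices(node, child)
            if not slices:
                continue
            idx = node.children.index(child)
            upper = node
            for t in slices:
                counter += 1
                filler = GeneNode(
                    f"{child.name}|ne{t}", NO_EVENT, child.species, t
                )
                if upper is node:
                    node.children[idx] = filler
                    filler.parent = node
                else:
                    upper.add_child(filler)
                upper = filler
            child.parent = upper
            upper.children.append(child)
    return tree


def splice_no_events(tree: ReconciledGeneTree) -> ReconciledGeneTree:
    """Remove all ``NoEvent`` nodes, reconnecting children to the closest
    non-``NoEvent`` ancestor (the inverse of :func:`subdivide`)."""
    for node in list(tree.iter_nodes()):
        if node.event != NO_EVENT:
            continue
        (child,) = node.children
        parent = node.parent
        if parent is None:
            tree.root = child
            child.parent = None
        else:
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
        node.children = []
        node.parent = None
    return tree
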