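"""Domain types for adjacency-history reconstruction.

The model follows the classical DTL (duplication-transfer-loss) setting: a
rooted binary *dated* species tree whose internal nodes (ancestral genomes)
are totally ordered in time, reconciled gene trees whose every node carries a
species branch, a time slice and an event label, and *adjacencies* -- unordered
pairs of genes that are immediately consecutive on a chromosome.

Time slices
-----------
For ``s`` extant genomes there are ``s - 1`` ancestral time slices, numbered
``0 .. s-2``; slice ``i`` is the interval immediately below the internal node
of rank ``i``.  Extant genes live at the extant level ``s - 1``.  A species
branch leading to node ``X`` overlaps slices ``rank(parent(X)) .. rank(X)-1``
(leaf branches run down to slice ``s-2``).  A Speciation gene node at ``X``
carries slice ``rank(X)``; all other events carry a slice within their
branch's span.

Transfers are modelled through unsampled lineages: a gene leaves the species
tree at a ``SpeciationOut`` node (one child continues inside the donor branch,
the other leaves) and re-enters at a ``Transfer`` node in the recipient
branch, possibly in a later slice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "EXTANT", "SPECIATION", "SPECIATION_OUT", "TRANSFER", "DUPLICATION",
    "LOSS", "NO_EVENT", "EVENTS", "OUTSIDE", "INF",
    "ValidationError", "SpeciesNode", "DatedSpeciesTree", "GeneNode",
    "ReconciledGeneTree", "CostParams", "DPCell", "AdjacencyClass",
    "AdjacencyRecord", "EventRecord", "History", "canonical_adjacency",
]

# Event labels. Short forms match the NHX ``Ev=`` tag values.
EXTANT = "Extant"
SPECIATION = "Spec"
SPECIATION_OUT = "SpecOut"
TRANSFER = "Trans"
DUPLICATION = "Dup"
LOSS = "Loss"
NO_EVENT = "NoEvent"

EVENTS = frozenset(
    {EXTANT, SPECIATION, SPECIATION_OUT, TRANSFER, DUPLICATION, LOSS, NO_EVENT}
)

#: species tag for lineages outside the sampled species tree
OUTSIDE = "OUT"

#: absorbing infinite cost sentinel (never emitted in outputs)
INF = float("inf")

# number of children each event must have
_ARITY = {
    EXTANT: (0,),
    LOSS: (0,),
    NO_EVENT: (1,),
    TRANSFER: (1,),
    SPECIATION: (2,),
    SPECIATION_OUT: (2,),
    DUPLICATION: (2,),
}


class ValidationError(ValueError):
    """Raised when an input violates the model's structural invariants."""


def canonical_adjacency(gene1: str, gene2: str) -> tuple[str, str]:
    """Return the unordered gene pair ``{gene1, gene2}`` in canonical
    (lexicographic) order.

    Adjacencies are unoriented: ``canonical_adjacency(a, b) ==
    canonical_adjacency(b, a)``.  Self-adjacencies are undefined.
    """
    if gene1 == gene2:
        raise ValidationError(f"self-adjacency {gene1!r}-{gene2!r} is undefined")
    return (gene1, gene2) if gene1 < gene2 else (gene2, gene1)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

class SpeciesNode:
    """A node of the dated species tree.

    The node name doubles as the identifier of the branch leading to it
    (the *species branch* carried by gene nodes).
    """

    __slots__ = ("name", "parent", "children", "rank")

    def __init__(self, name: str, rank: Optional[int] = None):
        self.name = name
        self.parent: Optional[SpeciesNode] = None
        self.children: list[SpeciesNode] = []
        self.rank = rank  # None for leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesNode({self.name!r}, rank={self.rank})"


class DatedSpeciesTree:
    """Rooted binary species tree with totally ordered internal nodes.

    Parameters
    ----------
    root:
        Root :class:`SpeciesNode`; every internal node must have ``rank``
        set, ranks must be pairwise distinct, start at 0 at the root and
        respect ancestry (parent rank < child rank).
    """

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.nodes: dict[str, SpeciesNode] = {}
        for node in self.iter_nodes():
            if node.name in self.nodes:
                raise ValidationError(f"duplicate species label {node.name!r}")
            self.nodes[node.name] = node
        self.leaves = [n for n in self.nodes.values() if n.is_leaf]
        self._validate()

    # -- structure ---------------------------------------------------------
    def iter_nodes(self) -> Iterator[SpeciesNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_slices(self) -> int:
        """Number of ancestral time slices (``s - 1``)."""
        return self.n_leaves - 1

    @property
    def extant_slice(self) -> int:
        """Slice index of the extant level."""
        return self.n_leaves - 1

    def _validate(self) -> None:
        internals = [n for n in self.nodes.values() if not n.is_leaf]
        for node in internals:
            if len(node.children) != 2:
                raise ValidationError(
                    f"species node {node.name!r} is not binary "
                    f"({len(node.children)} children)"
                )
            if node.rank is None:
                raise ValidationError(f"internal node {node.name!r} has no rank")
        ranks = sorted(n.rank for n in internals)
        if ranks != list(range(len(internals))):
            raise ValidationError(
                f"ranks must be a permutation of 0..{len(internals) - 1}, got {ranks}"
            )
        if self.root.rank != 0:
            raise ValidationError("root must have the smallest rank (0)")
        for node in internals:
            if node.parent is not None and node.parent.rank >= node.rank:
                raise ValidationError(
                    f"rank of {node.name!r} ({node.rank}) must exceed its "
                    f"parent's ({node.parent.rank})"
                )
        if len(self.leaves) != len(internals) + 1:
            raise ValidationError("tree is not binary")

    # -- dating ------------------------------------------------------------
    def branch_slices(self, name: str) -> range:
        """Slices overlapped by the branch leading to node ``name``.

        The root pseudo-branch overlaps nothing (empty range).
        """
        node = self.nodes[name]
        if node.parent is None:
            return range(0, 0)
        top = node.parent.rank
        bottom = (node.rank - 1) if not node.is_leaf else (self.n_leaves - 2)
        return range(top, bottom + 1)

    def is_ancestor_or_self(self, anc: str, desc: str) -> bool:
        node: Optional[SpeciesNode] = self.nodes[desc]
        while node is not None:
            if node.name == anc:
                return True
            node = node.parent
        return False


# ---------------------------------------------------------------------------
# reconciled gene trees
# ---------------------------------------------------------------------------

_uid_counter = itertools.count()


class GeneNode:
    """A node of a reconciled gene tree.

    Attributes
    ----------
    name:
        Globally unique gene identifier (auto-generated for unnamed internal
        nodes).
    event:
        One of the event labels (:data:`EVENTS`).
    species:
        Species branch identifier, or :data:`OUTSIDE` for unsampled lineages.
    slice_:
        Time slice index.
    """

    __slots__ = ("name", "event", "species", "slice_", "children", "parent", "uid")

    def __init__(self, name: str, event: str, species: str, slice_: int):
        self.name = name
        self.event = event
        self.species = species
        self.slice_ = slice_
        self.children: list[GeneNode] = []
        self.parent: Optional[GeneNode] = None
        self.uid: int = next(_uid_counter)

    def add_child(self, child: "GeneNode") -> "GeneNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "GeneNode":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_subtree(self) -> Iterator["GeneNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def is_ancestor_or_self(self, other: "GeneNode") -> bool:
        node: Optional[GeneNode] = other
        while node is not None:
            if node is self:
                return True
            node = node.parent
        return False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"GeneNode({self.name!r}, {self.event}, S={self.species}, "
            f"ts={self.slice_})"
        )


class ReconciledGeneTree:
    """A gene family tree annotated with species, slice and event per node."""

    def __init__(self, root: GeneNode, family: str):
        self.root = root
        self.family = family

    def iter_nodes(self) -> Iterator[GeneNode]:
        return self.root.iter_subtree()

    def leaves(self) -> list[GeneNode]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def extant_leaves(self) -> list[GeneNode]:
        return [n for n in self.iter_nodes() if n.event == EXTANT]

    def validate(self, species_tree: DatedSpeciesTree) -> None:
        """Check structural invariants against the dated species tree.

        Raises :class:`ValidationError` naming the offending gene node.
        """
        validate_gene_tree(self, species_tree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReconciledGeneTree({self.family!r})"


def _err(tree: ReconciledGeneTree, node: GeneNode, msg: str) -> ValidationError:
    return ValidationError(f"family {tree.family!r}, node {node.name!r}: {msg}")


def validate_gene_tree(tree: ReconciledGeneTree, sptree: DatedSpeciesTree) -> None:
    seen: set[str] = set()
    extant = sptree.extant_slice
    for node in tree.iter_nodes():
        if node.name in seen:
            raise _err(tree, node, "duplicate gene identifier")
        seen.add(node.name)
        if node.event not in EVENTS:
            raise _err(tree, node, f"unknown event {node.event!r}")
        if len(node.children) not in _ARITY[node.event]:
            raise _err(
                tree, node,
                f"event {node.event} requires {_ARITY[node.event][0]} "
                f"children, has {len(node.children)}",
            )
        if node.species == OUTSIDE:
            raise _err(
                tree, node,
                "node outside the species tree survived normalization "
                "(outside lineages must lead to a Transfer or Loss)",
            )
        if node.species not in sptree.nodes:
            raise _err(tree, node, f"unknown species {node.species!r}")
        sp = sptree.nodes[node.species]

        if node.event == EXTANT:
            if not sp.is_leaf:
                raise _err(tree, node, "extant gene in a non-extant species")
            if node.slice_ != extant:
                raise _err(
                    tree, node,
                    f"extant gene must be in slice {extant}, has {node.slice_}",
                )
        elif node.event == SPECIATION:
            if sp.is_leaf:
                raise _err(tree, node, "speciation mapped to an extant species")
            if node.slice_ != sp.rank:
                raise _err(
                    tree, node,
                    f"speciation at {sp.name!r} must be in slice {sp.rank}, "
                    f"has {node.slice_}",
                )
            child_species = sorted(c.species for c in node.children)
            expected = sorted(c.name for c in sp.children)
            if child_species != expected:
                raise _err(
                    tree, node,
                    f"speciation children map to {child_species}, expected the "
                    f"child branches {expected} of {sp.name!r}",
                )
        else:
            span = sptree.branch_slices(node.species)
            in_span = node.slice_ in span
            # the root genome sits at the root speciation boundary (slice 0)
            at_root = sp.parent is None and node.slice_ == 0
            if not (in_span or at_root):
                raise _err(
                    tree, node,
                    f"slice {node.slice_} outside the span "
                    f"{list(span)} of branch {node.species!r}",
                )

        if node.event == SPECIATION_OUT:
            inside = [c for c in node.children if c.species == node.species]
            away = [c for c in node.children if c.species != node.species]
            if len(inside) != 1 or len(away) != 1:
                raise _err(
                    tree, node,
                    "SpeciationOut needs one child inside its branch and one "
                    "leaving it",
                )
            if away[0].event not in (TRANSFER, LOSS):
                raise _err(
                    tree, node,
                    f"outgoing child {away[0].name!r} must be a Transfer "
                    f"(or a Loss outside), not {away[0].event}",
                )
        elif node.event in (DUPLICATION, NO_EVENT, TRANSFER):
            for c in node.children:
                if c.species != node.species:
                    raise _err(
                        tree, node,
                        f"child {c.name!r} changes species branch without a "
                        f"speciation ({node.species!r} -> {c.species!r})",
                    )
        if node.event == TRANSFER:
            anc, has_specout = node.parent, False
            while anc is not None:
                if anc.event == SPECIATION_OUT:
                    has_specout = True
                    break
                anc = anc.parent
            if node.parent is not None and not has_specout:
                raise _err(tree, node, "Transfer without a SpeciationOut ancestor")
            if node.parent is not None and node.parent.event == SPECIATION_OUT:
                if node.slice_ < node.parent.slice_:
                    raise _err(
                        tree, node,
                        "transfer arrives before its SpeciationOut departure",
                    )
        # chronology inside the species tree
        if (
            node.parent is not None
            and node.parent.event != SPECIATION_OUT
            and node.slice_ < node.parent.slice_
        ):
            raise _err(
                tree, node,
                f"slice {node.slice_} earlier than parent's "
                f"{node.parent.slice_} (non-chronological reconciliation)",
            )


# ---------------------------------------------------------------------------
# costs, DP cell, classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostParams:
    """Costs of the two rearrangement event types.

    Both default to 1, the setting under which the optimization minimizes the
    plain number of adjacency gains plus breakages.
    """

    gain: float = 1.0
    breakage: float = 1.0

    def __post_init__(self) -> None:
        for label, v in (("gain", self.gain), ("breakage", self.breakage)):
            if not (v >= 0 and v < INF):
                raise ValidationError(f"C({label}) must be finite and >= 0, got {v}")


@dataclass
class DPCell:
    """Minimum history costs for a pair of gene subtrees.

    ``c1`` assumes an adjacency between the two subtree roots, ``c0`` assumes
    none.  Either may be the infinite sentinel (both only at extant leaf
    pairs, where the input fixes the state).
    """

    c1: float
    c0: float


@dataclass
class AdjacencyClass:
    """An equivalence class of possibly-homologous extant adjacencies.

    ``root_a``/``root_b`` are the highest distinct gene nodes with disjoint
    subtrees from which every member adjacency's extremities descend.
    """

    members: list[tuple[str, str]]
    root_a: GeneNode
    root_b: GeneNode


# ---------------------------------------------------------------------------
# histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacencyRecord:
    """An adjacency located in a species branch and time slice.

    ``in_genome`` is true when both extremities are genes of the genome at
    that point (both Speciation nodes at the same species node, or both
    extant leaves), as opposed to an intermediate state between events.
    """

    species: str
    slice_: int
    gene1: str
    gene2: str
    in_genome: bool


@dataclass(frozen=True)
class EventRecord:
    kind: str  # "Gain" | "Break"
    species: str
    slice_: int
    gene1: str
    gene2: str


@dataclass(frozen=True)
class TransferLink:
    """An adjacency maintained through a single transfer event (Case of two
    compatible Transfer arrivals with the adjacency kept)."""

    donor_species: str
    donor_slice: int
    recipient_species: str
    recipient_slice: int
    gene1: str
    gene2: str


@dataclass(frozen=True)
class CoDuplicationLink:
    """An adjacency maintained through a simultaneous duplication of both of
    its extremities."""

    species: str
    slice_: int
    gene1: str
    gene2: str


@dataclass
class History:
    """A set of extant and ancestral adjacencies with its implied events.

    The cost is ``|gains| * C(gain) + |breaks| * C(breakage)``.
    """

    adjacencies: list[AdjacencyRecord] = field(default_factory=list)
    gains: list[EventRecord] = field(default_factory=list)
    breaks: list[EventRecord] = field(default_factory=list)
    transfer_links: list[TransferLink] = field(default_factory=list)
    coduplication_links: list[CoDuplicationLink] = field(default_factory=list)
    total_cost: float = 0.0

    def recomputed_cost(self, costs: CostParams) -> float:
        return len(self.gains) * costs.gain + len(self.breaks) * costs.breakage

    def extant_adjacencies(self, sptree: DatedSpeciesTree) -> set[tuple[str, str]]:
        ext = sptree.extant_slice
        return {
            canonical_adjacency(r.gene1, r.gene2)
            for r in self.adjacencies
            if r.slice_ == ext and r.in_genome
        }

    def genome_adjacencies(self, species: str) -> set[tuple[str, str]]:
        """Adjacencies of the (ancestral or extant) genome at ``species``."""
        return {
            canonical_adjacency(r.gene1, r.gene2)
            for r in self.adjacencies
            if r.species == species and r.in_genome
        }
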