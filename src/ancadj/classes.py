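"""Possible-homology classes of extant adjacencies.

Two extant adjacencies are *possibly homologous* when a pair of distinct
ancestral genes in the same species could be the extremities of a common
ancestral adjacency.  The relation's transitive closure partitions the
extant adjacencies into equivalence classes; each class is solved by one
dynamic program on the pair of subtrees hanging from its *roots*, the
highest such pair.

A pair of ancestors only qualifies if the dynamic program could actually
couple the two extremities from it: along the two descent paths, excursions
outside the species tree (SpeciationOut departure then Transfer re-entry)
must match in donor and arrival coordinates.  This *transfer signature*
condition is also what makes a Transfer arrival whose partner did not
co-transfer root an additional class of its own.
"""

from __future__ import annotations

from .model import (
    DUPLICATION, EXTANT, LOSS, NO_EVENT, SPECIATION, SPECIATION_OUT, TRANSFER,
    AdjacencyClass, GeneNode, ReconciledGeneTree,
    canonical_adjacency,
)
from .dp import transfers_compatible
from .io import build_gene_index

__all__ = ["possibly_homologous", "build_classes", "covering_pairs"]

PairKey = tuple[int, int]
Signature = tuple[tuple[str, int, str, int], ...]


def _annotated_chain(leaf: GeneNode) -> list[tuple[GeneNode, Signature]]:
    """Ancestors of ``leaf`` (leaf first) with the transfer signature of the
    descent path from each ancestor down to the leaf."""
    chain: list[tuple[GeneNode, Signature]] = [(leaf, ())]
    node, sig = leaf, ()
    while node.parent is not None:
        parent = node.parent
        if parent.event == SPECIATION_OUT and node.species != parent.species:
            sig = (
                (parent.species, parent.slice_, node.species, node.slice_),
            ) + sig
        node = parent
        chain.append((node, sig))
    return chain


def _disjoint(u: GeneNode, v: GeneNode) -> bool:
    return not u.is_ancestor_or_self(v) and not v.is_ancestor_or_self(u)


def _step_towards(node: GeneNode, target: GeneNode) -> GeneNode | None:
    for child in node.children:
        if child.is_ancestor_or_self(target):
            return child
    return None


def _couples(u: GeneNode, v: GeneNode, x: GeneNode, y: GeneNode) -> bool:
    """Whether the recurrences' descent from pair ``(u, v)`` actually pairs
    the extremities ``x`` (under ``u``) with ``y`` (under ``v``).

    Mirrors the case dispatch: transfers paired with a passive partner pass
    through, linked double departures couple the outgoing copies, unlinked
    ones only the inside continuations, and speciations pair children by
    species."""
    passive = (NO_EVENT, SPECIATION, EXTANT, SPECIATION_OUT)
    while True:
        if u is x and v is y:
            return True
        eu, ev = u.event, v.event
        if eu == LOSS or ev == LOSS:
            return False
        if eu == EXTANT and ev == EXTANT:
            return False
        if eu == NO_EVENT and u.slice_ < v.slice_:
            u = u.children[0]
            continue
        if ev == NO_EVENT and v.slice_ < u.slice_:
            v = v.children[0]
            continue
        if eu == DUPLICATION:
            u = _step_towards(u, x)
            continue
        if ev == DUPLICATION:
            v = _step_towards(v, y)
            continue
        if eu == TRANSFER and ev == TRANSFER:
            if not transfers_compatible(u, v):
                return False
            u, v = u.children[0], v.children[0]
            continue
        if eu == TRANSFER and ev in passive:
            u = u.children[0]
            continue
        if ev == TRANSFER and eu in passive:
            v = v.children[0]
            continue
        if eu == SPECIATION_OUT and ev == SPECIATION_OUT:
            nu, nv = _step_towards(u, x), _step_towards(v, y)
            u_away = nu.species != u.species
            v_away = nv.species != v.species
            if u_away != v_away:
                return False
            if u_away and not (
                nu.event == TRANSFER
                and nv.event == TRANSFER
                and transfers_compatible(nu, nv)
            ):
                return False
            u, v = nu, nv
            continue
        if ev == SPECIATION_OUT:
            nv = _step_towards(v, y)
            if nv.species != v.species:
                return False  # partner stays, copy leaves alone
            v = nv
            continue
        if eu == SPECIATION_OUT:
            nu = _step_towards(u, x)
            if nu.species != u.species:
                return False
            u = nu
            continue
        if eu == SPECIATION and ev == SPECIATION:
            nu, nv = _step_towards(u, x), _step_towards(v, y)
            if nu.species != nv.species:
                return False
            u, v = nu, nv
            continue
        if eu == NO_EVENT:
            u = u.children[0]
            continue
        if ev == NO_EVENT:
            v = v.children[0]
            continue
        return False


def covering_pairs(
    x: GeneNode, y: GeneNode
) -> dict[PairKey, tuple[GeneNode, GeneNode]]:
    """All pairs of ancestors ``(u, v)`` of ``x`` and ``y`` in the same
    species branch, with disjoint subtrees and matching transfer
    signatures -- the candidate ancestral extremities of an adjacency
    ancestral to ``xy``."""
    out: dict[PairKey, tuple[GeneNode, GeneNode]] = {}
    chain_y = _annotated_chain(y)
    by_species: dict[str, list[tuple[GeneNode, Signature]]] = {}
    for v, sig in chain_y:
        by_species.setdefault(v.species, []).append((v, sig))
    for u, sig_u in _annotated_chain(x):
        for v, sig_v in by_species.get(u.species, ()):
            if u is v or sig_u != sig_v:
                continue
            if not _disjoint(u, v):
                continue
            if not _couples(u, v, x, y):
                continue  # the recurrences cannot pair x with y from here
            key = (u.uid, v.uid) if u.uid < v.uid else (v.uid, u.uid)
            out[key] = (u, v) if u.uid < v.uid else (v, u)
    return out


def _adjacency_pairs(
    adj: tuple[str, str], index: dict[str, GeneNode]
) -> dict[PairKey, tuple[GeneNode, GeneNode]]:
    return covering_pairs(index[adj[0]], index[adj[1]])


def possibly_homologous(
    adj1: tuple[str, str],
    adj2: tuple[str, str],
    trees: list[ReconciledGeneTree],
) -> bool:
    """True iff the two extant adjacencies could descend from a common
    ancestral adjacency.  Symmetric and reflexive."""
    index = build_gene_index(trees)
    p1 = _adjacency_pairs(canonical_adjacency(*adj1), index)
    p2 = _adjacency_pairs(canonical_adjacency(*adj2), index)
    return bool(p1.keys() & p2.keys())


def _pick_root(
    keys: set[PairKey], pairs: dict[PairKey, tuple[GeneNode, GeneNode]]
) -> tuple[GeneNode, GeneNode]:
    """Deterministic 'highest' pair: earliest combined slice, then node
    names."""

    def rank(key: PairKey):
        u, v = pairs[key]
        return (u.slice_ + v.slice_, min(u.slice_, v.slice_), u.name, v.name)

    return pairs[min(keys, key=rank)]


def build_classes(
    adjacencies: list[tuple[str, str]],
    trees: list[ReconciledGeneTree],
) -> list[AdjacencyClass]:
    """Partition extant adjacencies into possible-homology classes and
    locate each class's root pair.

    Classes are the connected components of the pairwise relation (adjacency
    order does not matter).  When no single pair covers every member of a
    component (possible for same-family adjacencies, whose roots must have
    disjoint subtrees), the component is split greedily into maximal
    coverable subclasses, earliest root first.
    """
    index = build_gene_index(trees)
    adjacencies = sorted({canonical_adjacency(*a) for a in adjacencies})
    pair_sets = [_adjacency_pairs(a, index) for a in adjacencies]
    pair_nodes: dict[PairKey, tuple[GeneNode, GeneNode]] = {}
    for ps in pair_sets:
        pair_nodes.update(ps)

    # union-find over adjacencies via shared covering pairs
    parent = list(range(len(adjacencies)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    first_owner: dict[PairKey, int] = {}
    for i, ps in enumerate(pair_sets):
        for key in ps:
            if key in first_owner:
                union(first_owner[key], i)
            else:
                first_owner[key] = i

    components: dict[int, list[int]] = {}
    for i in range(len(adjacencies)):
        components.setdefault(find(i), []).append(i)

    out: list[AdjacencyClass] = []
    for members in components.values():
        remaining = list(members)
        while remaining:
            common = set(pair_sets[remaining[0]].keys())
            for i in remaining[1:]:
                common &= pair_sets[i].keys()
            if common:
                covered, rest = remaining, []
            else:
                # greedy split: take the pair covering the most members
                counts: dict[PairKey, list[int]] = {}
                for i in remaining:
                    for key in pair_sets[i]:
                        counts.setdefault(key, []).append(i)

                def score(item):
                    key, covered_ids = item
                    u, v = pair_nodes[key]
                    return (-len(covered_ids), u.slice_ + v.slice_, u.name, v.name)

                best_key, covered = min(counts.items(), key=score)
                common = {best_key}
                rest = [i for i in remaining if i not in covered]
            root_a, root_b = _pick_root(common, pair_nodes)
            out.append(
                AdjacencyClass(
                    members=[adjacencies[i] for i in covered],
                    root_a=root_a,
                    root_b=root_b,
                )
            )
            remaining = rest
    out.sort(key=lambda c: c.members[0])
    return out
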