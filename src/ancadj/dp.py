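"""The adjacency-history dynamic program.

For a pair of gene subtrees rooted at ``a`` and ``b`` on the same species
branch, ``c1(a, b)`` is the minimum cost of a history assuming an adjacency
between ``a`` and ``b`` and ``c0(a, b)`` assuming none.  Cells are computed
by case analysis on the pair of events ``(E(a), E(b))``, translating the
propagation rules and adding the possibility of a gain or breakage at each
step:

1. Extant/Extant: the input fixes the state.
2. GeneLoss with anything: both costs 0 (a loss is not a rearrangement).
3. NoEvent/NoEvent: both lineages change slice; break or gain possible.
4. {Extant,NoEvent,Spec,SpecOut}/Dup: the duplication resolves first; the
   adjacency follows one copy for free, both copies with a gain, none with
   a breakage.
5. Dup/Dup: minimum over a-first, b-first and simultaneous resolution; the
   simultaneous term enumerates all 2^4 presence configurations over the
   four child pairs, costed against the best of the two perfect matchings
   of copies.
6. Spec/Spec: children paired by species; the adjacency propagates to both
   descendant genomes, each absence costing a breakage (each presence under
   ``c0`` costing a gain).
7. {Extant,NoEvent,Spec}/SpecOut: the adjacency follows the inside child.
8. SpecOut/SpecOut: the adjacency propagates to the inside pair (for free,
   nothing happened inside the donor genome) and to the outgoing pair
   (breakable / gainable).
9. Transfer/Transfer arriving in the same species and slice from
   SpeciationOut departures in the same species and slice: one step, like
   Case 3.  Otherwise the pair cannot carry an adjacency: ``(inf, 0)``.

A Transfer paired with a non-Transfer, non-Loss node roots its own
equivalence class; its cell passes through to the arrival's child.

Combinations of a duplication or loss with any event not listed follow the
"no event" rule, the duplication or loss resolving first.
"""

from __future__ import annotations

from itertools import product
from typing import Callable, Optional

from .model import (
    DUPLICATION, EXTANT, INF, LOSS, NO_EVENT, SPECIATION, SPECIATION_OUT,
    TRANSFER,
    AdjacencyClass, CostParams, DPCell, GeneNode, canonical_adjacency,
)

__all__ = [
    "fill_matrix", "compute_cell", "cell_key", "case_of", "options",
    "class_optimum", "d12_configurations", "donor_context",
]

CellKey = tuple[int, int]

#: option = (cost, child assignments, gains, breaks, link-tag)
Option = tuple[
    float,
    tuple[tuple[GeneNode, GeneNode, int], ...],
    tuple[tuple[GeneNode, GeneNode], ...],
    tuple[tuple[GeneNode, GeneNode], ...],
    Optional[str],
]


def cell_key(a: GeneNode, b: GeneNode) -> CellKey:
    return (a.uid, b.uid) if a.uid < b.uid else (b.uid, a.uid)


def donor_context(t: GeneNode) -> Optional[tuple[str, int]]:
    """Species branch and slice of the SpeciationOut departure feeding a
    Transfer arrival, or None for a transfer at a (pruned) tree root."""
    node = t.parent
    while node is not None:
        if node.event == SPECIATION_OUT:
            return (node.species, node.slice_)
        node = node.parent
    return None


def transfers_compatible(a: GeneNode, b: GeneNode) -> bool:
    """True when two Transfer arrivals can represent one transfer event:
    same recipient branch and slice, and SpeciationOut departures from the
    same branch and slice (or both arrivals rooting pruned subtrees)."""
    return _transfers_compatible(a, b)


def _transfers_compatible(a: GeneNode, b: GeneNode) -> bool:
    if a.species != b.species or a.slice_ != b.slice_:
        return False
    da, db = donor_context(a), donor_context(b)
    if da is None and db is None:
        # both arrivals root pruned subtrees; same arrival point is the best
        # available evidence of a shared transfer event
        return True
    return da is not None and db is not None and da == db


def case_of(a: GeneNode, b: GeneNode) -> tuple[str, GeneNode, GeneNode]:
    """Dispatch a cell to its recurrence case.

    Returns ``(case, x, y)`` with the nodes oriented so the case applies to
    ``y`` (e.g. for ``"dup"``, ``y`` is the duplication).
    """
    ea, eb = a.event, b.event
    if ea == LOSS or eb == LOSS:
        return ("loss", a, b)
    if ea == EXTANT and eb == EXTANT:
        return ("extant", a, b)
    # a NoEvent lagging strictly behind its partner advances first, so the
    # two lineages meet their same-slice events aligned
    if ea == NO_EVENT and a.slice_ < b.slice_:
        return ("unary_noevent", b, a)
    if eb == NO_EVENT and b.slice_ < a.slice_:
        return ("unary_noevent", a, b)
    if ea == DUPLICATION and eb == DUPLICATION:
        return ("dupdup", a, b)
    if eb == DUPLICATION:
        return ("dup", a, b)
    if ea == DUPLICATION:
        return ("dup", b, a)
    if ea == TRANSFER and eb == TRANSFER:
        if _transfers_compatible(a, b):
            return ("transfer", a, b)
        return ("incompatible", a, b)
    if ea == TRANSFER:
        return ("transfer_mixed", b, a)
    if eb == TRANSFER:
        return ("transfer_mixed", a, b)
    if ea == SPECIATION_OUT and eb == SPECIATION_OUT:
        return ("soso", a, b)
    if eb == SPECIATION_OUT:
        return ("so", a, b)
    if ea == SPECIATION_OUT:
        return ("so", b, a)
    if ea == SPECIATION and eb == SPECIATION:
        return ("specspec", a, b)
    if ea == NO_EVENT and eb == NO_EVENT:
        return ("noeno", a, b)
    if ea == NO_EVENT:
        return ("unary_noevent", b, a)
    if eb == NO_EVENT:
        return ("unary_noevent", a, b)
    raise RuntimeError(
        f"unreachable event combination ({ea}, {eb}) for nodes "
        f"{a.name!r}, {b.name!r}"
    )


def _linked_departures(out_x: GeneNode, out_y: GeneNode) -> bool:
    """True when two outgoing SpeciationOut children represent one transfer
    event, so the adjacency can travel with them (Case of two departures
    followed by compatible arrivals)."""
    return (
        out_x.event == TRANSFER
        and out_y.event == TRANSFER
        and _transfers_compatible(out_x, out_y)
    )


def _inside_out(so: GeneNode) -> tuple[GeneNode, GeneNode]:
    inside = [c for c in so.children if c.species == so.species]
    away = [c for c in so.children if c.species != so.species]
    if len(inside) != 1 or len(away) != 1:  # pragma: no cover - validated input
        raise RuntimeError(f"malformed SpeciationOut node {so.name!r}")
    return inside[0], away[0]


def _pair_children(a: GeneNode, b: GeneNode) -> list[tuple[GeneNode, GeneNode]]:
    """Speciation children matched by species branch."""
    a1, a2 = a.children
    by_species = {c.species: c for c in b.children}
    try:
        return [(a1, by_species[a1.species]), (a2, by_species[a2.species])]
    except KeyError:  # pragma: no cover - validated input
        raise RuntimeError(
            f"speciation children of {a.name!r} and {b.name!r} do not pair"
        ) from None


def dependencies(a: GeneNode, b: GeneNode) -> list[tuple[GeneNode, GeneNode]]:
    """Child cells a cell's recurrence refers to."""
    case, x, y = case_of(a, b)
    if case in ("loss", "extant", "incompatible"):
        return []
    if case == "noeno":
        return [(x.children[0], y.children[0])]
    if case == "unary_noevent":
        return [(x, y.children[0])]
    if case == "dup":
        d1, d2 = y.children
        return [(x, d1), (x, d2)]
    if case == "dupdup":
        a1, a2 = x.children
        b1, b2 = y.children
        return (
            [(x, b1), (x, b2), (a1, y), (a2, y)]
            + [(u, v) for u in (a1, a2) for v in (b1, b2)]
        )
    if case == "specspec":
        return _pair_children(x, y)
    if case == "so":
        return [(x, _inside_out(y)[0])]
    if case == "soso":
        in_x, out_x = _inside_out(x)
        in_y, out_y = _inside_out(y)
        if _linked_departures(out_x, out_y):
            return [(in_x, in_y), (out_x, out_y)]
        return [(in_x, in_y)]
    if case == "transfer":
        return [(x.children[0], y.children[0])]
    if case == "transfer_mixed":
        return [(x, y.children[0])]
    raise AssertionError(case)


# ---------------------------------------------------------------------------
# the simultaneous-duplication term
# ---------------------------------------------------------------------------

#: the four child pairs of a simultaneous duplication, as (i, j) index pairs,
#: and the two perfect matchings of copies
_D12_SLOTS = ((0, 0), (1, 1), (0, 1), (1, 0))
_D12_MATCHINGS = (((0, 0), (1, 1)), ((0, 1), (1, 0)))


def d12_configurations() -> list[dict]:
    """Enumerate the configurations of the simultaneous-duplication term.

    One configuration per subset of the four child pairs (2^4 = 16), each
    carrying, for both perfect matchings of the copies, the number of gains
    (present pairs outside the matching) and breakages (matched pairs
    absent).  The term's value is the minimum over configurations and
    matchings of the children's costs plus the event costs.
    """
    configs = []
    for bits in product((0, 1), repeat=4):
        present = frozenset(p for p, bit in zip(_D12_SLOTS, bits) if bit)
        per_matching = []
        for matching in _D12_MATCHINGS:
            mset = frozenset(matching)
            per_matching.append(
                {
                    "matching": matching,
                    "gains": sorted(present - mset),
                    "breaks": sorted(mset - present),
                }
            )
        configs.append({"present": present, "matchings": per_matching})
    return configs


_D12_CONFIGS = d12_configurations()


# ---------------------------------------------------------------------------
# recurrence options
# ---------------------------------------------------------------------------

def options(
    a: GeneNode,
    b: GeneNode,
    state: int,
    cell: Callable[[GeneNode, GeneNode], DPCell],
    costs: CostParams,
    extant: set[tuple[str, str]],
    members: Optional[set[tuple[str, str]]] = None,
) -> list[Option]:
    """All resolution options of a cell, in preference (printed) order.

    The cell value is the minimum option cost; backtracking re-enumerates
    the options and follows the best one.  ``members`` restricts the input
    constraint to the current class: an extant adjacency belonging to
    another class (reachable when a possible-homology component had to be
    split) is neutral here -- its gain is charged by its own class.
    """
    G, B = costs.gain, costs.breakage
    case, x, y = case_of(a, b)
    opts: list[Option] = []

    def c(u: GeneNode, v: GeneNode, s: int) -> float:
        dc = cell(u, v)
        return dc.c1 if s else dc.c0

    def add(cost, children=(), gains=(), breaks=(), link=None):
        if cost < INF:
            opts.append((cost, tuple(children), tuple(gains), tuple(breaks), link))

    if case == "extant":
        pair = canonical_adjacency(a.name, b.name)
        if pair in extant and members is not None and pair not in members:
            add(0.0)  # another class's adjacency: no constraint here
        elif (state == 1) == (pair in extant):
            add(0.0)
        return opts
    if case == "loss":
        add(0.0)
        return opts
    if case == "incompatible":
        if state == 0:
            add(0.0)
        return opts

    if case in ("noeno", "transfer"):
        u, v = x.children[0], y.children[0]
        link = "transfer" if case == "transfer" else None
        if state == 1:
            add(c(u, v, 1), [(u, v, 1)], link=link)
            add(c(u, v, 0) + B, [(u, v, 0)], breaks=[(u, v)])
        else:
            add(c(u, v, 0), [(u, v, 0)])
            add(c(u, v, 1) + G, [(u, v, 1)], gains=[(u, v)])
        return opts

    if case == "unary_noevent":
        u, v = x, y.children[0]
        if state == 1:
            add(c(u, v, 1), [(u, v, 1)])
            add(c(u, v, 0) + B, [(u, v, 0)], breaks=[(u, v)])
        else:
            add(c(u, v, 0), [(u, v, 0)])
            add(c(u, v, 1) + G, [(u, v, 1)], gains=[(u, v)])
        return opts

    if case == "transfer_mixed":
        u, v = x, y.children[0]
        add(c(u, v, state), [(u, v, state)])
        return opts

    def ordered_dup(w: GeneNode, d: GeneNode) -> None:
        """D1/D0: duplication ``d`` resolves first against partner ``w``."""
        d1, d2 = d.children
        if state == 1:
            add(c(w, d1, 1) + c(w, d2, 0), [(w, d1, 1), (w, d2, 0)])
            add(c(w, d1, 0) + c(w, d2, 1), [(w, d1, 0), (w, d2, 1)])
            add(
                c(w, d1, 1) + c(w, d2, 1) + G,
                [(w, d1, 1), (w, d2, 1)],
                gains=[(w, d2)],
            )
            add(
                c(w, d1, 0) + c(w, d2, 0) + B,
                [(w, d1, 0), (w, d2, 0)],
                breaks=[(w, d1)],
            )
        else:
            add(c(w, d1, 0) + c(w, d2, 0), [(w, d1, 0), (w, d2, 0)])
            add(
                c(w, d1, 0) + c(w, d2, 1) + G,
                [(w, d1, 0), (w, d2, 1)],
                gains=[(w, d2)],
            )
            add(
                c(w, d1, 1) + c(w, d2, 0) + G,
                [(w, d1, 1), (w, d2, 0)],
                gains=[(w, d1)],
            )
            add(
                c(w, d1, 1) + c(w, d2, 1) + 2 * G,
                [(w, d1, 1), (w, d2, 1)],
                gains=[(w, d1), (w, d2)],
            )

    if case == "dup":
        ordered_dup(x, y)
        return opts

    if case == "dupdup":
        ordered_dup(x, y)  # D1/D0: b's duplication first
        ordered_dup(y, x)  # D2 and the a-first mirror of D00
        if state == 1 and x.species == y.species and x.slice_ == y.slice_:
            # D12: simultaneous duplications
            ax = x.children
            by = y.children
            for config in _D12_CONFIGS:
                present = config["present"]
                children = [
                    (ax[i], by[j], 1 if (i, j) in present else 0)
                    for (i, j) in _D12_SLOTS
                ]
                base = sum(
                    c(ax[i], by[j], 1 if (i, j) in present else 0)
                    for (i, j) in _D12_SLOTS
                )
                best = min(
                    config["matchings"],
                    key=lambda m: len(m["gains"]) * G + len(m["breaks"]) * B,
                )
                cost = base + len(best["gains"]) * G + len(best["breaks"]) * B
                kept = present & frozenset(best["matching"])
                add(
                    cost,
                    children,
                    gains=[(ax[i], by[j]) for (i, j) in best["gains"]],
                    breaks=[(ax[i], by[j]) for (i, j) in best["breaks"]],
                    link="coduplication" if kept else None,
                )
        return opts

    if case == "specspec":
        (a1, b1), (a2, b2) = _pair_children(x, y)
        if state == 1:
            add(c(a1, b1, 1) + c(a2, b2, 1), [(a1, b1, 1), (a2, b2, 1)])
            add(
                c(a1, b1, 1) + c(a2, b2, 0) + B,
                [(a1, b1, 1), (a2, b2, 0)],
                breaks=[(a2, b2)],
            )
            add(
                c(a1, b1, 0) + c(a2, b2, 1) + B,
                [(a1, b1, 0), (a2, b2, 1)],
                breaks=[(a1, b1)],
            )
            add(
                c(a1, b1, 0) + c(a2, b2, 0) + 2 * B,
                [(a1, b1, 0), (a2, b2, 0)],
                breaks=[(a1, b1), (a2, b2)],
            )
        else:
            add(c(a1, b1, 0) + c(a2, b2, 0), [(a1, b1, 0), (a2, b2, 0)])
            add(
                c(a1, b1, 1) + c(a2, b2, 0) + G,
                [(a1, b1, 1), (a2, b2, 0)],
                gains=[(a1, b1)],
            )
            add(
                c(a1, b1, 0) + c(a2, b2, 1) + G,
                [(a1, b1, 0), (a2, b2, 1)],
                gains=[(a2, b2)],
            )
            add(
                c(a1, b1, 1) + c(a2, b2, 1) + 2 * G,
                [(a1, b1, 1), (a2, b2, 1)],
                gains=[(a1, b1), (a2, b2)],
            )
        return opts

    if case == "so":
        inside, _ = _inside_out(y)
        add(c(x, inside, state), [(x, inside, state)])
        return opts

    if case == "soso":
        in_x, out_x = _inside_out(x)
        in_y, out_y = _inside_out(y)
        if not _linked_departures(out_x, out_y):
            # two unrelated departures: the donor adjacency just continues,
            # and the copies leave separately without ever being adjacent
            add(c(in_x, in_y, state), [(in_x, in_y, state)])
            return opts
        if state == 1:
            add(
                c(in_x, in_y, 1) + c(out_x, out_y, 1),
                [(in_x, in_y, 1), (out_x, out_y, 1)],
            )
            add(
                c(in_x, in_y, 1) + c(out_x, out_y, 0) + B,
                [(in_x, in_y, 1), (out_x, out_y, 0)],
                breaks=[(out_x, out_y)],
            )
        else:
            add(
                c(in_x, in_y, 0) + c(out_x, out_y, 0),
                [(in_x, in_y, 0), (out_x, out_y, 0)],
            )
            add(
                c(in_x, in_y, 0) + c(out_x, out_y, 1) + G,
                [(in_x, in_y, 0), (out_x, out_y, 1)],
                gains=[(out_x, out_y)],
            )
        return opts

    raise AssertionError(case)  # pragma: no cover


# ---------------------------------------------------------------------------
# matrix filling
# ---------------------------------------------------------------------------

def compute_cell(
    a: GeneNode,
    b: GeneNode,
    matrix: dict[CellKey, DPCell],
    costs: CostParams,
    extant_adjacencies: set[tuple[str, str]],
    members: Optional[set[tuple[str, str]]] = None,
) -> DPCell:
    """Compute one cell from already-computed child cells."""

    def cell(u: GeneNode, v: GeneNode) -> DPCell:
        return matrix[cell_key(u, v)]

    values = []
    for state in (1, 0):
        opts = options(a, b, state, cell, costs, extant_adjacencies, members)
        values.append(min((o[0] for o in opts), default=INF))
    return DPCell(c1=values[0], c0=values[1])


def fill_matrix(
    cls: AdjacencyClass,
    costs: CostParams,
    extant_adjacencies: set[tuple[str, str]],
) -> dict[CellKey, DPCell]:
    """Fill all cells reachable from the class's root pair, children first.

    Iterative post-order over the pair DAG (the recursion is strictly
    size-decreasing, so it terminates on any valid input).
    """
    matrix: dict[CellKey, DPCell] = {}
    members = set(cls.members)
    stack: list[tuple[GeneNode, GeneNode, bool]] = [(cls.root_a, cls.root_b, False)]
    while stack:
        a, b, expanded = stack.pop()
        key = cell_key(a, b)
        if key in matrix:
            continue
        if expanded:
            matrix[key] = compute_cell(
                a, b, matrix, costs, extant_adjacencies, members
            )
            continue
        stack.append((a, b, True))
        for u, v in dependencies(a, b):
            if cell_key(u, v) not in matrix:
                stack.append((u, v, False))
    return matrix


def class_optimum(
    cls: AdjacencyClass, matrix: dict[CellKey, DPCell], costs: CostParams
) -> tuple[float, int]:
    """Optimal cost of a class and the root state achieving it.

    The root adjacency, if asserted, has no parent and is itself a gain:
    the optimum is ``min(c1(root) + C(gain), c0(root))``; ties go to the
    state without the adjacency.
    """
    root = matrix[cell_key(cls.root_a, cls.root_b)]
    with_adj = root.c1 + costs.gain
    if root.c0 <= with_adj:
        return root.c0, 0
    return with_adj, 1
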