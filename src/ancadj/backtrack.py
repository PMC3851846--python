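"""Recover one minimum-cost adjacency history from filled DP matrices.

Per class the root state is ``argmin{c1(root) + C(gain), c0(root)}`` (the
root adjacency has no parent, so asserting it costs a gain); choices are
then propagated top-down by re-applying each case's minimization.  Ties are
resolved deterministically and conservatively: the state without the
adjacency wins at the root, and among equal-cost resolutions the one
asserting fewer child adjacencies wins, then the earliest in the printed
order of the recurrences.
"""

from __future__ import annotations

from .model import (
    EXTANT, LOSS, OUTSIDE, SPECIATION,
    AdjacencyClass, AdjacencyRecord, CoDuplicationLink, CostParams, DPCell,
    EventRecord, GeneNode, History, TransferLink,
)
from .dp import CellKey, cell_key, class_optimum, donor_context, fill_matrix, options

__all__ = ["optimal_history", "reconstruct_history"]


def _location(u: GeneNode, v: GeneNode) -> tuple[str, int]:
    if u.species == OUTSIDE:  # pragma: no cover - normalized trees
        return v.species, v.slice_
    return u.species, u.slice_


def _in_genome(u: GeneNode, v: GeneNode) -> bool:
    return (u.event == SPECIATION and v.event == SPECIATION) or (
        u.event == EXTANT and v.event == EXTANT
    )


def optimal_history(
    classes: list[AdjacencyClass],
    matrices: list[dict[CellKey, DPCell]],
    costs: CostParams,
) -> History:
    """Backtrack all classes and assemble the union history."""
    history = History()
    extant = {a for cls in classes for a in cls.members}
    total = 0.0
    for cls, matrix in zip(classes, matrices):
        total += _backtrack_class(cls, matrix, costs, history, extant)
    history.total_cost = total
    return history


def _backtrack_class(
    cls: AdjacencyClass,
    matrix: dict[CellKey, DPCell],
    costs: CostParams,
    history: History,
    extant: set[tuple[str, str]],
) -> float:
    members = set(cls.members)

    def cell(u: GeneNode, v: GeneNode) -> DPCell:
        return matrix[cell_key(u, v)]

    value, root_state = class_optimum(cls, matrix, costs)
    if root_state == 1:
        sp, ts = _location(cls.root_a, cls.root_b)
        history.gains.append(
            EventRecord("Gain", sp, ts, cls.root_a.name, cls.root_b.name)
        )

    stack: list[tuple[GeneNode, GeneNode, int]] = [
        (cls.root_a, cls.root_b, root_state)
    ]
    seen: set[tuple[CellKey, int]] = set()
    while stack:
        u, v, state = stack.pop()
        key = (cell_key(u, v), state)
        if key in seen:
            continue
        seen.add(key)
        if state == 1 and u.event != LOSS and v.event != LOSS:
            sp, ts = _location(u, v)
            history.adjacencies.append(
                AdjacencyRecord(sp, ts, u.name, v.name, _in_genome(u, v))
            )
        target = cell(u, v).c1 if state else cell(u, v).c0
        opts = options(u, v, state, cell, costs, extant, members)
        if not opts:
            continue
        best = None
        for idx, opt in enumerate(opts):
            if opt[0] != target:
                continue
            rank = (sum(s for *_pair, s in opt[1]), idx)
            if best is None or rank < best[0]:
                best = (rank, opt)
        assert best is not None, "cell value not among its options"
        _, (cost, children, gains, breaks, link) = best
        for p, q in gains:
            sp, ts = _location(p, q)
            history.gains.append(EventRecord("Gain", sp, ts, p.name, q.name))
        for p, q in breaks:
            sp, ts = _location(p, q)
            history.breaks.append(EventRecord("Break", sp, ts, p.name, q.name))
        if link == "transfer" and state == 1:
            ctx = donor_context(u)
            donor_sp, donor_ts = ctx if ctx is not None else (u.species, u.slice_)
            history.transfer_links.append(
                TransferLink(
                    donor_species=donor_sp,
                    donor_slice=donor_ts,
                    recipient_species=u.species,
                    recipient_slice=u.slice_,
                    gene1=u.name,
                    gene2=v.name,
                )
            )
        elif link == "coduplication":
            history.coduplication_links.append(
                CoDuplicationLink(
                    species=u.species, slice_=u.slice_, gene1=u.name, gene2=v.name
                )
            )
        stack.extend(children)
    return value


def reconstruct_history(bundle, costs: CostParams = CostParams()):
    """Run the whole reconstruction on an input bundle.

    Subdivides the gene trees in place, builds the possible-homology
    classes, fills one DP matrix per class and backtracks a minimum-cost
    history.  Returns ``(history, classes)``.
    """
    from .classes import build_classes
    from .slicing import subdivide

    for tree in bundle.gene_trees:
        subdivide(tree, bundle.species_tree)
    classes = build_classes(bundle.adjacencies, bundle.gene_trees)
    extant = {a for cls in classes for a in cls.members}
    matrices = [fill_matrix(cls, costs, extant) for cls in classes]
    return optimal_history(classes, matrices, costs), classes
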