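"""Exhaustive minimum-cost history search on tiny adjacency classes.

Used in tests as the independent correctness reference for the dynamic
program.  Every subset of candidate ancestral adjacencies is enumerated as a
putative history and scored directly from the propagation rules: a present
adjacency with no rule parent is a gain, a rule descendant slot left empty
by a present adjacency is a breakage.  Parent/child attribution (which copy
an adjacency follows through a duplication, which junction parents a shared
child) is itself minimized by an exact assignment between propagation slots
and present adjacencies; simultaneous-vs-ordered resolution of double
duplications is enumerated exhaustively.

Two modelling rules mirror the propagation semantics exactly:

* a SpeciationOut leaves the donor genome untouched, so the adjacency state
  is *continuous* through the inside continuation: pairs linked through such
  steps share one presence state, and only the topmost pair of a linked
  group can be gained or parented from above;
* a Transfer arrival paired with a passive partner is identified with the
  pair at the arrival's child (the pair cannot be recursed and roots its own
  class).

The scoring shares no code with the dynamic program -- it re-derives the
propagation rules from their definitions -- which is what makes the
equivalence test meaningful.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import (
    DUPLICATION, EXTANT, LOSS, NO_EVENT, SPECIATION, SPECIATION_OUT, TRANSFER,
    AdjacencyClass, CostParams, GeneNode,
)

__all__ = ["brute_force_min_cost", "OracleSizeError"]

_BIG = 1e9
_PASSIVE = (NO_EVENT, SPECIATION, EXTANT, SPECIATION_OUT)


class OracleSizeError(RuntimeError):
    """The candidate pair set is too large for exhaustive enumeration."""


def _specout_context(t: GeneNode):
    node = t.parent
    while node is not None:
        if node.event == SPECIATION_OUT:
            return (node.species, node.slice_)
        node = node.parent
    return None


def _compatible_transfers(u: GeneNode, v: GeneNode) -> bool:
    if u.species != v.species or u.slice_ != v.slice_:
        return False
    cu, cv = _specout_context(u), _specout_context(v)
    if cu is None and cv is None:
        return True
    return cu is not None and cv is not None and cu == cv


def _rep(u: GeneNode, v: GeneNode) -> tuple[GeneNode, GeneNode]:
    """Collapse a Transfer paired with a passive partner onto the arrival's
    child (the identification the recurrences use for such pairs)."""
    while True:
        if u.event == TRANSFER and v.event in _PASSIVE:
            u = u.children[0]
        elif v.event == TRANSFER and u.event in _PASSIVE:
            v = v.children[0]
        else:
            return u, v


def _key(u: GeneNode, v: GeneNode):
    return (u.uid, v.uid) if u.uid < v.uid else (v.uid, u.uid)


def _inside_out(so: GeneNode) -> tuple[GeneNode, GeneNode]:
    inside = [c for c in so.children if c.species == so.species][0]
    away = [c for c in so.children if c.species != so.species][0]
    return inside, away


class _Slot:
    """One propagation offer of a present adjacency: the set of child pairs
    it may propagate to; if breakable, leaving it empty costs a breakage."""

    __slots__ = ("candidates", "breakable")

    def __init__(self, candidates, breakable):
        self.candidates = candidates
        self.breakable = breakable


def _junction_modes(u: GeneNode, v: GeneNode):
    """Possible slot structures of a present pair, per the propagation rules.

    Returns a list of alternatives (usually one); double duplications have
    up to four (each duplication first; the two copy matchings when
    simultaneous).  Inside continuations of SpeciationOut steps carry no
    slot: their state is handled by the continuity groups.
    """
    eu, ev = u.event, v.event
    if eu == LOSS or ev == LOSS:
        return [[]]  # the adjacency dies with the gene, for free
    if eu == EXTANT and ev == EXTANT:
        return [[]]
    if eu == DUPLICATION and ev == DUPLICATION:
        u1, u2 = u.children
        v1, v2 = v.children
        modes = [
            [_Slot([(u, v1), (u, v2)], True)],
            [_Slot([(u1, v), (u2, v)], True)],
        ]
        if u.species == v.species and u.slice_ == v.slice_:
            modes.append([_Slot([(u1, v1)], True), _Slot([(u2, v2)], True)])
            modes.append([_Slot([(u1, v2)], True), _Slot([(u2, v1)], True)])
        return modes
    if ev == DUPLICATION:
        d1, d2 = v.children
        return [[_Slot([(u, d1), (u, d2)], True)]]
    if eu == DUPLICATION:
        d1, d2 = u.children
        return [[_Slot([(d1, v), (d2, v)], True)]]
    if eu == TRANSFER and ev == TRANSFER:
        return [[_Slot([(u.children[0], v.children[0])], True)]]
    if eu == SPECIATION_OUT and ev == SPECIATION_OUT:
        out_u = _inside_out(u)[1]
        out_v = _inside_out(v)[1]
        if (
            out_u.event == TRANSFER
            and out_v.event == TRANSFER
            and _compatible_transfers(out_u, out_v)
        ):
            return [[_Slot([(out_u, out_v)], True)]]
        return [[]]  # unrelated departures: donor state just continues
    if ev == SPECIATION_OUT or eu == SPECIATION_OUT:
        return [[]]  # one-sided departure: inside state continues, no slot
    if eu == SPECIATION and ev == SPECIATION:
        u1, u2 = u.children
        by_sp = {c.species: c for c in v.children}
        return [[
            _Slot([(u1, by_sp[u1.species])], True),
            _Slot([(u2, by_sp[u2.species])], True),
        ]]
    if eu == NO_EVENT and ev == NO_EVENT:
        return [[_Slot([(u.children[0], v.children[0])], True)]]
    if eu == NO_EVENT:
        return [[_Slot([(u.children[0], v)], True)]]
    if ev == NO_EVENT:
        return [[_Slot([(u, v.children[0])], True)]]
    raise RuntimeError(f"no propagation rule for ({eu}, {ev})")


def _normalize_slots(slots, universe, foreign):
    """Map slot candidates through the pass-through identification, drop
    absorbing candidates (a Loss, or an extant adjacency owned by another
    class: free absorption, the slot becomes unbreakable) and candidates
    outside the candidate universe (unexplainable: slot stays breakable)."""
    out = []
    for slot in slots:
        cands = []
        breakable = slot.breakable
        for p, q in slot.candidates:
            if p.event == LOSS or q.event == LOSS:
                breakable = False  # following the lost copy is free
                continue
            p, q = _rep(p, q)
            key = _key(p, q)
            if key in foreign:
                breakable = False  # another class explains this adjacency
                continue
            if key in universe:
                cands.append(key)
        if cands or breakable:
            out.append(_Slot(cands, breakable))
    return out


def _build_universe(cls: AdjacencyClass, extant: set[tuple[str, str]]):
    """Candidate pairs, plus the keys of extant adjacencies owned by other
    classes (neutral here: absorbed for free, never enumerated)."""
    nodes_a = list(cls.root_a.iter_subtree())
    nodes_b = list(cls.root_b.iter_subtree())
    member_set = set(cls.members)
    universe: dict[tuple[int, int], tuple[GeneNode, GeneNode]] = {}
    foreign: set[tuple[int, int]] = set()
    for u in nodes_a:
        for v in nodes_b:
            if u is v or u.species != v.species:
                continue
            if u.event == LOSS or v.event == LOSS:
                continue
            if u.event == TRANSFER and v.event in _PASSIVE:
                continue  # identified with its pass-through representative
            if v.event == TRANSFER and u.event in _PASSIVE:
                continue
            if u.event == TRANSFER and v.event == TRANSFER:
                if not _compatible_transfers(u, v):
                    continue
            if u.event == EXTANT and v.event == EXTANT:
                pair = (u.name, v.name) if u.name < v.name else (v.name, u.name)
                if pair in extant and pair not in member_set:
                    foreign.add(_key(u, v))
                    continue
            universe[_key(u, v)] = (u, v)
    return universe, foreign


def _continuity_groups(universe):
    """Group pair keys whose states are locked together by inside-of-
    SpeciationOut continuity.  Returns (group id per key, members per group,
    top key per group)."""
    parent = {k: k for k in universe}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    links = {}  # key -> its specout-parent key (upward)
    for key, (u, v) in universe.items():
        for node, other in ((u, v), (v, u)):
            p = node.parent
            if (
                p is not None
                and p.event == SPECIATION_OUT
                and node.species == p.species  # inside child
            ):
                up = _key(p, other)
                if up in universe:
                    links[key] = up
                    ru, rk = find(up), find(key)
                    if ru != rk:
                        parent[rk] = ru
                    break
    groups: dict = {}
    for k in universe:
        groups.setdefault(find(k), []).append(k)
    tops = {}
    for gid, members in groups.items():
        candidates = [k for k in members if k not in links]
        # continuity chains have a unique upward-maximal pair
        tops[gid] = candidates[0] if candidates else members[0]
    key_group = {k: find(k) for k in universe}
    return key_group, groups, tops


def _score(present_groups, state, costs):
    """Exact cost of one history: assignment between propagation slots and
    the gainable (top) pairs of present groups.

    A continuity group's event resolutions are emitted once: full junctions
    for chain-bottom members, only the outgoing slot for higher members
    (which are SpeciationOut stages of the same lineage pair).
    """
    groups, tops, junctions, universe, key_group, foreign = state
    top_keys = sorted(tops[gid] for gid in present_groups)
    universe_keys = set(universe)
    # One adjacency lineage per group: walk from the top stage, pairing
    # inside continuations the way the recurrences do, emitting an outgoing
    # slot per linked double departure and the bottom stage's full junction.
    fixed_slots, emitters = [], []
    for gid in present_groups:
        key = tops[gid]
        while True:
            u, v = universe[key]
            eu, ev = u.event, v.event
            if eu == SPECIATION_OUT and ev == SPECIATION_OUT:
                in_u, out_u = _inside_out(u)
                in_v, out_v = _inside_out(v)
                if (
                    out_u.event == TRANSFER
                    and out_v.event == TRANSFER
                    and _compatible_transfers(out_u, out_v)
                ):
                    fixed_slots.append(_Slot([(out_u, out_v)], True))
                nxt = in_u, in_v
            elif eu == SPECIATION_OUT and ev != DUPLICATION:
                nxt = _inside_out(u)[0], v
            elif ev == SPECIATION_OUT and eu != DUPLICATION:
                nxt = u, _inside_out(v)[0]
            else:
                emitters.append(junctions[key])
                break
            nk = _key(*nxt)
            if nk not in universe_keys or nk in foreign:
                break  # continuation absorbed (loss or foreign adjacency)
            key = nk
    best = _BIG
    for choice in product(*emitters):
        slots = list(fixed_slots)
        for mode in choice:
            slots.extend(mode)
        slots = _normalize_slots(slots, universe_keys, foreign)
        for slot in slots:
            slot.candidates = sorted(
                {tops[key_group[c]] for c in slot.candidates}
            )
        ns, nc = len(slots), len(top_keys)
        size = ns + nc
        if size == 0:
            best = min(best, 0.0)
            continue
        mat = np.full((size, size), _BIG)
        for i, slot in enumerate(slots):
            for j, key in enumerate(top_keys):
                if key in slot.candidates:
                    mat[i, j] = 0.0
            mat[i, nc + i] = costs.breakage if slot.breakable else 0.0
        for j in range(nc):
            mat[ns + j, j] = costs.gain
        mat[ns:, nc:] = 0.0
        rows, cols = linear_sum_assignment(mat)
        best = min(best, float(mat[rows, cols].sum()))
    return best


def brute_force_min_cost(
    cls: AdjacencyClass,
    costs: CostParams,
    extant_adjacencies: Optional[set[tuple[str, str]]] = None,
    max_free: int = 14,
) -> float:
    """Minimum history cost of one class by full enumeration.

    Enumerates every subset of candidate ancestral pair groups (extant pairs
    are fixed by the input; ``extant_adjacencies`` is the full input set,
    defaulting to the class's own members) and returns the minimum
    propagation-rule score.  Refuses when more than ``max_free`` groups are
    free (exponential blowup guard).
    """
    extant = set(cls.members) if extant_adjacencies is None else extant_adjacencies
    universe, foreign = _build_universe(cls, extant)
    key_group, groups, tops = _continuity_groups(universe)
    member_set = set(cls.members)

    forced_present, forced_absent, free = set(), set(), []
    for key, (u, v) in universe.items():
        if u.event == EXTANT and v.event == EXTANT:
            pair = (u.name, v.name) if u.name < v.name else (v.name, u.name)
            gid = key_group[key]
            if pair in member_set:
                forced_present.add(gid)
            else:
                forced_absent.add(gid)
    if forced_present & forced_absent:  # pragma: no cover - cannot happen
        raise RuntimeError("contradictory continuity constraints")
    for gid in groups:
        if gid not in forced_present and gid not in forced_absent:
            free.append(gid)
    if len(free) > max_free:
        raise OracleSizeError(
            f"{len(free)} free candidate pair groups exceed the enumeration "
            f"guard ({max_free})"
        )

    junctions = {key: _junction_modes(*universe[key]) for key in universe}
    state = (groups, tops, junctions, universe, key_group, foreign)
    base = sorted(forced_present)
    best = _BIG
    free = sorted(free)
    for r in range(len(free) + 1):
        for combo in combinations(free, r):
            score = _score(base + list(combo), state, costs)
            if score < best:
                best = score
    return best
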