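"""Forward simulation of gene content and adjacency evolution.

Generates the three inputs of the reconstruction (dated species tree,
reconciled gene trees, extant adjacencies) together with the ground-truth
history and a structured event log, so the whole pipeline is testable
without external data.

The generator evolves a circular root genome slice by slice down a random
ranked species tree.  Per gene and slice a duplication, transfer or loss may
occur; per adjacency and slice a breakage; per genome and slice a gain of a
random adjacency.  Duplications are tandem with probability 1/2 (the copy is
created adjacent to the original, a new adjacency); transfers route through
a SpeciationOut departure and a Transfer arrival in a uniformly
later-or-equal slice, optionally taking a contiguous block of 2-4 genes
whose internal adjacencies travel with it (the ground truth for co-transfer
cluster detection).  A lost gene's adjacencies vanish freely -- loss is not
a rearrangement and the model does not rejoin the lost gene's neighbours.

One seeded random stream drives everything: equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .io import InputBundle
from .model import (
    DUPLICATION, EXTANT, LOSS, SPECIATION, SPECIATION_OUT, TRANSFER,
    AdjacencyRecord, DatedSpeciesTree, EventRecord, GeneNode, History,
    ReconciledGeneTree, SpeciesNode, ValidationError,
)

__all__ = ["SimParams", "simulate", "random_species_tree"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Rates are per slice: ``p_dup``/``p_transfer``/``p_loss`` per gene,
    ``p_break`` per adjacency, ``p_gain`` per genome (one random extra
    adjacency).  ``p_block`` is the probability that a transfer takes a
    contiguous run of 2-4 genes instead of a single gene.
    """

    n_species: int = 10
    root_genes: int = 50
    p_dup: float = 0.02
    p_transfer: float = 0.02
    p_loss: float = 0.02
    p_gain: float = 0.01
    p_break: float = 0.02
    p_block: float = 0.25
    p_tandem: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError("need at least 2 species")
        if self.root_genes < 1:
            raise ValidationError("need at least 1 root gene")
        for name in ("p_dup", "p_transfer", "p_loss", "p_gain", "p_break",
                     "p_block", "p_tandem"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} is not a probability")
        if self.p_dup + self.p_transfer + self.p_loss > 1.0:
            raise ValidationError(
                "per-gene event probabilities must sum to at most 1"
            )


def random_species_tree(n_species: int, rng: random.Random) -> DatedSpeciesTree:
    """A uniformly random ranked topology on ``n_species`` leaves.

    Internal nodes are named ``N<rank>``, leaves ``S1..Sn`` in traversal
    order; only the rank order matters to the reconstruction.
    """
    root = SpeciesNode("N0", 0)
    pendants = [SpeciesNode("", None), SpeciesNode("", None)]
    for p in pendants:
        p.parent = root
        root.children.append(p)
    for rank in range(1, n_species - 1):
        node = rng.choice(pendants)
        pendants.remove(node)
        node.name, node.rank = f"N{rank}", rank
        for _ in range(2):
            child = SpeciesNode("", None)
            child.parent = node
            node.children.append(child)
            pendants.append(child)
    # name leaves in deterministic traversal order
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            counter += 1
            node.name = f"S{counter}"
        stack.extend(reversed(node.children))
    return DatedSpeciesTree(root)


class _Live:
    """A live gene lineage: where to attach its next materialized node."""

    __slots__ = ("key", "family", "parent")

    def __init__(self, key: int, family: str, parent: GeneNode | None):
        self.key = key
        self.family = family
        self.parent = parent


class _Genome:
    """Gene content and adjacency graph of one evolving lineage."""

    __slots__ = ("genes", "adjs")

    def __init__(self):
        self.genes: dict[int, _Live] = {}
        self.adjs: dict[tuple[int, int], None] = {}

    @staticmethod
    def edge(k1: int, k2: int) -> tuple[int, int]:
        return (k1, k2) if k1 < k2 else (k2, k1)

    def add_adj(self, k1: int, k2: int) -> bool:
        e = self.edge(k1, k2)
        if k1 == k2 or e in self.adjs:
            return False
        self.adjs[e] = None
        return True

    def drop_gene(self, key: int) -> None:
        del self.genes[key]
        for e in [e for e in self.adjs if key in e]:
            del self.adjs[e]

    def neighbours(self, key: int) -> list[int]:
        out = [b if a == key else a for a, b in self.adjs if key in (a, b)]
        return sorted(out)


class _Simulation:
    def __init__(self, params: SimParams):
        self.p = params
        self.rng = random.Random(params.seed)
        self.sptree = random_species_tree(params.n_species, self.rng)
        self.key_counter = 0
        self.name_counters: dict[str, int] = {}
        self.family_roots: dict[str, GeneNode] = {}
        self.branch_genomes: dict[str, _Genome] = {}
        self.arrivals: dict[tuple[str, int], list[dict]] = {}
        self.truth = History()
        self.event_log: list[dict] = []

    # -- plumbing ----------------------------------------------------------
    def new_live(self, family: str, parent: GeneNode | None) -> _Live:
        self.key_counter += 1
        return _Live(self.key_counter, family, parent)

    def materialize(self, live: _Live, event: str, species: str, t: int) -> GeneNode:
        n = self.name_counters.get(live.family, 0) + 1
        self.name_counters[live.family] = n
        node = GeneNode(f"{live.family}_{n}", event, species, t)
        if live.parent is None:
            self.family_roots[live.family] = node
        else:
            live.parent.add_child(node)
        return node

    def log(self, kind: str, species: str, t: int, k1: int, k2: int) -> None:
        rec = EventRecord(kind, species, t, f"g{min(k1, k2)}", f"g{max(k1, k2)}")
        (self.truth.gains if kind == "Gain" else self.truth.breaks).append(rec)

    # -- main loop ---------------------------------------------------------
    def run(self) -> tuple[InputBundle, History, list[dict]]:
        s = self.p.n_species
        rank_to_node = {
            n.rank: n for n in self.sptree.nodes.values() if not n.is_leaf
        }
        root_genome = self.init_root_genome()
        for t in range(s - 1):
            node = rank_to_node.get(t)
            if node is not None:
                genome = (
                    root_genome if node.parent is None
                    else self.branch_genomes.pop(node.name)
                )
                self.speciate(node, t, genome)
            active = sorted(
                name for name in self.sptree.nodes
                if t in self.sptree.branch_slices(name)
            )
            for name in active:
                self.gene_events(name, t)
            for name in active:
                self.deliver_arrivals(name, t)
            for name in active:
                self.breaks_and_gains(name, t)
        return self.finish()

    def init_root_genome(self) -> _Genome:
        genome = _Genome()
        lives = [
            self.new_live(f"F{i + 1}", None) for i in range(self.p.root_genes)
        ]
        for live in lives:
            genome.genes[live.key] = live
        root_name = self.sptree.root.name
        keys = [lv.key for lv in lives]
        if len(keys) >= 2:
            edges = list(zip(keys, keys[1:]))
            if len(keys) >= 3:
                edges.append((keys[-1], keys[0]))
            for k1, k2 in edges:
                if genome.add_adj(k1, k2):
                    self.log("Gain", root_name, 0, k1, k2)
        return genome

    def speciate(self, node: SpeciesNode, t: int, genome: _Genome) -> None:
        spec_nodes: dict[int, GeneNode] = {}
        for key in sorted(genome.genes):
            live = genome.genes[key]
            spec_nodes[key] = self.materialize(live, SPECIATION, node.name, t)
        for k1, k2 in sorted(genome.adjs):
            n1, n2 = spec_nodes[k1].name, spec_nodes[k2].name
            if n2 < n1:
                n1, n2 = n2, n1
            self.truth.adjacencies.append(
                AdjacencyRecord(node.name, t, n1, n2, True)
            )
        for child in node.children:
            child_genome = _Genome()
            mapping: dict[int, int] = {}
            for key in sorted(genome.genes):
                live = self.new_live(genome.genes[key].family, spec_nodes[key])
                child_genome.genes[live.key] = live
                mapping[key] = live.key
            for k1, k2 in genome.adjs:
                child_genome.add_adj(mapping[k1], mapping[k2])
            self.branch_genomes[child.name] = child_genome

    # -- per-slice events --------------------------------------------------
    def gene_events(self, branch: str, t: int) -> None:
        p, rng = self.p, self.rng
        genome = self.branch_genomes[branch]
        for key in sorted(genome.genes):
            live = genome.genes.get(key)
            if live is None:
                continue
            r = rng.random()
            if r < p.p_dup:
                self.duplicate(genome, live, branch, t)
            elif r < p.p_dup + p.p_transfer:
                self.transfer(genome, live, branch, t)
            elif r < p.p_dup + p.p_transfer + p.p_loss:
                self.materialize(live, LOSS, branch, t)
                genome.drop_gene(key)

    def duplicate(self, genome: _Genome, live: _Live, branch: str, t: int) -> None:
        rng = self.rng
        dup = self.materialize(live, DUPLICATION, branch, t)
        live.parent = dup  # first copy keeps the genome slot
        copy = self.new_live(live.family, dup)
        genome.genes[copy.key] = copy
        if rng.random() < self.p.p_tandem:
            nbrs = genome.neighbours(live.key)
            if len(nbrs) == 1:
                move = [nbrs[0]] if rng.random() < 0.5 else []
            else:
                move = [n for n in nbrs if rng.random() < 0.5]
                if nbrs and len(move) == len(nbrs):
                    move.pop(rng.randrange(len(move)))
            for n in move:
                del genome.adjs[genome.edge(live.key, n)]
                genome.add_adj(copy.key, n)
            if genome.add_adj(live.key, copy.key):
                self.log("Gain", branch, t, live.key, copy.key)
        else:
            sites = sorted(e for e in genome.adjs if copy.key not in e)
            if sites:
                u, v = rng.choice(sites)
                del genome.adjs[(u, v)]
                self.log("Break", branch, t, u, v)
                for a, b in ((u, copy.key), (copy.key, v)):
                    if genome.add_adj(a, b):
                        self.log("Gain", branch, t, a, b)

    def transfer(self, genome: _Genome, live: _Live, branch: str, t: int) -> None:
        p, rng, s = self.p, self.rng, self.p.n_species
        block = [live.key]
        if rng.random() < p.p_block:
            size = rng.randint(2, 4)
            while len(block) < size:
                ends = [block[0], block[-1]]
                options = []
                for end in ends:
                    options += [
                        (end, n) for n in genome.neighbours(end) if n not in block
                    ]
                if not options:
                    break
                end, nxt = rng.choice(sorted(options))
                if end == block[0]:
                    block.insert(0, nxt)
                else:
                    block.append(nxt)
        t2 = rng.randint(t, s - 2)
        recipients = sorted(
            name for name in self.sptree.nodes
            if t2 in self.sptree.branch_slices(name) and name != branch
        )
        if not recipients:
            return
        target = rng.choice(recipients)
        internal = [
            (i, j)
            for i in range(len(block))
            for j in range(i + 1, len(block))
            if genome.edge(block[i], block[j]) in genome.adjs
        ]
        away_lives = []
        for key in block:
            gene = genome.genes[key]
            so = self.materialize(gene, SPECIATION_OUT, branch, t)
            gene.parent = so  # donor copy stays in place
            away_lives.append(self.new_live(gene.family, so))
        self.arrivals.setdefault((target, t2), []).append(
            {
                "lives": away_lives,
                "internal": internal,
                "donor": (branch, t),
            }
        )

    def deliver_arrivals(self, branch: str, t: int) -> None:
        rng = self.rng
        genome = self.branch_genomes[branch]
        for arr in self.arrivals.pop((branch, t), []):
            old_adjs = sorted(genome.adjs)
            new_keys, names = [], []
            for live in arr["lives"]:
                node = self.materialize(live, TRANSFER, branch, t)
                live.parent = node
                genome.genes[live.key] = live
                new_keys.append(live.key)
                names.append(node.name)
            maintained = []
            for i, j in arr["internal"]:
                genome.add_adj(new_keys[i], new_keys[j])
                maintained.append(tuple(sorted((names[i], names[j]))))
            if old_adjs:
                u, v = rng.choice(old_adjs)
                del genome.adjs[(u, v)]
                self.log("Break", branch, t, u, v)
                for a, b in ((u, new_keys[0]), (new_keys[-1], v)):
                    if genome.add_adj(a, b):
                        self.log("Gain", branch, t, a, b)
            else:
                others = sorted(k for k in genome.genes if k not in new_keys)
                if others and genome.add_adj(others[0], new_keys[0]):
                    self.log("Gain", branch, t, others[0], new_keys[0])
            self.event_log.append(
                {
                    "type": "transfer",
                    "donor": arr["donor"],
                    "recipient": (branch, t),
                    "genes": sorted(names),
                    "maintained_adjacencies": sorted(maintained),
                }
            )

    def breaks_and_gains(self, branch: str, t: int) -> None:
        p, rng = self.p, self.rng
        genome = self.branch_genomes[branch]
        for edge in sorted(genome.adjs):
            if rng.random() < p.p_break:
                del genome.adjs[edge]
                self.log("Break", branch, t, *edge)
        if rng.random() < p.p_gain and len(genome.genes) >= 2:
            k1, k2 = rng.sample(sorted(genome.genes), 2)
            if genome.add_adj(k1, k2):
                self.log("Gain", branch, t, k1, k2)

    # -- wrap-up -----------------------------------------------------------
    def finish(self) -> tuple[InputBundle, History, list[dict]]:
        s = self.p.n_species
        extant_adjacencies: list[tuple[str, str]] = []
        for leaf in sorted(self.sptree.leaves, key=lambda n: n.name):
            genome = self.branch_genomes.pop(leaf.name)
            leaf_nodes: dict[int, GeneNode] = {}
            for key in sorted(genome.genes):
                leaf_nodes[key] = self.materialize(
                    genome.genes[key], EXTANT, leaf.name, s - 1
                )
            for k1, k2 in sorted(genome.adjs):
                n1, n2 = sorted((leaf_nodes[k1].name, leaf_nodes[k2].name))
                extant_adjacencies.append((n1, n2))
                self.truth.adjacencies.append(
                    AdjacencyRecord(leaf.name, s - 1, n1, n2, True)
                )
        self.truth.total_cost = float(
            len(self.truth.gains) + len(self.truth.breaks)
        )
        trees = [
            ReconciledGeneTree(self.family_roots[fam], fam)
            for fam in sorted(self.family_roots, key=lambda f: int(f[1:]))
        ]
        bundle = InputBundle(self.sptree, trees, sorted(extant_adjacencies))
        return bundle, self.truth, self.event_log


def simulate(params: SimParams) -> tuple[InputBundle, History, list[dict]]:
    """Run the generator; returns ``(inputs, true history, event log)``.

    The true history's cost counts every logged gain and breakage at unit
    costs (root-genome adjacencies are origination gains); it is an upper
    bound on the parsimony optimum, attained when no signal is lost.
    """
    return _Simulation(params).run()
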