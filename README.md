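# ancadj — ancestral gene adjacencies along a dated species phylogeny

`ancadj` reconstructs the gene *adjacencies* (pairs of immediately
consecutive genes) of ancestral genomes from reconciled gene trees that
account for gene origination, speciation, duplication, **lateral transfer**
and loss.  It is aimed at comparative genomics of prokaryotes and other
lineages where transfer is frequent: given a dated species tree, one
reconciled tree per gene family and the extant adjacencies, it infers a
minimum-cost history of adjacency **gains** and **breakages**, reports how
circular each ancestral genome looks (degree distributions, adjacency/gene
ratios), and detects clusters of co-transferred and co-duplicated genes.

## Model

The species tree is rooted, binary and *dated*: its internal nodes (the
ancestral genomes) are totally ordered, and consecutive nodes delimit *time
slices* (`s − 1` of them for `s` extant genomes).  Each gene-tree node
carries a species branch, a time slice and an event label among
`Extant`, `Spec` (speciation), `SpecOut` (speciation out of the species
tree — a transfer departure into an unsampled lineage), `Trans` (transfer
re-entry), `Dup`, `Loss`; unary `NoEvent` nodes mark slice crossings.

An adjacency between genes *a* and *b* propagates to their descendants by
deterministic rules (it follows one copy through a duplication for free,
both descendant genomes through a speciation, the inside continuation and
— for a shared departure — the outgoing copies through a `SpecOut`, the
arrival children through matching transfers, and dies freely with a lost
gene).  A *history* is a set of extant and ancestral adjacencies; an
adjacency with no rule parent is a **gain**, a present adjacency whose rule
descendant is absent is a **breakage**, and the cost of a history is

        cost = |gains| · C(gain) + |breaks| · C(break)        (default 1, 1)

Extant adjacencies are partitioned into *possible-homology* classes (pairs
of ancestral genes that could have carried a common ancestral adjacency);
each class is solved exactly by a dynamic program over pairs of gene
subtrees, computing for every pair `(a, b)` on one species branch the
minimum costs `c₁(a, b)` / `c₀(a, b)` of a history with / without an
adjacency between them, by case analysis on the event pair `(E(a), E(b))`.
Backtracking recovers one optimal history.  The whole computation is
polynomial; in the no-event limit it reduces to Sankoff–Rousseau small
parsimony on the presence/absence character.

## Worked example

A two-family, four-species instance ships with the package
(`src/ancadj/data/worked_example/`): species tree `((A,B)e,(C,D)f)r` dated
`r=0, e=1, f=2`; family 1 duplicates in tandem in the branch to A and is
lost in the branch to C; both families co-transfer from the branch to B
into the branch to C; the extant adjacencies are the tandem pair in A and
one conserved pair each in B and D.

```bash
ancadj reconstruct \
    --species-tree src/ancadj/data/worked_example/species.nwk \
    --ranks        src/ancadj/data/worked_example/ranks.tsv \
    --gene-trees   src/ancadj/data/worked_example/gene_trees.nwk \
    --adjacencies  src/ancadj/data/worked_example/adjacencies.tsv \
    --out-dir      out/
```

prints

```
cost 3: 2 gains, 1 breakages (2 classes)
```

meaning: the three extant adjacencies are explained by a history of total
cost 3 — one gain for the tandem pair, one gain of an ancestral adjacency
at the root that propagates to B and D, and one breakage of its transferred
copy in the branch to C (the transferred genes are present in C but no
longer adjacent).  `out/` then contains the located ancestral adjacencies
(`adjacencies.tsv`), the gain/breakage events (`events.tsv`), per-genome
degree and adjacency/gene tables, and the co-transfer/co-duplication
cluster table.

A synthetic data set with ground truth comes from the built-in forward
simulator:

```bash
ancadj simulate --species 36 --root-genes 1000 --seed 1 --out-dir sim/
ancadj reconstruct --species-tree sim/species.nwk --ranks sim/ranks.tsv \
    --gene-trees sim/gene_trees.nwk --adjacencies sim/adjacencies.tsv \
    --out-dir sim_out/
```

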