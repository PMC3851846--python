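# Methods

## The model

Genomes are sets of genes plus a set of adjacencies (unordered, unoriented
gene pairs; no strand or chromosome assignment).  Evolution happens along a
rooted binary species tree whose internal nodes are totally ordered in time
(ranks `0..s−2`, root first).  The interval below the node of rank `i` is
time slice `i`; extant genes sit at level `s−1`.  The branch leading to a
node `X` spans slices `rank(parent(X)) .. rank(X)−1` (leaf branches down to
`s−2`), a speciation gene node at `X` carries slice `rank(X)`, and every
other event carries a slice within its branch's span.  Transfers are
modelled through unsampled lineages: a `SpecOut` node forks an inside
continuation and an outgoing copy, which re-enters at a `Trans` node in the
recipient branch at the same or a later slice.  Lineages do not diversify
outside the species tree; reconciliations that contain such nodes are
pruned first, cutting the affected trees into independent pieces.

A history is scored by its adjacency gains and breakages only — gene
origination, duplication, transfer and loss are inputs fixed by the
reconciled trees, and a gene loss silently removes its adjacencies (loss is
not a rearrangement).

## Algorithm

1. **Subdivision** inserts unary `NoEvent` nodes at the slices strictly
   between a parent and child, so every in-tree step spans at most one
   boundary (nothing is inserted on outside excursions).  Splicing the
   `NoEvent` nodes back out recovers the input exactly.
2. **Classes.**  For an extant adjacency `xy`, a *covering pair* is a pair
   of ancestors `(u, v)` of `x` and `y` on one species branch, with
   disjoint subtrees, whose descent paths carry identical transfer
   signatures (the sequence of departure/arrival coordinates) and from
   which the recurrences can actually couple `x` with `y` (verified by an
   explicit descent walk).  Adjacencies sharing a covering pair are
   possibly homologous; the transitive closure partitions the input, each
   class rooting at the earliest common covering pair (ties broken by node
   name).  When no single pair covers a whole component — possible for
   same-family adjacencies, whose roots must have disjoint subtrees — the
   component is split greedily, largest coverable subset first.  Extant
   adjacencies owned by a sibling split class are *neutral* inside a
   class's matrix (a free `(0,0)` cell), so each gain is charged exactly
   once.
3. **Dynamic program.**  For each class, cells `c₁/c₀(a, b)` are filled
   lazily from the root pair by case analysis on `(E(a), E(b))`:
   extant pairs are fixed by the input; a loss absorbs the adjacency for
   free; double `NoEvent` steps and matching transfer arrivals allow a
   gain or breakage; a duplication resolves first against an unchanged
   partner (the adjacency follows one copy freely, both with a gain, none
   with a breakage); double duplications take the best of either ordering
   and of the 16 simultaneous configurations (every subset of the four
   child pairs, costed against the better of the two copy matchings); a
   speciation propagates to both descendant genomes; a `SpecOut` passes the
   donor state through unchanged, and a *shared* double departure (same
   departure and arrival coordinates on both sides) additionally offers
   the adjacency to the outgoing pair.  A `Trans` paired with a passive
   partner roots its own class and passes through to the arrival's child.
   A `NoEvent` lagging strictly behind its partner's slice advances first,
   which keeps co-departures aligned.
4. **Backtracking** picks `argmin{c₁(root)+C(gain), c₀(root)}` per class
   and re-applies each case's minimization top-down.  Among equal-cost
   options the resolution asserting fewer child adjacencies wins, then the
   earliest in case order; a root tie goes to the state without the
   adjacency.  Consequently the reported history is the conservative one
   among co-optima.  Recomputing the cost from the returned event lists
   always equals the sum of class optima (asserted in the tests).

The matrix for a class has at most `|T₁|·|T₂|` cells; in practice the
lazy filling visits a near-linear number because only same-branch pairs
couple.  The bundled 36-genome / 1000-family demonstration runs in a few
minutes on one CPU.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `C(gain)` | cost of an adjacency gain | 1 |
| `C(break)` | cost of an adjacency breakage | 1 |

Equal costs minimize the plain number of rearrangements and are the
setting used everywhere; the recurrences accept any non-negative finite
pair.

## The synthetic-data generator

`ancadj.simulate` evolves a circular root genome forward, slice by slice,
down a uniformly random ranked species tree.  Per slice: each gene
duplicates with `p_dup` (tandem with probability ½, creating the copy
adjacency; otherwise the copy is inserted into a random adjacency — one
breakage, two gains), transfers with `p_transfer` (a contiguous block of
2–4 genes with probability `p_block`; the donor keeps its copy, the block's
internal adjacencies travel free, and the block is inserted into a random
recipient adjacency), or is lost with `p_loss` (its adjacencies vanish
freely — the neighbours are *not* rejoined); each adjacency breaks with
`p_break`; each genome gains one random adjacency with `p_gain`.  Defaults
(`10` species, `50` root genes, rates `0.01–0.02` per slice) keep extant
genomes recognizably circular while exercising every event type; the scale
demonstration uses 36 species, 1000 families and per-slice rates of
`0.002–0.003`, which yields a few thousand events over the tree — the
regime of a bacterial phylum-level dataset.

What the generator does **not** emulate: sequence evolution and gene-tree
estimation error (input trees are always correct), rejoining of a lost
gene's neighbours (so sustained loss fragments genomes, whereas real
chromosomes stay circular), replacement of a homolog by a transferred
copy, and any correlation between events beyond block transfers.  Passing
tests therefore show the *inference machinery* is exact for the model, not
that real reconciliations are error-free.

Ground truth: the generator returns the true history (snapshots of every
ancestral genome, all gain/breakage events — root-genome adjacencies count
as origination gains) and a structured event log used to verify co-transfer
cluster detection.  One seeded stream drives everything; equal seeds give
byte-identical output files.

## Numerical and degenerate-input choices

* Infinity is `float('inf')`: absorbing under addition, never emitted.
* All costs are exact floating-point sums of `C(gain)`/`C(break)`; the
  oracle comparison is therefore exact equality, not a tolerance.
* Transfer arrivals at (possibly pruned) tree roots have no departure
  context; two such arrivals at the same branch and slice are treated as
  one event, the best available evidence.
* A `SpecOut` whose outgoing lineage dies outside is spliced away during
  normalization; unary outside nodes are collapsed so a departure's
  outgoing child is its `Trans` re-entry.
* Duplicate input adjacencies collapse to one (the model has no adjacency
  copy number); self-adjacencies are rejected.

## Verification

The test suite checks, besides unit behaviour: exact agreement of the
dynamic program with an independent exhaustive oracle (subset enumeration
over candidate ancestral pairs scored directly from the propagation rules,
with slot/pair attribution solved by exact assignment) on more than a
hundred random instances at three cost settings; equality with an
independently coded Sankoff–Rousseau small parsimony on event-free
instances; the parsimony bound (inferred cost ≤ true simulated cost) on
every replicate; and exact recovery of all ancestral adjacencies when the
generator is run with no events.  The oracle deliberately shares no code
with the dynamic program.

## Known limitations

* One optimal history is reported; co-optima are neither enumerated nor
  sampled, and tie-breaking is intentionally conservative (an equal-cost
  history with more ancestral adjacencies and fewer gains may exist).
* Deep ancestors close to the root typically lack signal: their
  adjacency/gene ratio drops toward 0 and degree-0 genes dominate, as the
  scale demonstration's report tables show.
* Chained departures from one branch in one slice are paired with a
  partner's departures in tree order; the rare ambiguous pairings of
  stacked same-slice transfers are resolved deterministically, not
  optimized over.
* Adjacencies are unoriented and chromosomes are never assembled; degree
  statistics stand in for contiguity.
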