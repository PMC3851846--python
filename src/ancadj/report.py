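"""Summaries of a reconstructed history.

Degree distributions and adjacency/gene ratios measure how close each
(ancestral) genome is to the circular structure expected of a bacterial
chromosome: in a perfectly reconstructed circular genome every gene has
degree 2 and the adjacency/gene ratio is 1.  Cluster detection finds groups
of genes moved or copied together: adjacencies maintained through a single
transfer event (same donor and arrival coordinates) or through a
simultaneous duplication.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .model import (
    EXTANT, SPECIATION,
    DatedSpeciesTree, History, ReconciledGeneTree, ValidationError,
)

__all__ = [
    "genes_of_species", "degree_distribution", "adjacency_gene_ratio",
    "find_event_clusters", "GeneCluster", "write_report_tables",
]


def genes_of_species(
    trees: list[ReconciledGeneTree],
    species_tree: DatedSpeciesTree,
    species: str,
) -> list[str]:
    """Gene identifiers present in the genome at ``species``.

    For an internal species node these are the Speciation gene nodes mapped
    to it (every lineage alive at the node speciates); for an extant species
    the Extant leaves.
    """
    if species not in species_tree.nodes:
        raise ValidationError(f"unknown species {species!r}")
    wanted = EXTANT if species_tree.nodes[species].is_leaf else SPECIATION
    out = []
    for tree in trees:
        for node in tree.iter_nodes():
            if node.event == wanted and node.species == species:
                out.append(node.name)
    return sorted(out)


def degree_distribution(
    history: History,
    trees: list[ReconciledGeneTree],
    species_tree: DatedSpeciesTree,
    species: str,
) -> dict[int, float]:
    """Proportion of genes of ``species`` having each adjacency degree.

    Genes in no adjacency have degree 0; proportions sum to 1.
    """
    genes = genes_of_species(trees, species_tree, species)
    if not genes:
        raise ValidationError(f"species {species!r} has no genes")
    degree = dict.fromkeys(genes, 0)
    for g1, g2 in history.genome_adjacencies(species):
        for g in (g1, g2):
            if g in degree:
                degree[g] += 1
    dist: dict[int, float] = {}
    for d in degree.values():
        dist[d] = dist.get(d, 0) + 1
    n = len(genes)
    return {d: c / n for d, c in sorted(dist.items())}


def adjacency_gene_ratio(
    history: History,
    trees: list[ReconciledGeneTree],
    species_tree: DatedSpeciesTree,
    species: str,
) -> float:
    """Number of adjacencies over number of genes at ``species`` (the ideal,
    circular-genome value is 1).  Undefined for a species with no genes."""
    genes = genes_of_species(trees, species_tree, species)
    if not genes:
        raise ValidationError(f"species {species!r} has no genes")
    return len(history.genome_adjacencies(species)) / len(genes)


@dataclass(frozen=True)
class GeneCluster:
    """A connected set of >= 2 genes moved or copied by one event."""

    kind: str  # "Transfer" | "Duplication"
    species: str  # recipient (transfer) or duplicating species
    slice_: int
    donor_species: str | None
    donor_slice: int | None
    genes: tuple[str, ...]


def find_event_clusters(history: History, kind: str) -> list[GeneCluster]:
    """Clusters of co-transferred or co-duplicated genes.

    Two maintained adjacencies join the same cluster only when they share a
    gene *and* the same event (same donor context, recipient species and
    slice for transfers; same species and slice for duplications):
    "co-transferred" means moved by one event.  Minimum cluster size 2.
    """
    if kind not in ("Transfer", "Duplication"):
        raise ValidationError(f"unknown cluster kind {kind!r}")
    graphs: dict[tuple, nx.Graph] = {}
    if kind == "Transfer":
        for link in history.transfer_links:
            key = (
                link.donor_species, link.donor_slice,
                link.recipient_species, link.recipient_slice,
            )
            graphs.setdefault(key, nx.Graph()).add_edge(link.gene1, link.gene2)
    else:
        for link in history.coduplication_links:
            key = (None, None, link.species, link.slice_)
            graphs.setdefault(key, nx.Graph()).add_edge(link.gene1, link.gene2)
    clusters = []
    for key, graph in sorted(graphs.items(), key=lambda kv: str(kv[0])):
        donor_sp, donor_ts, sp, ts = key
        for comp in nx.connected_components(graph):
            if len(comp) < 2:
                continue
            clusters.append(
                GeneCluster(
                    kind=kind,
                    species=sp,
                    slice_=ts,
                    donor_species=donor_sp,
                    donor_slice=donor_ts,
                    genes=tuple(sorted(comp)),
                )
            )
    clusters.sort(key=lambda c: (c.species, c.slice_, c.genes))
    return clusters


_DEGREE_BINS = list(range(7))  # 0..6, plus an overflow bin


def write_report_tables(
    history: History,
    trees: list[ReconciledGeneTree],
    species_tree: DatedSpeciesTree,
    path: str,
) -> None:
    """Write per-species degree, ratio and cluster TSV tables."""
    os.makedirs(path, exist_ok=True)
    species_names = sorted(
        species_tree.nodes,
        key=lambda n: (species_tree.nodes[n].rank is None,
                       species_tree.nodes[n].rank or 0, n),
    )
    degree_rows, ratio_rows = [], []
    for sp in species_names:
        genes = genes_of_species(trees, species_tree, sp)
        if not genes:
            continue
        dist = degree_distribution(history, trees, species_tree, sp)
        row = {"species": sp, "n_genes": len(genes)}
        for k in _DEGREE_BINS:
            row[f"deg{k}"] = round(dist.get(k, 0.0), 6)
        row["deg7plus"] = round(sum(v for d, v in dist.items() if d >= 7), 6)
        degree_rows.append(row)
        ratio_rows.append(
            {
                "species": sp,
                "n_genes": len(genes),
                "n_adjacencies": len(history.genome_adjacencies(sp)),
                "ratio": round(
                    adjacency_gene_ratio(history, trees, species_tree, sp), 6
                ),
            }
        )
    pd.DataFrame(degree_rows).to_csv(
        os.path.join(path, "degree_distribution.tsv"), sep="\t", index=False
    )
    pd.DataFrame(ratio_rows).to_csv(
        os.path.join(path, "adjacency_gene_ratio.tsv"), sep="\t", index=False
    )
    cluster_rows = []
    for kind in ("Transfer", "Duplication"):
        for i, c in enumerate(find_event_clusters(history, kind), start=1):
            cluster_rows.append(
                {
                    "cluster_id": f"{kind[:1]}{i}",
                    "kind": c.kind,
                    "species": c.species,
                    "slice": c.slice_,
                    "donor_species": c.donor_species if c.donor_species else ".",
                    "donor_slice": c.donor_slice if c.donor_slice is not None else ".",
                    "n_genes": len(c.genes),
                    "genes": ",".join(c.genes),
                }
            )
    pd.DataFrame(
        cluster_rows,
        columns=[
            "cluster_id", "kind", "species", "slice", "donor_species",
            "donor_slice", "n_genes", "genes",
        ],
    ).to_csv(os.path.join(path, "clusters.tsv"), sep="\t", index=False)
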