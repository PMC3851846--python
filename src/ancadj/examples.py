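"""Packaged worked example.

A two-family instance on four species dated as in the package's README:
a tandem duplication in the branch to A, gene losses in the branches to A
and C, a two-gene transfer from the branch to B into the branch to C whose
transferred adjacency does not survive to the present, and conserved extant
adjacencies in B and D.  Its unique optimal history costs 3 with unit
costs: two gains and one breakage.
"""

from __future__ import annotations

from importlib import resources

from .io import InputBundle, read_adjacencies, read_gene_trees, read_species_tree

__all__ = ["load_worked_example", "worked_example_dir"]


def worked_example_dir():
    """The packaged data directory (a ``importlib.resources`` traversable)."""
    return resources.files("ancadj").joinpath("data", "worked_example")


def load_worked_example() -> InputBundle:
    """Load the packaged worked example as an :class:`InputBundle`."""
    root = worked_example_dir()
    sptree = read_species_tree(
        root.joinpath("species.nwk").read_text(),
        root.joinpath("ranks.tsv").read_text(),
    )
    texts = [
        line
        for line in root.joinpath("gene_trees.nwk").read_text().splitlines()
        if line.strip()
    ]
    trees = read_gene_trees(texts, sptree)
    adjacencies = read_adjacencies(
        root.joinpath("adjacencies.tsv").read_text(), trees
    )
    return InputBundle(sptree, trees, adjacencies)
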