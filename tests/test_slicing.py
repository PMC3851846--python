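import pytest

from ancadj.io import read_species_tree
from ancadj.model import NO_EVENT, ValidationError
from ancadj.simulate import SimParams, simulate
from ancadj.slicing import assign_slices, splice_no_events, subdivide


class TestAssignSlices:
    def test_four_taxon_dating(self, four_species_tree):
        slices = assign_slices(four_species_tree)
        # branches to A, B and to the ancestor of C and D overlap two
        # slices, all others one
        assert slices["A"] == [1, 2]
        assert slices["B"] == [1, 2]
        assert slices["f"] == [0, 1]
        assert slices["e"] == [0]
        assert slices["C"] == [2]
        assert slices["D"] == [2]
        assert slices["r"] == []

    def test_two_leaf_tree(self):
        tree = read_species_tree("(A,B)r;", "r\t0\n")
        slices = assign_slices(tree)
        assert slices["A"] == [0] and slices["B"] == [0]

    def test_caterpillar_deepest_branch(self):
        tree = read_species_tree(
            "(((A,B)x,C)y,D)z;", "z\t0\ny\t1\nx\t2\n"
        )
        # internal ranks strictly between the root and the leaf level,
        # plus one: the deepest terminal branch overlaps three slices
        assert assign_slices(tree)["D"] == [0, 1, 2]


class TestSubdivide:
    def test_single_slice_branch_unchanged(self, worked_example):
        from ancadj.io import read_gene_trees

        # lineages from the rank-2 speciation to extant leaves cross no
        # interior slice: nothing to insert
        text = (
            "(gC[&&NHX:S=C:Ev=Extant:ts=3],gD[&&NHX:S=D:Ev=Extant:ts=3])"
            "x[&&NHX:S=f:Ev=Spec:ts=2];"
        )
        (tree,) = read_gene_trees([text], worked_example.species_tree)
        subdivide(tree, worked_example.species_tree)
        assert all(n.event != NO_EVENT for n in tree.iter_nodes())

    def test_two_slice_event_free_branch_gets_one_filler(self, worked_example):
        # family 1's A-branch lineage: speciation at e (slice 1), next event
        # at slice 2 -- but its B lineage runs from e (slice 1) straight to
        # an extant leaf (slice 3) through the SpecOut at slice 2.  Build a
        # cleaner probe: a lineage from e (slice 1) to an extant leaf at
        # slice 3 with no event crosses exactly one interior slice.
        from ancadj.io import read_gene_trees

        text = (
            "(gA[&&NHX:S=A:Ev=Extant:ts=3],gB[&&NHX:S=B:Ev=Extant:ts=3])"
            "x[&&NHX:S=e:Ev=Spec:ts=1];"
        )
        (tree,) = read_gene_trees([text], worked_example.species_tree)
        subdivide(tree, worked_example.species_tree)
        fillers = [n for n in tree.iter_nodes() if n.event == NO_EVENT]
        assert len(fillers) == 2  # one per terminal branch
        assert {f.slice_ for f in fillers} == {2}

    def test_adjacent_slices_property_on_simulations(self):
        for seed in range(20):
            bundle, _, _ = simulate(
                SimParams(n_species=6, root_genes=10, seed=seed)
            )
            for tree in bundle.gene_trees:
                subdivide(tree, bundle.species_tree)
                for node in tree.iter_nodes():
                    for child in node.children:
                        if (
                            node.event == "SpecOut"
                            and child.species != node.species
                        ):
                            continue  # untracked outside excursion
                        assert 0 <= child.slice_ - node.slice_ <= 1

    def test_splice_recovers_input(self, worked_example):
        tree = worked_example.gene_trees[0]
        before = sorted(
            (n.name, n.event, n.species, n.slice_) for n in tree.iter_nodes()
        )
        subdivide(tree, worked_example.species_tree)
        splice_no_events(tree)
        after = sorted(
            (n.name, n.event, n.species, n.slice_) for n in tree.iter_nodes()
        )
        assert before == after

    def test_event_multiset_preserved(self, worked_example):
        tree = worked_example.gene_trees[0]
        before = sorted(
            n.event for n in tree.iter_nodes() if n.event != NO_EVENT
        )
        subdivide(tree, worked_example.species_tree)
        after = sorted(
            n.event for n in tree.iter_nodes() if n.event != NO_EVENT
        )
        assert before == after

    def test_non_chronological_rejected(self, worked_example):
        from ancadj.model import GeneNode, ReconciledGeneTree

        parent = GeneNode("p", "Dup", "A", 2)
        parent.add_child(GeneNode("c1", "Extant", "A", 3))
        bad = GeneNode("c2", "NoEvent", "A", 1)
        parent.add_child(bad)
        bad.add_child(GeneNode("c3", "Extant", "A", 3))
        tree = ReconciledGeneTree(parent, "F")
        with pytest.raises(ValidationError, match="chronolog"):
            subdivide(tree, worked_example.species_tree)
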