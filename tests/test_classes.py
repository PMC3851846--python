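import random

from ancadj.classes import build_classes, covering_pairs, possibly_homologous
from ancadj.io import build_gene_index
from ancadj.simulate import SimParams, simulate
from ancadj.slicing import subdivide


def _prepared(seed, **kw):
    params = dict(n_species=4, root_genes=5, p_dup=0.06, p_transfer=0.08,
                  p_loss=0.05, p_gain=0.05, p_break=0.06)
    params.update(kw)
    bundle, _, _ = simulate(SimParams(seed=seed, **params))
    for tree in bundle.gene_trees:
        subdivide(tree, bundle.species_tree)
    return bundle


class TestPossiblyHomologous:
    def test_reflexive_and_symmetric(self, worked_example):
        for t in worked_example.gene_trees:
            subdivide(t, worked_example.species_tree)
        trees = worked_example.gene_trees
        a1, a2 = ("xB", "yB"), ("xD", "yD")
        assert possibly_homologous(a1, a1, trees)
        assert possibly_homologous(a1, a2, trees) == possibly_homologous(
            a2, a1, trees
        )

    def test_conserved_pair_is_homologous_across_species(self, worked_example):
        for t in worked_example.gene_trees:
            subdivide(t, worked_example.species_tree)
        # the B and D adjacencies descend from one ancestral pair at the root
        assert possibly_homologous(
            ("xB", "yB"), ("xD", "yD"), worked_example.gene_trees
        )

    def test_unrelated_families_not_homologous(self, worked_example):
        for t in worked_example.gene_trees:
            subdivide(t, worked_example.species_tree)
        # the tandem pair shares no ancestral pair with the B adjacency
        assert not possibly_homologous(
            ("xA1", "xA2"), ("xB", "yB"), worked_example.gene_trees
        )


class TestBuildClasses:
    def test_worked_example_partition(self, worked_example):
        for t in worked_example.gene_trees:
            subdivide(t, worked_example.species_tree)
        classes = build_classes(
            worked_example.adjacencies, worked_example.gene_trees
        )
        partition = sorted(tuple(c.members) for c in classes)
        assert partition == [
            (("xA1", "xA2"),),
            (("xB", "yB"), ("xD", "yD")),
        ]
        big = next(c for c in classes if len(c.members) == 2)
        assert {big.root_a.name, big.root_b.name} == {"xr", "yr"}

    def test_tandem_class_roots_are_disjoint_leaves(self, worked_example):
        for t in worked_example.gene_trees:
            subdivide(t, worked_example.species_tree)
        classes = build_classes(
            worked_example.adjacencies, worked_example.gene_trees
        )
        tandem = next(c for c in classes if c.members == [("xA1", "xA2")])
        assert not tandem.root_a.is_ancestor_or_self(tandem.root_b)
        assert not tandem.root_b.is_ancestor_or_self(tandem.root_a)

    def test_order_independence(self):
        bundle = _prepared(seed=7)
        classes1 = build_classes(bundle.adjacencies, bundle.gene_trees)
        rng = random.Random(1)
        shuffled = list(bundle.adjacencies)
        rng.shuffle(shuffled)
        classes2 = build_classes(shuffled, bundle.gene_trees)
        assert [c.members for c in classes1] == [c.members for c in classes2]

    def test_partition_matches_pairwise_closure_oracle(self):
        """Connected components of the pairwise relation, computed by an
        independent union oracle over explicit pairwise checks."""
        instances = 0
        for seed in range(40):
            bundle = _prepared(seed=seed)
            adjs = sorted(bundle.adjacencies)
            if len(adjs) < 2:
                continue
            instances += 1
            index = build_gene_index(bundle.gene_trees)
            sets = [
                set(covering_pairs(index[a], index[b])) for a, b in adjs
            ]
            # brute-force transitive closure
            comp = list(range(len(adjs)))

            def find(i):
                while comp[i] != i:
                    i = comp[i]
                return i

            for i in range(len(adjs)):
                for j in range(i + 1, len(adjs)):
                    if sets[i] & sets[j]:
                        ri, rj = find(i), find(j)
                        if ri != rj:
                            comp[max(ri, rj)] = min(ri, rj)
            expected = {}
            for i, adj in enumerate(adjs):
                expected.setdefault(find(i), set()).add(adj)
            classes = build_classes(adjs, bundle.gene_trees)
            got = {}
            # map each class back to its closure component via any member
            for cls in classes:
                root = find(adjs.index(cls.members[0]))
                got.setdefault(root, set()).update(cls.members)
            assert got == expected
        assert instances >= 20

    def test_class_count_bounded_by_adjacencies(self):
        for seed in range(10):
            bundle = _prepared(seed=100 + seed)
            classes = build_classes(bundle.adjacencies, bundle.gene_trees)
            assert len(classes) <= len(bundle.adjacencies)
            covered = sorted(a for c in classes for a in c.members)
            assert covered == sorted(set(bundle.adjacencies))
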