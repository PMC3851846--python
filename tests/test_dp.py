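from ancadj.classes import build_classes
from ancadj.dp import (
    cell_key, class_optimum, d12_configurations, fill_matrix,
)
from ancadj.model import CostParams, GeneNode, AdjacencyClass
from ancadj.oracle import OracleSizeError, brute_force_min_cost
from ancadj.simulate import SimParams, simulate
from ancadj.slicing import subdivide


def _leaf_pair_class(adjacent: bool):
    a = GeneNode("ga", "Extant", "A", 1)
    b = GeneNode("gb", "Extant", "A", 1)
    members = [("ga", "gb")] if adjacent else []
    return AdjacencyClass(members=members, root_a=a, root_b=b)


class TestBaseCases:
    def test_extant_adjacent_pair(self):
        cls = _leaf_pair_class(adjacent=True)
        m = fill_matrix(cls, CostParams(), {("ga", "gb")})
        cell = m[cell_key(cls.root_a, cls.root_b)]
        assert (cell.c1, cell.c0) == (0.0, float("inf"))

    def test_extant_non_adjacent_pair(self):
        cls = _leaf_pair_class(adjacent=False)
        m = fill_matrix(cls, CostParams(), set())
        cell = m[cell_key(cls.root_a, cls.root_b)]
        assert (cell.c1, cell.c0) == (float("inf"), 0.0)

    def test_gene_loss_is_free(self):
        a = GeneNode("lost", "Loss", "A", 1)
        b = GeneNode("gb", "Extant", "A", 2)
        cls = AdjacencyClass(members=[], root_a=a, root_b=b)
        m = fill_matrix(cls, CostParams(), set())
        cell = m[cell_key(a, b)]
        assert (cell.c1, cell.c0) == (0.0, 0.0)


class TestD12:
    def test_enumerates_sixteen_configurations(self):
        configs = d12_configurations()
        assert len(configs) == 16
        assert len({c["present"] for c in configs}) == 16

    def test_costs_match_matching_rule(self):
        # each configuration's cost is the best over the two copy
        # matchings of (gains = present outside the matching) and
        # (breakages = matched but absent)
        for config in d12_configurations():
            present = config["present"]
            for m in config["matchings"]:
                mset = set(m["matching"])
                assert set(m["gains"]) == set(present) - mset
                assert set(m["breaks"]) == mset - set(present)

    def test_zero_cost_configurations_are_the_two_matchings(self):
        free = [
            c["present"]
            for c in d12_configurations()
            if any(
                not m["gains"] and not m["breaks"] for m in c["matchings"]
            )
        ]
        assert sorted(map(sorted, free)) == [
            sorted({(0, 0), (1, 1)}),
            sorted({(0, 1), (1, 0)}),
        ]


def _classes_of(seed, **kw):
    params = dict(n_species=4, root_genes=5, p_dup=0.08, p_transfer=0.08,
                  p_loss=0.06, p_gain=0.05, p_break=0.08)
    params.update(kw)
    bundle, _, _ = simulate(SimParams(seed=seed, **params))
    for tree in bundle.gene_trees:
        subdivide(tree, bundle.species_tree)
    classes = build_classes(bundle.adjacencies, bundle.gene_trees)
    extant = {a for c in classes for a in c.members}
    return classes, extant


class TestMatrix:
    def test_symmetry_under_swapping_trees(self):
        classes, extant = _classes_of(seed=3)
        costs = CostParams()
        for cls in classes:
            m1 = fill_matrix(cls, costs, extant)
            swapped = AdjacencyClass(
                members=cls.members, root_a=cls.root_b, root_b=cls.root_a
            )
            m2 = fill_matrix(swapped, costs, extant)
            k = cell_key(cls.root_a, cls.root_b)
            assert (m1[k].c1, m1[k].c0) == (m2[k].c1, m2[k].c0)

    def test_matrix_size_bounded_by_node_product(self):
        classes, extant = _classes_of(seed=11)
        for cls in classes:
            m = fill_matrix(cls, CostParams(), extant)
            bound = len(list(cls.root_a.iter_subtree())) * len(
                list(cls.root_b.iter_subtree())
            )
            assert len(m) <= bound

    def test_cost_monotone_in_event_costs(self):
        classes, extant = _classes_of(seed=17)
        for cls in classes:
            base = fill_matrix(cls, CostParams(1, 1), extant)
            dearer = fill_matrix(cls, CostParams(2, 3), extant)
            for key, cell in base.items():
                assert dearer[key].c1 >= cell.c1
                assert dearer[key].c0 >= cell.c0

    def test_agrees_with_brute_force_smoke(self):
        checked = 0
        for seed in range(6):
            classes, extant = _classes_of(seed=seed)
            for cls in classes:
                m = fill_matrix(cls, CostParams(), extant)
                value, _ = class_optimum(cls, m, CostParams())
                try:
                    expected = brute_force_min_cost(
                        cls, CostParams(), extant, max_free=10
                    )
                except OracleSizeError:
                    continue
                assert value == expected
                checked += 1
        assert checked >= 5
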