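import pytest

from ancadj.backtrack import reconstruct_history
from ancadj.io import InputBundle, read_gene_trees, read_species_tree, read_adjacencies
from ancadj.model import CostParams
from ancadj.simulate import SimParams, simulate


class TestWorkedExample:
    def test_cost_and_decomposition(self, worked_example):
        history, classes = reconstruct_history(worked_example, CostParams())
        assert history.total_cost == 3.0
        assert len(history.gains) == 2
        assert len(history.breaks) == 1
        assert len(classes) == 2

    def test_ancestral_adjacency_runs_through_all_ancestors(self, worked_example):
        history, _ = reconstruct_history(worked_example, CostParams())
        for ancestor in ("r", "e", "f"):
            assert len(history.genome_adjacencies(ancestor)) == 1

    def test_breakage_located_in_recipient_branch(self, worked_example):
        history, _ = reconstruct_history(worked_example, CostParams())
        (brk,) = history.breaks
        assert brk.species == "C"

    def test_self_consistency_of_cost(self, worked_example):
        costs = CostParams()
        history, _ = reconstruct_history(worked_example, costs)
        assert history.recomputed_cost(costs) == history.total_cost

    def test_extant_adjacencies_reproduced_exactly(self, worked_example):
        expected = set(worked_example.adjacencies)
        history, _ = reconstruct_history(worked_example, CostParams())
        assert history.extant_adjacencies(worked_example.species_tree) == expected


def test_empty_adjacency_set_gives_empty_history(worked_example):
    worked_example.adjacencies = []
    history, classes = reconstruct_history(worked_example, CostParams())
    assert history.total_cost == 0
    assert classes == [] and history.adjacencies == []


def test_conserved_adjacency_costs_one_gain():
    """One adjacency perfectly conserved across a pure-speciation tree of
    four species: any history needs a gain, and a single gain at the class
    root achieves it, leaving the ancestral adjacency in every ancestor."""
    sptree = read_species_tree("((A,B)e,(C,D)f)r;", "r\t0\ne\t1\nf\t2\n")
    trees = read_gene_trees(
        [
            "((g{0}A[&&NHX:S=A:Ev=Extant:ts=3],g{0}B[&&NHX:S=B:Ev=Extant:ts=3])"
            "n{0}e[&&NHX:S=e:Ev=Spec:ts=1],"
            "(g{0}C[&&NHX:S=C:Ev=Extant:ts=3],g{0}D[&&NHX:S=D:Ev=Extant:ts=3])"
            "n{0}f[&&NHX:S=f:Ev=Spec:ts=2])"
            "n{0}r[&&NHX:S=r:Ev=Spec:ts=0:Fam=F{0}];".format(fam)
            for fam in ("1", "2")
        ],
        sptree,
    )
    adjacencies = read_adjacencies(
        "g1A\tg2A\ng1B\tg2B\ng1C\tg2C\ng1D\tg2D\n", trees
    )
    bundle = InputBundle(sptree, trees, adjacencies)
    costs = CostParams(gain=1.0, breakage=1.0)
    history, classes = reconstruct_history(bundle, costs)
    assert len(classes) == 1
    assert history.total_cost == costs.gain
    assert len(history.gains) == 1 and not history.breaks
    for ancestor in ("r", "e", "f"):
        assert len(history.genome_adjacencies(ancestor)) == 1


class TestInvariantsOnSimulations:
    @pytest.mark.parametrize("seed", range(8))
    def test_upper_bound_and_self_consistency(self, seed):
        bundle, _, _ = simulate(
            SimParams(n_species=5, root_genes=8, p_dup=0.05, p_transfer=0.06,
                      p_loss=0.05, p_gain=0.05, p_break=0.06, seed=seed)
        )
        costs = CostParams()
        history, classes = reconstruct_history(bundle, costs)
        # the all-independent-gains history is always feasible
        assert history.total_cost <= costs.gain * len(bundle.adjacencies)
        assert history.recomputed_cost(costs) == history.total_cost
        assert history.extant_adjacencies(bundle.species_tree) == set(
            bundle.adjacencies
        )

    def test_degree_can_exceed_two(self):
        # no constraint caps an ancestral gene's number of adjacencies;
        # the history may assign several partners to one gene
        bundle, _, _ = simulate(
            SimParams(n_species=4, root_genes=6, p_gain=0.3, p_break=0.0,
                      p_dup=0.0, p_transfer=0.0, p_loss=0.0, seed=2)
        )
        history, _ = reconstruct_history(bundle, CostParams())
        degree = {}
        ext = bundle.species_tree.extant_slice
        for rec in history.adjacencies:
            if rec.slice_ == ext and rec.in_genome:
                for g in (rec.gene1, rec.gene2):
                    degree[g] = degree.get(g, 0) + 1
        assert max(degree.values()) >= 3
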