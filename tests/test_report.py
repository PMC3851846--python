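import pytest

from ancadj.backtrack import reconstruct_history
from ancadj.model import CostParams, ValidationError
from ancadj.report import (
    adjacency_gene_ratio, degree_distribution, find_event_clusters,
    genes_of_species, write_report_tables,
)
from ancadj.simulate import SimParams, simulate


def _no_event_run(n_genes=10, n_species=4, seed=0):
    bundle, truth, _ = simulate(
        SimParams(n_species=n_species, root_genes=n_genes, p_dup=0,
                  p_transfer=0, p_loss=0, p_gain=0, p_break=0, seed=seed)
    )
    history, _ = reconstruct_history(bundle, CostParams())
    return bundle, history


class TestDegreeDistribution:
    def test_circular_genome_is_all_degree_two(self):
        bundle, history = _no_event_run()
        for leaf in bundle.species_tree.leaves:
            dist = degree_distribution(
                history, bundle.gene_trees, bundle.species_tree, leaf.name
            )
            assert dist == {2: 1.0}

    def test_species_without_adjacencies_is_all_degree_zero(self):
        bundle, history = _no_event_run()
        history.adjacencies = []  # degrade: drop every adjacency
        leaf = bundle.species_tree.leaves[0].name
        dist = degree_distribution(
            history, bundle.gene_trees, bundle.species_tree, leaf
        )
        assert dist == {0: 1.0}

    def test_proportions_sum_to_one(self):
        bundle, truth, _ = simulate(
            SimParams(n_species=5, root_genes=12, p_dup=0.04, p_transfer=0.04,
                      p_loss=0.04, p_gain=0.04, p_break=0.05, seed=4)
        )
        history, _ = reconstruct_history(bundle, CostParams())
        for name, node in bundle.species_tree.nodes.items():
            if node.parent is None:
                continue
            genes = genes_of_species(bundle.gene_trees, bundle.species_tree, name)
            if not genes:
                continue
            dist = degree_distribution(
                history, bundle.gene_trees, bundle.species_tree, name
            )
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_degraded_history_has_fewer_degree_two_genes(self):
        bundle, history = _no_event_run(n_genes=12)
        ancestor = next(
            n.name for n in bundle.species_tree.nodes.values()
            if n.rank == 1
        )
        good = degree_distribution(
            history, bundle.gene_trees, bundle.species_tree, ancestor
        )
        # deliberately degrade: delete some of that ancestor's adjacencies
        kept, dropped = [], 0
        for rec in history.adjacencies:
            if rec.species == ancestor and rec.in_genome and dropped < 4:
                dropped += 1
                continue
            kept.append(rec)
        history.adjacencies = kept
        worse = degree_distribution(
            history, bundle.gene_trees, bundle.species_tree, ancestor
        )
        assert good.get(2, 0.0) >= worse.get(2, 0.0)

    def test_unknown_species_rejected(self):
        bundle, history = _no_event_run()
        with pytest.raises(ValidationError):
            degree_distribution(
                history, bundle.gene_trees, bundle.species_tree, "nope"
            )


class TestRatio:
    def test_circular_genome_ratio_is_one(self):
        bundle, history = _no_event_run()
        for name, node in bundle.species_tree.nodes.items():
            if node.parent is None:
                continue
            assert adjacency_gene_ratio(
                history, bundle.gene_trees, bundle.species_tree, name
            ) == pytest.approx(1.0)

    def test_half_ratio(self):
        bundle, history = _no_event_run(n_genes=10)
        leaf = bundle.species_tree.leaves[0].name
        full = history.genome_adjacencies(leaf)
        keep = sorted(full)[:5]
        history.adjacencies = [
            r for r in history.adjacencies
            if not (r.species == leaf and r.in_genome)
            or tuple(sorted((r.gene1, r.gene2))) in keep
        ]
        assert adjacency_gene_ratio(
            history, bundle.gene_trees, bundle.species_tree, leaf
        ) == pytest.approx(0.5)

    def test_handshake_bound(self):
        for seed in range(5):
            bundle, truth, _ = simulate(
                SimParams(n_species=4, root_genes=10, p_gain=0.2, seed=seed)
            )
            history, _ = reconstruct_history(bundle, CostParams())
            for leaf in bundle.species_tree.leaves:
                dist = degree_distribution(
                    history, bundle.gene_trees, bundle.species_tree, leaf.name
                )
                max_degree = max(dist)
                ratio = adjacency_gene_ratio(
                    history, bundle.gene_trees, bundle.species_tree, leaf.name
                )
                assert ratio <= max_degree / 2 + 1e-9


class TestClusters:
    def test_no_transfers_no_clusters(self):
        _, history = _no_event_run()
        assert find_event_clusters(history, "Transfer") == []
        assert find_event_clusters(history, "Duplication") == []

    def test_block_transfer_recovered_as_one_cluster(self):
        # drive the simulator until a block of >= 3 genes is co-transferred
        # with its internal adjacencies surviving to the present
        for seed in range(60):
            bundle, truth, log = simulate(
                SimParams(n_species=5, root_genes=12, p_transfer=0.08,
                          p_block=1.0, p_dup=0, p_loss=0, p_gain=0,
                          p_break=0, seed=seed)
            )
            big = [
                e for e in log
                if e["type"] == "transfer" and len(e["genes"]) >= 3
            ]
            if not big:
                continue
            history, _ = reconstruct_history(bundle, CostParams())
            clusters = find_event_clusters(history, "Transfer")
            cluster_sets = [set(c.genes) for c in clusters]
            found = 0
            for event in big:
                genes = set(event["genes"])
                if any(genes <= cs for cs in cluster_sets):
                    found += 1
            if found:
                # no cluster merges genes across distinct transfer events
                for c in clusters:
                    key_events = [
                        e for e in log
                        if e["type"] == "transfer"
                        and set(e["genes"]) & set(c.genes)
                    ]
                    assert len({
                        (e["donor"], e["recipient"]) for e in key_events
                    }) == 1
                return
        pytest.fail("no surviving multi-gene block transfer found")

    def test_single_gene_transfers_make_no_cluster(self):
        bundle, truth, log = simulate(
            SimParams(n_species=5, root_genes=10, p_transfer=0.08,
                      p_block=0.0, p_dup=0, p_loss=0, p_gain=0, p_break=0,
                      seed=1)
        )
        assert any(e["type"] == "transfer" for e in log)
        history, _ = reconstruct_history(bundle, CostParams())
        assert find_event_clusters(history, "Transfer") == []

    def test_unknown_kind_rejected(self):
        _, history = _no_event_run()
        with pytest.raises(ValidationError):
            find_event_clusters(history, "Speciation")


def test_report_tables_written(tmp_path):
    bundle, history = _no_event_run()
    write_report_tables(
        history, bundle.gene_trees, bundle.species_tree, str(tmp_path)
    )
    for name in ("degree_distribution.tsv", "adjacency_gene_ratio.tsv",
                 "clusters.tsv"):
        assert (tmp_path / name).exists()
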