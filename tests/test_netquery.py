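"""Network queries: shared genes, concordance, pathway links, keyword subnets.

Each query is checked against brute-force oracles operating on the raw
generating tables/slices, independent of the graph query paths.
"""

import pandas as pd
import pytest

import _oracles as oracles
from pdkg import corpus as corpus_mod
from pdkg import netquery, synthetic
from pdkg.kg import build_graph
from pdkg.netquery import (
    core_protein_pathway_links,
    direction_concordance,
    genes_to_pathways,
    pathway_keyword_subnetwork,
    shared_genes,
)


def deg_frame(genes, directions=None):
    directions = directions or ["UP"] * len(genes)
    return pd.DataFrame({
        "gene": genes,
        "log2fc": [1.0 if d == "UP" else -1.0 for d in directions],
        "p_adjust": [0.001 * (i + 1) for i in range(len(genes))],
    })


def graph_from_tables(tables, core=None, slices=None):
    return build_graph(corpus_mod.aggregate_corpus(tables, core_protein_lists=core), slices)


def empty_slices(gene_sets=None, drugs=None):
    return synthetic.ResourceSlices(
        gene_sets=gene_sets or {},
        ppi=pd.DataFrame(columns=["source", "target", "interaction_type"]),
        diseases=pd.DataFrame(columns=["gene", "disease", "category"]),
        drugs=drugs if drugs is not None else pd.DataFrame(columns=["gene", "drug"]),
        mapping=None,
    )


class TestSharedGenes:
    def test_single_dataset_graph_yields_empty_with_warning(self):
        kg = graph_from_tables({"A": deg_frame(["G1", "G2"])})
        with pytest.warns(UserWarning, match="exceeds"):
            report = shared_genes(kg, min_datasets=2)
        assert len(report.genes) == 0

    def test_planted_fixture_five_pairs_one_triple(self):
        # 5 genes in exactly 2 datasets, 1 gene in 3 datasets
        tables = {
            "A": deg_frame(["S1", "S2", "S3", "T", "U1"]),
            "B": deg_frame(["S1", "S2", "S4", "T", "U2"]),
            "C": deg_frame(["S3", "S4", "S5", "T", "U3"]),
            "D": deg_frame(["S5", "U4", "U5", "U6", "U7"]),
        }
        kg = graph_from_tables(tables)
        assert set(shared_genes(kg, 2).symbols()) == {"S1", "S2", "S3", "S4", "S5", "T"}
        assert set(shared_genes(kg, 3).symbols()) == {"T"}

    def test_min_datasets_one_returns_every_measured_gene(self, study_kg, scenario):
        report = shared_genes(study_kg, min_datasets=1)
        expected = {g for t in scenario.deg_tables.values() for g in t["gene"]}
        assert set(report.symbols()) == expected

    def test_result_shrinks_weakly_as_min_datasets_grows(self, study_kg):
        previous = None
        for k in range(1, 6):
            current = set(shared_genes(study_kg, k).symbols())
            if previous is not None:
                assert current <= previous
            previous = current

    def test_pairwise_overlap_counts_every_pair_a_gene_belongs_to(self):
        tables = {
            "A": deg_frame(["T", "X"]),
            "B": deg_frame(["T", "Y"]),
            "C": deg_frame(["T", "Z"]),
        }
        report = shared_genes(graph_from_tables(tables), 2)
        assert report.pairwise_overlap == {("A", "B"): 1, ("A", "C"): 1, ("B", "C"): 1}


class TestDirectionConcordance:
    def test_up_up_concordant_up_down_discordant(self):
        tables = {
            "A": deg_frame(["CONC", "DISC"], ["UP", "UP"]),
            "B": deg_frame(["CONC", "DISC"], ["UP", "DOWN"]),
        }
        summary = direction_concordance(shared_genes(graph_from_tables(tables), 2))
        by_gene = dict(zip(summary.table["gene"], summary.table["concordant"]))
        assert by_gene == {"CONC": True, "DISC": False}
        assert summary.n_concordant + summary.n_discordant == summary.n_shared == 2


class TestGenesToPathways:
    def test_fixture_two_genes_share_pathway_third_has_none(self):
        tables = {"S": deg_frame(["A", "B", "C"])}
        slices = empty_slices(gene_sets={"P": ("A", "B")})
        kg = graph_from_tables(tables, slices=slices)
        result = genes_to_pathways(kg, ["A", "B", "C"])
        assert set(result.subnetwork.nodes) == {"gene:A", "gene:B", "pathway:P"}
        assert len(result.subnetwork.edges) == 2
        assert result.n_genes_with_pathway == 2
        assert result.n_pathways == 1

    def test_unknown_gene_skipped_with_warning(self, study_kg):
        with pytest.warns(UserWarning, match="unknown gene"):
            result = genes_to_pathways(study_kg, ["NOT_A_GENE"])
        assert result.subnetwork.nodes == ()

    def test_counts_match_slice_oracle(self, study_kg, study_slices, scenario):
        genes = sorted(scenario.spec.shared_assignments)[:25]
        result = genes_to_pathways(study_kg, genes)
        expected = oracles.pathway_counts_from_slices(study_slices, genes)
        got = dict(zip(result.per_gene_counts["gene"], result.per_gene_counts["n_pathways"]))
        assert got == expected


class TestCoreProteinPathwayLinks:
    def test_one_shared_pathway_yields_one_path(self):
        tables = {"S": deg_frame(["Y"])}
        slices = empty_slices(gene_sets={"P": ("X", "Y")})
        kg = graph_from_tables(tables, core={"S": ("X",)}, slices=slices)
        sub = core_protein_pathway_links(kg, "S")
        assert sub.meta["paths"] == [["gene:X", "pathway:P", "gene:Y"]] or \
               sub.meta["paths"] == [("gene:X", "pathway:P", "gene:Y")]
        assert set(sub.nodes) == {"gene:X", "pathway:P", "gene:Y"}

    def test_disjoint_memberships_give_empty_subnetwork(self):
        tables = {"S": deg_frame(["Y"])}
        slices = empty_slices(gene_sets={"P1": ("X",), "P2": ("Y",)})
        kg = graph_from_tables(tables, core={"S": ("X",)}, slices=slices)
        sub = core_protein_pathway_links(kg, "S")
        assert sub.nodes == () and sub.edges == ()

    def test_unknown_dataset_rejected(self, study_kg):
        with pytest.raises(ValueError, match="unknown dataset"):
            core_protein_pathway_links(study_kg, "NOT_A_STUDY")

    def test_matches_raw_input_oracle_on_study_scenario(self, scenario, study_kg, study_slices):
        for dataset in synthetic.ALL_DATASETS:
            sub = core_protein_pathway_links(study_kg, dataset)
            got = {
                (c.split(":", 1)[1], p.split(":", 1)[1], d.split(":", 1)[1])
                for c, p, d in sub.meta["paths"]
            }
            expected = oracles.core_links_from_raw(
                scenario.deg_tables, scenario.core_proteins, study_slices, dataset
            )
            assert got == expected


class TestKeywordSubnetwork:
    def test_no_matching_pathway_gives_empty_subnetwork(self, study_kg):
        sub = pathway_keyword_subnetwork(study_kg, "zzz-no-such-pathway")
        assert sub.nodes == () and sub.edges == ()

    def test_planted_fixture_counts_by_hand(self):
        # two ROBO pathways covering 3 measured genes; one drug targets one gene
        tables = {"S1": deg_frame(["A", "B"]), "S2": deg_frame(["C", "D"])}
        slices = empty_slices(
            gene_sets={"ROBO guidance A": ("A", "B"), "ROBO guidance B": ("C",), "Other": ("D",)},
            drugs=pd.DataFrame({"gene": ["C", "D"], "drug": ["DrugX", "DrugY"]}),
        )
        kg = graph_from_tables(tables, slices=slices)
        sub = pathway_keyword_subnetwork(kg, "robo", include_drugs=True)
        assert sub.meta["n_pathways"] == 2
        assert sub.meta["n_genes"] == 3
        assert sub.meta["n_drugs"] == 1  # DrugY targets D, which is not a ROBO member
        assert sub.meta["genes_per_dataset"] == {"S1": 2, "S2": 1}
        # nodes: 2 pathways + 3 genes + 1 drug + 2 cell-line-time-points
        assert len(sub.nodes) == 8
        # edges: 3 INVOLVED_IN + 3 MEASURED_IN + 1 TARGETED_BY
        assert len(sub.edges) == 7

    def test_include_drugs_false_drops_drug_nodes(self):
        tables = {"S1": deg_frame(["A"])}
        slices = empty_slices(
            gene_sets={"ROBO path": ("A",)},
            drugs=pd.DataFrame({"gene": ["A"], "drug": ["DrugX"]}),
        )
        kg = graph_from_tables(tables, slices=slices)
        sub = pathway_keyword_subnetwork(kg, "ROBO", include_drugs=False)
        assert not any(t == "TARGETED_BY" for _u, t, _v in sub.edges)

    def test_member_genes_match_raw_input_oracle(self, scenario, study_kg, study_slices):
        sub = pathway_keyword_subnetwork(study_kg, "ROBO")
        got = {n.split(":", 1)[1] for n in sub.nodes if n.startswith("gene:")}
        assert got == oracles.keyword_genes_from_raw(scenario.deg_tables, study_slices, "ROBO")

    def test_empty_keyword_rejected(self, study_kg):
        with pytest.raises(ValueError):
            pathway_keyword_subnetwork(study_kg, "")


class TestOracleEquivalenceOnRandomGraphs:
    """All queries equal brute-force scans on random <=200-node fixtures."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_shared_and_concordant_match_table_oracle(self, seed):
        spec = synthetic.OverlapSpec(
            datasets=("A", "B", "C", "D"), universe_size=120, top_n=20,
            shared_assignments={
                "G000001": {"A": "UP", "B": "UP"},
                "G000002": {"A": "UP", "C": "DOWN"},
                "G000003": {"B": "DOWN", "C": "DOWN", "D": "DOWN"},
            },
            seed=seed,
        )
        tables = synthetic.generate_deg_tables(spec)
        kg = graph_from_tables(tables)
        for k in (1, 2, 3, 4):
            report = shared_genes(kg, k)
            assert set(report.symbols()) == oracles.shared_genes_from_tables(tables, k)
            concordant = set(report.genes.loc[report.genes["concordant"], "gene"])
            assert concordant == oracles.concordant_from_tables(tables, k)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pathway_queries_match_slice_oracle(self, seed):
        spec = synthetic.OverlapSpec(datasets=("A", "B"), universe_size=100, top_n=15, seed=seed)
        tables = synthetic.generate_deg_tables(spec)
        slices = synthetic.generate_resource_slices(
            synthetic.ResourceSliceSpec(
                universe=synthetic.gene_universe(100), n_pathways=8, n_drugs=3,
                keyword_pathways=("ROBO-like set",), seed=seed,
            )
        )
        core = {"A": ("G000001",), "B": ()}
        kg = graph_from_tables(tables, core=core, slices=slices)
        assert kg.n_nodes <= 200

        genes = sorted({g for t in tables.values() for g in t["gene"]})
        result = genes_to_pathways(kg, genes)
        got = dict(zip(result.per_gene_counts["gene"], result.per_gene_counts["n_pathways"]))
        assert got == oracles.pathway_counts_from_slices(slices, genes)

        sub = pathway_keyword_subnetwork(kg, "ROBO")
        got_genes = {n.split(":", 1)[1] for n in sub.nodes if n.startswith("gene:")}
        assert got_genes == oracles.keyword_genes_from_raw(tables, slices, "ROBO")

        for dataset in ("A", "B"):
            links = core_protein_pathway_links(kg, dataset)
            got_paths = {
                (c.split(":", 1)[1], p.split(":", 1)[1], d.split(":", 1)[1])
                for c, p, d in links.meta["paths"]
            }
            assert got_paths == oracles.core_links_from_raw(tables, core, slices, dataset)


def test_every_returned_subnetwork_is_contained_in_parent(study_kg):
    subs = [
        genes_to_pathways(study_kg, ["G000001", "G000002"]).subnetwork,
        pathway_keyword_subnetwork(study_kg, "ROBO"),
        core_protein_pathway_links(study_kg, "GBA"),
    ]
    for sub in subs:
        assert sub.is_subgraph_of(study_kg)
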