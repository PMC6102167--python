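"""Alias resolution, similarity search, target queries, network export."""

import math

import networkx as nx
import pandas as pd
import pytest
from lxml import etree

from polypharm.ingest import SourceRecord
from polypharm.query import (
    build_database,
    build_network,
    export_network,
    load_database,
    load_network,
    molecules_for_targets,
    resolve_alias,
    save_database,
    similarity_search,
    targets_of,
)
from polypharm.structures import compute_fingerprint, standardize_structure, tanimoto


def quant(alias, smiles, gene, value=100.0):
    return SourceRecord(alias, smiles, gene, "quantitative",
                        value_type="IC50", value=value, unit="nM")


@pytest.fixture(scope="module")
def small_db():
    records = [
        quant("imatinib-like", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1", "ABL1", 50.0),
        quant("imatinib-like", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1", "KIT", 120.0),
        SourceRecord("imatinib-like", None, "PDGFRA", "qualitative"),
        quant("limki-A", "CC(C)NCC(O)COc1cccc2ccccc12", "LIMK1", 20.0),
        quant("limki-A", "CC(C)NCC(O)COc1cccc2ccccc12", "LIMK2", 80.0),
        quant("limki-B", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", "LIMK1", 15.0),
        quant("limki-B", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", "LIMK2", 10.0),
        quant("limk1-only", "CCOC(=O)c1ccc(N)cc1", "LIMK1", 500.0),
        quant("other", "Cn1c(=O)c2c(ncn2C)n(C)c1=O", "AURKA", 40.0),
        SourceRecord("name-only-probe", None, "LIMK2", "qualitative"),
    ]
    return build_database(records)


class TestResolveAlias:
    def test_known_alias(self, small_db):
        ids = resolve_alias(small_db, "imatinib-like")
        assert len(ids) == 1

    def test_case_insensitive(self, small_db):
        assert resolve_alias(small_db, "IMATINIB-LIKE") == resolve_alias(small_db, "imatinib-like")

    def test_unknown_alias_empty(self, small_db):
        assert resolve_alias(small_db, "no-such-molecule") == set()


class TestSimilaritySearch:
    def test_exact_structure_returns_one(self, small_db):
        hits = similarity_search(small_db, "CC(C)NCC(O)COc1cccc2ccccc12", threshold=1.0)
        assert len(hits) == 1
        assert hits[0].similarity == 1.0

    def test_threshold_zero_returns_all_structured(self, small_db, db):
        hits = similarity_search(small_db, "CCO", threshold=0.0)
        structured = [e for e in small_db.registry.entries.values() if e.canonical_smiles]
        assert len(hits) == len(structured)

    def test_equals_brute_force_scan(self, db):
        """Hit sets at several thresholds match an all-pairs Tanimoto oracle."""
        query = "CC(=O)Oc1ccccc1C(=O)O"
        qfp = compute_fingerprint(standardize_structure(query))
        oracle = {}
        for internal_id, entry in db.registry.entries.items():
            if entry.canonical_smiles is None:
                continue
            oracle[internal_id] = tanimoto(qfp, compute_fingerprint(entry.canonical_smiles))
        for threshold in (0.0, 0.3, 0.5, 0.8, 1.0):
            hits = similarity_search(db, query, threshold=threshold)
            expected = {i for i, s in oracle.items() if s >= threshold}
            assert {h.internal_id for h in hits} == expected
            for h in hits:
                assert h.similarity == oracle[h.internal_id]

    def test_sorted_descending_with_id_tiebreak(self, db):
        hits = similarity_search(db, "CCCCO", threshold=0.0)
        keys = [(-h.similarity, h.internal_id) for h in hits]
        assert keys == sorted(keys)

    def test_bad_threshold_rejected(self, small_db):
        with pytest.raises(ValueError):
            similarity_search(small_db, "CCO", threshold=1.5)

    def test_structureless_molecules_never_hit(self, small_db):
        hits = similarity_search(small_db, "CCO", threshold=0.0)
        for h in hits:
            assert small_db.registry.entries[h.internal_id].canonical_smiles is not None


class TestTargetsOf:
    def test_rows_and_ordering(self, small_db):
        (mid,) = resolve_alias(small_db, "imatinib-like")
        rows = targets_of(small_db, [mid])
        assert list(rows["gene_symbol"]) == ["ABL1", "KIT", "PDGFRA"]
        means = rows["mean_pchembl"].tolist()
        assert means[0] > means[1] and math.isnan(means[2])  # qualitative-only last

    def test_unknown_id_raises(self, small_db):
        with pytest.raises(KeyError):
            targets_of(small_db, ["MOL999999"])

    def test_empty_id_list_empty_table(self, small_db):
        assert len(targets_of(small_db, [])) == 0


class TestMoleculesForTargets:
    def test_single_gene_equals_gene_index(self, small_db):
        assert molecules_for_targets(small_db, ["LIMK1"]) == small_db.gene_index["LIMK1"]

    def test_all_subset_of_any(self, small_db):
        genes = ["LIMK1", "LIMK2"]
        assert molecules_for_targets(small_db, genes, "all") <= \
               molecules_for_targets(small_db, genes, "any")

    def test_all_equals_intersection_of_singletons(self, small_db):
        genes = ["LIMK1", "LIMK2", "AURKA"]
        singles = [molecules_for_targets(small_db, [g]) for g in genes]
        expected = singles[0] & singles[1] & singles[2]
        assert molecules_for_targets(small_db, genes, "all") == expected

    def test_dual_limk_inhibitors_found(self, small_db):
        both = molecules_for_targets(small_db, ["LIMK1", "LIMK2"], "all")
        names = {min(small_db.registry.entries[i].aliases) for i in both}
        assert names == {"limki-A", "limki-B"}  # limk1-only and the LIMK2-only probe drop out

    def test_unknown_gene_warns_not_errors(self, small_db):
        with pytest.warns(UserWarning, match="NOSUCHGENE"):
            result = molecules_for_targets(small_db, ["LIMK1", "NOSUCHGENE"], "all")
        assert result == set()

    def test_empty_gene_list_rejected(self, small_db):
        with pytest.raises(ValueError):
            molecules_for_targets(small_db, [])


class TestNetworks:
    def test_one_molecule_two_targets(self, small_db):
        (mid,) = resolve_alias(small_db, "limki-A")
        graph = build_network(small_db, [mid])
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2
        assert nx.is_bipartite(graph)

    def test_shared_target_has_degree_two(self, small_db):
        ids = sorted(resolve_alias(small_db, "limki-A") | resolve_alias(small_db, "limki-B"))
        graph = build_network(small_db, ids)
        assert graph.degree("LIMK1") == 2

    def test_edge_count_equals_summary_rows(self, db):
        ids = sorted(db.registry.entries)
        graph = build_network(db, ids)
        assert graph.number_of_edges() == len(db.summaries)
        assert nx.is_bipartite(graph)
        kinds = nx.get_node_attributes(graph, "kind")
        for u, v in graph.edges:
            assert {kinds[u], kinds[v]} == {"molecule", "target"}

    @pytest.mark.parametrize("fmt,suffix", [("graphml", ".graphml"), ("json-node-link", ".json")])
    def test_round_trip(self, small_db, tmp_path, fmt, suffix):
        ids = sorted(resolve_alias(small_db, "limki-A") | resolve_alias(small_db, "imatinib-like"))
        graph = build_network(small_db, ids)
        path = tmp_path / f"net{suffix}"
        export_network(graph, fmt, path)
        back = load_network(fmt, path)
        assert set(back.nodes) == set(graph.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in graph.edges}
        assert nx.get_node_attributes(back, "kind") == nx.get_node_attributes(graph, "kind")

    def test_empty_network_exports(self, small_db, tmp_path):
        graph = build_network(small_db, [])
        for fmt, name in [("graphml", "e.graphml"), ("json-node-link", "e.json")]:
            export_network(graph, fmt, tmp_path / name)
            assert load_network(fmt, tmp_path / name).number_of_nodes() == 0

    def test_graphml_is_wellformed_namespaced_xml(self, small_db, tmp_path):
        (mid,) = resolve_alias(small_db, "limki-A")
        export_network(build_network(small_db, [mid]), "graphml", tmp_path / "n.graphml")
        root = etree.parse(str(tmp_path / "n.graphml")).getroot()
        assert root.tag == "{http://graphml.graphdrawing.org/xmlns}graphml"
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        assert len(root.findall("g:graph/g:node", ns)) == 3
        assert len(root.findall("g:graph/g:edge", ns)) == 2

    def test_unknown_format_rejected(self, small_db, tmp_path):
        with pytest.raises(ValueError):
            export_network(build_network(small_db, []), "gexf", tmp_path / "x")


def test_save_load_round_trip(db, tmp_path):
    save_database(db, tmp_path / "db")
    back = load_database(tmp_path / "db")
    assert set(back.registry.entries) == set(db.registry.entries)
    assert back.gene_index == db.gene_index
    assert back.params == db.params
    pd.testing.assert_frame_equal(
        back.summaries.reset_index(drop=True),
        db.summaries.drop(columns=["mean_by_type"]).reset_index(drop=True),
        check_exact=False, atol=1e-12,
    )
    # similarity works on the reloaded database (fingerprints recomputed lazily)
    hits = similarity_search(back, "CC(=O)Oc1ccccc1C(=O)O", threshold=1.0)
    assert len(hits) == 1 and hits[0].similarity == 1.0
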