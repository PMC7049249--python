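import pytest

from evigraph.engine import execute
from evigraph.etl import (
    EtlError,
    load_drug_response,
    load_expression_matrix,
    load_g2p,
    load_maf,
    load_pathways_gmt,
    merge_elements,
)
from evigraph.graph import Edge, Graph, Vertex, validate_against_schema
from evigraph.query import compile_query, parse_query

MAF_HEADER = "Tumor_Sample_Barcode\tHugo_Symbol\tGene\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tCENTERS\n"


def _write_maf(tmp_path, rows, name="toy.maf"):
    path = tmp_path / name
    path.write_text(MAF_HEADER + "".join("\t".join(r) + "\n" for r in rows))
    return str(path)


V1 = ("TP53", "ENSG3", "17", "7578406", "C", "T")
V2 = ("PIK3CA", "ENSG7", "3", "178936091", "G", "A")


def _row(aliquot, variant, centers="MUTECT|MUSE"):
    hugo, gene, chrom, start, ref, alt = variant
    return (aliquot, hugo, gene, chrom, start, ref, alt, centers)


class TestMaf:
    def test_shared_variant_is_deduplicated_across_samples(self, tmp_path):
        path = _write_maf(tmp_path, [_row("a1", V1), _row("a2", V1), _row("a1", V2)])
        out = load_maf(path, "Project:P")
        by_label = {}
        for v in out.vertices:
            by_label.setdefault(v.label, []).append(v)
        assert len(by_label["SomaticCallset"]) == 2
        assert len(by_label["Allele"]) == 2  # v1 shared, v2 once
        allele_edges = [e for e in out.edges if e.label == "alleles"]
        assert len(allele_edges) == 3
        assert len([e for e in out.edges if e.label == "somatic_callsets"]) == 2

    def test_caller_list_split_on_pipes(self, tmp_path):
        path = _write_maf(tmp_path, [_row("a1", V1, "MUTECT|MUSE")])
        (edge,) = [e for e in load_maf(path, "P").edges if e.label == "alleles"]
        assert edge.data["methods"] == ["MUTECT", "MUSE"]
        assert edge.data["ensembl_gene"] == "ENSG3"

    def test_header_only_yields_nothing(self, tmp_path):
        path = _write_maf(tmp_path, [])
        out = load_maf(path, "P")
        assert out.vertices == [] and out.edges == []

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Tumor_Sample_Barcode\tGene\n")
        with pytest.raises(EtlError, match="missing required column"):
            load_maf(str(path), "P")

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = _write_maf(tmp_path, [_row("a1", V1), _row("a2", ("X", "E", "1", "zero", "A", "C"))])
        with pytest.raises(EtlError, match=":3"):
            load_maf(str(path), "P")

    def test_allele_dedup_independent_of_row_order(self, tmp_path):
        rows = [_row("a1", V1), _row("a2", V1), _row("a1", V2)]
        p1 = _write_maf(tmp_path, rows, "one.maf")
        p2 = _write_maf(tmp_path, rows[::-1], "two.maf")
        alleles = lambda p: sorted(v.gid for v in load_maf(p, "P").vertices if v.label == "Allele")
        assert alleles(p1) == alleles(p2)

    def test_idempotent_and_schema_conformant(self, tmp_path, schema):
        path = _write_maf(tmp_path, [_row("a1", V1), _row("a2", V2)])
        first, second = load_maf(path, "P"), load_maf(path, "P")
        assert [v.to_record() for v in first.vertices] == [v.to_record() for v in second.vertices]
        assert [e.to_record() for e in first.edges] == [e.to_record() for e in second.edges]
        assert validate_against_schema(first.to_graph(), schema) == []


class TestGmt:
    def test_line_produces_bidirectional_membership(self, tmp_path, schema):
        path = tmp_path / "sets.gmt"
        path.write_text("PWA\tsource\tG1\tG2\tG3\tG4\n")
        out = load_pathways_gmt(str(path))
        assert sum(v.label == "Pathway" for v in out.vertices) == 1
        assert sum(e.label == "genes" for e in out.edges) == 4
        assert sum(e.label == "pathways" for e in out.edges) == 4
        assert validate_against_schema(out.to_graph(), schema) == []

    def test_duplicate_gene_in_line_collapses(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("PWA\tsrc\tG1\tG1\tG2\n")
        out = load_pathways_gmt(str(path))
        assert sum(e.label == "genes" for e in out.edges) == 2

    def test_shared_gene_links_to_both_pathways(self, tmp_path):
        path = tmp_path / "two.gmt"
        path.write_text("PWA\tsrc\tG1\tG2\nPWB\tsrc\tG1\tG3\n")
        graph = load_pathways_gmt(str(path)).to_graph()
        doc = [
            {"op": "V", "args": ["G1"]},
            {"op": "as", "args": "gene"},
            {"op": "out", "args": ["pathways"]},
            {"op": "render", "args": ["$gene._gid", "$._gid"]},
        ]
        rows = execute(graph, compile_query(parse_query(doc)))
        assert rows == [["G1", "Pathway:PWA"], ["G1", "Pathway:PWB"]]

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "short.gmt"
        path.write_text("PWA\tsrc\tG1\nPWB\tonly-description\n")
        with pytest.raises(EtlError, match=":2"):
            load_pathways_gmt(str(path))


class TestExpression:
    def _write(self, tmp_path, text):
        path = tmp_path / "expr.tsv"
        path.write_text(text)
        return str(path)

    def test_matrix_rows_become_expression_vertices(self, tmp_path, schema):
        path = self._write(tmp_path, "aliquot\tG1\tG2\tG3\nA1\t1.5\t0.0\t7\nA2\t2\t3\t4\n")
        out = load_expression_matrix(path)
        ge = [v for v in out.vertices if v.label == "GeneExpression"]
        assert len(ge) == 2
        assert ge[0].data["values"] == {"G1": 1.5, "G2": 0.0, "G3": 7.0}  # zero retained
        assert validate_against_schema(out.to_graph(), schema) == []

    def test_negative_value_rejected(self, tmp_path):
        path = self._write(tmp_path, "aliquot\tG1\nA1\t-2\n")
        with pytest.raises(EtlError, match="negative"):
            load_expression_matrix(path)

    def test_round_trip_through_query_engine(self, tmp_path):
        path = self._write(tmp_path, "aliquot\tG1\tG2\nA1\t1.0\t2.5\nA2\t0.5\t9.0\n")
        graph = load_expression_matrix(path).to_graph()
        doc = [
            {"op": "V", "args": ["Aliquot:A1", "Aliquot:A2"]},
            {"op": "as", "args": "aliquot"},
            {"op": "out", "args": ["gene_expressions"]},
            {"op": "as", "args": "exp"},
            {"op": "render", "args": ["$aliquot._gid", "$exp._data.values"]},
        ]
        rows = execute(graph, compile_query(parse_query(doc)))
        assert rows == [
            ["Aliquot:A1", {"G1": 1.0, "G2": 2.5}],
            ["Aliquot:A2", {"G1": 0.5, "G2": 9.0}],
        ]


DRUG_CSV_HEADER = "sample_id,project_id,compound_id,submitter_compound_id,ec50,auc\n"


class TestDrugResponse:
    def test_single_row_element_counts(self, tmp_path, schema):
        path = tmp_path / "dr.csv"
        path.write_text(DRUG_CSV_HEADER + "S1,CTRP_Breast_Cancer,CID1,fulvestrant,0.31,0.8\n")
        out = load_drug_response(str(path))
        labels = sorted(v.label for v in out.vertices)
        assert labels == ["Aliquot", "Compound", "DrugResponse", "Project"]
        assert sorted(e.label for e in out.edges) == ["compounds", "drug_response", "projects"]
        assert validate_against_schema(out.to_graph(), schema) == []

    def test_compound_deduplicated_across_rows(self, tmp_path):
        path = tmp_path / "dr.csv"
        path.write_text(
            DRUG_CSV_HEADER
            + "S1,P1,CID1,drugx,0.3,\n"
            + "S2,P1,CID1,drugx,0.1,0.5\n"
        )
        out = load_drug_response(str(path))
        assert sum(v.label == "Compound" for v in out.vertices) == 1
        assert sum(v.label == "DrugResponse" for v in out.vertices) == 2
        assert sum(e.label == "projects" for e in out.edges) == 1  # derived once

    def test_non_numeric_ec50_reports_line(self, tmp_path):
        path = tmp_path / "dr.csv"
        path.write_text(DRUG_CSV_HEADER + "S1,P1,CID1,x,high,\n")
        with pytest.raises(EtlError, match=":2"):
            load_drug_response(str(path))

    def test_sensitivity_query_recovers_csv_tuples(self, tmp_path):
        path = tmp_path / "dr.csv"
        path.write_text(
            DRUG_CSV_HEADER
            + "S1,P1,CID1,fulvestrant,0.307,\n"
            + "S2,P1,CID1,fulvestrant,0.023,\n"
            + "S2,P1,CID2,otherdrug,0.9,\n"
        )
        out = load_drug_response(str(path))
        # attach sample anchors so the traversal can start at samples
        g = Graph()
        for sid in ("S1", "S2"):
            g.add_vertex(Vertex(f"Sample:{sid}", "Sample", {}))
        merge_elements(g, out)
        for sid in ("S1", "S2"):
            g.add_edge(Edge(f"sa{sid}", f"Sample:{sid}", f"Aliquot:{sid}", "aliquots"))
        g.finalize()
        doc = [
            {"op": "V", "args": ["Sample:S1", "Sample:S2"]},
            {"op": "as", "args": "sample"},
            {"op": "out", "args": ["aliquots"]},
            {"op": "out", "args": ["drug_response"]},
            {"op": "as", "args": "response"},
            {"op": "out", "args": ["compounds"]},
            {"op": "hasId", "args": ["Compound:CID1"]},
            {"op": "render", "args": ["$sample._gid", "$response.submitter_compound_id", "$response.ec50"]},
        ]
        rows = execute(g, compile_query(parse_query(doc)))
        assert rows == [["Sample:S1", "fulvestrant", 0.307], ["Sample:S2", "fulvestrant", 0.023]]


class TestG2p:
    def _allele_graph(self):
        g = Graph()
        g.add_vertex(Vertex("Allele:17:7578406:C:T", "Allele", {}))
        return g.finalize()

    def test_publications_fan_out(self, tmp_path, schema):
        path = tmp_path / "g2p.jsonl"
        path.write_text(
            '{"association_id": "A1", "allele_key": "17:7578406:C:T",'
            ' "compound_ids": ["CID1"], "publication_urls": ["pubmed/1", "pubmed/2"],'
            ' "phenotype": "drug sensitivity", "description": "d"}\n'
        )
        base = self._allele_graph()
        out = load_g2p(str(path), base)
        assert sum(e.label == "publications" for e in out.edges) == 2
        assert out.warnings == []
        merged = merge_elements(base, out)
        assert validate_against_schema(merged, schema) == []

    def test_unmatched_allele_key_warns_and_skips(self, tmp_path):
        path = tmp_path / "g2p.jsonl"
        path.write_text(
            '{"association_id": "A1", "allele_key": "1:1:A:C", "compound_ids": ["CID1"],'
            ' "publication_urls": [], "phenotype": "", "description": ""}\n'
        )
        out = load_g2p(str(path), self._allele_graph())
        assert out.edges == [] and out.vertices == []
        assert len(out.warnings) == 1

    def test_distinct_collapses_multiple_associations_per_case(self, tmp_path):
        """Two associations in different publications linking one allele to one
        compound still yield a single (case, compound) pair."""
        path = tmp_path / "g2p.jsonl"
        path.write_text(
            '{"association_id": "A1", "allele_key": "17:7578406:C:T", "compound_ids": ["CID1"],'
            ' "publication_urls": ["pubmed/1"], "phenotype": "", "description": ""}\n'
            '{"association_id": "A2", "allele_key": "17:7578406:C:T", "compound_ids": ["CID1"],'
            ' "publication_urls": ["pubmed/2"], "phenotype": "", "description": ""}\n'
        )
        g = Graph()
        g.add_vertex(Vertex("Case:C1", "Case", {}))
        g.add_vertex(Vertex("CS1", "SomaticCallset", {}))
        g.add_vertex(Vertex("Allele:17:7578406:C:T", "Allele", {}))
        g.add_edge(Edge("cc", "Case:C1", "CS1", "samples"))  # stand-in hop for brevity
        g.add_edge(Edge("ca", "CS1", "Allele:17:7578406:C:T", "alleles"))
        g.finalize()
        merge_elements(g, load_g2p(str(path), g))
        doc = [
            {"op": "V", "args": ["Case:C1"]},
            {"op": "as", "args": "case"},
            {"op": "out", "args": ["samples"]},
            {"op": "out", "args": ["alleles"]},
            {"op": "out", "args": ["g2p_associations"]},
            {"op": "out", "args": ["compounds"]},
            {"op": "distinct", "args": ["$case._gid", "_gid"]},
            {"op": "aggregate", "args": [{"name": "compound", "field": "_gid"}]},
        ]
        rows = execute(g, compile_query(parse_query(doc)))
        assert rows == [{"compound": [{"key": "Compound:CID1", "value": 1}]}]

    def test_record_without_evidence_rejected(self, tmp_path):
        path = tmp_path / "g2p.jsonl"
        path.write_text(
            '{"association_id": "A1", "allele_key": "17:7578406:C:T", "compound_ids": [],'
            ' "publication_urls": [], "phenotype": "", "description": ""}\n'
        )
        with pytest.raises(EtlError, match="at least one"):
            load_g2p(str(path), self._allele_graph())
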