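import pytest

from evigraph.engine import aggregate_terms, apply_step, execute, render_rows
from evigraph.graph import Edge, Graph, Vertex
from evigraph.query import (
    QueryError,
    Step,
    TermAggregation,
    Traveler,
    compile_query,
    parse_field_path,
    parse_query,
)


def _pathway_graph():
    """One pathway with 3 member genes, one gene also in a second pathway."""
    g = Graph()
    g.add_vertex(Vertex("Pathway:P", "Pathway"))
    g.add_vertex(Vertex("Pathway:Q", "Pathway"))
    for i in range(3):
        g.add_vertex(Vertex(f"ENSG{i}", "Gene"))
        g.add_edge(Edge(f"pg{i}", "Pathway:P", f"ENSG{i}", "genes"))
        g.add_edge(Edge(f"gp{i}", f"ENSG{i}", "Pathway:P", "pathways"))
    return g


def _run(graph, doc):
    return execute(graph, compile_query(parse_query(doc)))


def test_v_step_emits_named_or_all_vertices(cohort_graph):
    assert _run(cohort_graph, [{"op": "V", "args": []}, {"op": "count"}]) == [10]
    rows = _run(cohort_graph, [{"op": "V", "args": ["Case:C2", "Case:C1"]}])
    assert [r["gid"] for r in rows] == ["Case:C2", "Case:C1"]  # given order kept
    assert _run(cohort_graph, [{"op": "V", "args": ["Nope"]}, {"op": "count"}]) == [0]


def test_out_fans_travelers_across_matching_edges(cohort_graph):
    rows = _run(cohort_graph, [{"op": "V", "args": ["Project:P1"]}, {"op": "out", "args": ["cases"]}])
    assert [r["gid"] for r in rows] == ["Case:C1", "Case:C2", "Case:C3"]
    # wrong label: no travelers survive
    assert _run(
        cohort_graph, [{"op": "V", "args": ["Project:P1"]}, {"op": "out", "args": ["samples"]}, {"op": "count"}]
    ) == [0]


def test_tumor_filter_path_count(cohort_graph):
    doc = [
        {"op": "V", "args": ["Project:P1"]},
        {"op": "out", "args": ["cases"]},
        {"op": "out", "args": ["samples"]},
        {"op": "has", "args": {"op": "eq", "field": "gdc_attributes.sample_type", "value": "Primary Tumor"}},
        {"op": "count"},
    ]
    assert _run(cohort_graph, doc) == [2]


def test_edge_landing_exposes_edge_data():
    g = Graph()
    g.add_vertex(Vertex("CS", "SomaticCallset"))
    for i, gene in enumerate(["g1", "g1", "g2"]):
        g.add_vertex(Vertex(f"Allele:{i}", "Allele"))
        g.add_edge(Edge(f"e{i}", "CS", f"Allele:{i}", "alleles", {"ensembl_gene": gene}))
    g.finalize()
    doc = [
        {"op": "V", "args": ["CS"]},
        {"op": "outE", "args": ["alleles"]},
        {"op": "aggregate", "args": [{"name": "geneCount", "field": "ensembl_gene"}]},
    ]
    assert _run(g, doc) == [{"geneCount": [{"key": "g1", "value": 2}, {"key": "g2", "value": 1}]}]


def test_in_steps_mirror_out(cohort_graph):
    rows = _run(cohort_graph, [{"op": "V", "args": ["Case:C1"]}, {"op": "in", "args": ["cases"]}])
    assert [r["gid"] for r in rows] == ["Project:P1"]
    rows = _run(cohort_graph, [{"op": "V", "args": ["Case:C1"]}, {"op": "inE", "args": ["cases"]}])
    assert [r["gid"] for r in rows] == ["pc1"]


def test_traversal_from_edge_position_is_an_error(cohort_graph):
    doc = [
        {"op": "V", "args": ["Project:P1"]},
        {"op": "outE", "args": ["cases"]},
        {"op": "out", "args": ["samples"]},
    ]
    with pytest.raises(QueryError, match="out"):
        _run(cohort_graph, doc)


def test_mark_select_returns_travelers_to_marked_element():
    g = _pathway_graph()
    doc = [
        {"op": "V", "args": ["Pathway:P"]},
        {"op": "as", "args": "pathway"},
        {"op": "out", "args": ["genes"]},
        {"op": "select", "args": "pathway"},
    ]
    rows = _run(g.finalize(), doc)
    assert [r["gid"] for r in rows] == ["Pathway:P"] * 3  # one traveler per member gene


def test_select_is_idempotent(fixture42):
    graph, _ = fixture42
    base = [
        {"op": "V", "args": []},
        {"op": "hasLabel", "args": ["Pathway"]},
        {"op": "as", "args": "p"},
        {"op": "out", "args": ["genes"]},
    ]
    once = _run(graph, base + [{"op": "select", "args": "p"}])
    twice = _run(graph, base + [{"op": "select", "args": "p"}, {"op": "select", "args": "p"}])
    assert once == twice


def test_remarking_a_name_overwrites_the_snapshot(cohort_graph):
    doc = [
        {"op": "V", "args": ["Project:P1"]},
        {"op": "as", "args": "m"},
        {"op": "out", "args": ["cases"]},
        {"op": "as", "args": "m"},
        {"op": "out", "args": ["samples"]},
        {"op": "select", "args": "m"},
    ]
    rows = _run(cohort_graph, doc)
    assert [r["label"] for r in rows] == ["Case"] * 3


def test_distinct_keeps_first_traveler_per_tuple(fixture42):
    graph, _ = fixture42
    base = [{"op": "V", "args": []}, {"op": "hasLabel", "args": ["Sample"]},
            {"op": "distinct", "args": ["gdc_attributes.sample_type"]}]
    rows = _run(graph, base)
    assert len(rows) == 2  # tumor + normal
    twice = _run(graph, base[:2] + [base[2], base[2]])
    assert twice == rows  # distinct is idempotent


def test_limit_truncates_stream(cohort_graph):
    assert _run(cohort_graph, [{"op": "V", "args": []}, {"op": "limit", "args": 4}, {"op": "count"}]) == [4]
    assert _run(cohort_graph, [{"op": "V", "args": []}, {"op": "limit", "args": 0}, {"op": "count"}]) == [0]


class TestAggregation:
    def _travelers(self, values):
        out = []
        for i, v in enumerate(values):
            data = {} if v is None else {"f": v}
            out.append(Traveler(Vertex(f"V{i}", "X", data)))
        return out

    def test_null_values_are_skipped(self):
        aggs = [TermAggregation("a", parse_field_path("f"))]
        result = aggregate_terms(self._travelers(["g1", "g1", "g2", None]), aggs)
        assert result == {"a": [{"key": "g1", "value": 2}, {"key": "g2", "value": 1}]}

    def test_empty_stream_gives_empty_buckets(self):
        assert aggregate_terms([], [TermAggregation("a", parse_field_path("f"))]) == {"a": []}

    def test_ties_break_by_key_ascending(self):
        result = aggregate_terms(
            self._travelers(["c", "a", "b"]), [TermAggregation("a", parse_field_path("f"))]
        )
        assert [b["key"] for b in result["a"]] == ["a", "b", "c"]

    def test_bucket_sum_bounded_by_traveler_count(self):
        travelers = self._travelers(["x", None, "x", "y", None])
        result = aggregate_terms(travelers, [TermAggregation("a", parse_field_path("f"))])
        assert sum(b["value"] for b in result["a"]) == 3 <= len(travelers)


class TestRender:
    def test_missing_fields_render_as_null(self):
        t = Traveler(Vertex("Compound:X", "Compound", {"synonym": "FULVESTRANT"}))
        rows = render_rows([t], [parse_field_path("_gid"), parse_field_path("synonym"),
                                 parse_field_path("absent")])
        assert rows == [["Compound:X", "FULVESTRANT", None]]

    def test_nested_values_pass_through_unflattened(self):
        values = {"ENSG1": 1.5, "ENSG2": 0.0}
        t = Traveler(Vertex("GE", "GeneExpression", {"values": values}))
        t = Traveler(t.current, {"exp": t.current})
        rows = render_rows([t], [parse_field_path("$exp._data.values")])
        assert rows == [[values]]


def test_unfinalized_graph_refuses_queries():
    g = Graph()
    g.add_vertex(Vertex("A", "X"))
    with pytest.raises(QueryError, match="finalized"):
        execute(g, compile_query(parse_query([{"op": "V", "args": []}])))
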