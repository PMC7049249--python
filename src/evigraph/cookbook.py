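"""The eight worked analyses as named, parameterized traversal queries.

Each function builds a query document (the serialized step-record form),
parses and compiles it, and runs it through the engine -- never by bespoke
graph walking -- so every cookbook call exercises the full query path.
Defaults target the conventional gids of the default synthetic fixture, so
the whole chain runs with zero arguments.

The analyses chain like the original study: q1 finds the most mutated genes
in a tumor cohort, q2/q3 map them onto pathways, q4/q5 pull literature and
compound evidence for the same mutations, q6 intersects those compounds
with a cell-line screen, q7 reads out EC50 sensitivity for one compound,
and q8 fetches expression vectors for the screened cell lines via their
cross-project ``same_as`` partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from .engine import ResultRow, execute
from .graph import Graph
from .query import compile_query, parse_query
from .synthetic import (
    DEFAULT_COMPOUND,
    DEFAULT_PROGRAM,
    DEFAULT_PROJECT,
    DEFAULT_PROJECT_ID,
)


@dataclass
class CookbookResult:
    query_id: str
    rows: list[ResultRow]
    query_doc: list[dict[str, Any]]


def _run(query_id: str, graph: Graph, doc: list[dict[str, Any]]) -> CookbookResult:
    rows = execute(graph, compile_query(parse_query(doc)))
    return CookbookResult(query_id=query_id, rows=rows, query_doc=doc)


def _eq(field: str, value: Any) -> dict[str, Any]:
    return {"op": "eq", "field": field, "value": value}


_TUMOR_FILTER = {"op": "has", "args": _eq("gdc_attributes.sample_type", "Primary Tumor")}


def q1_mutation_counts(graph: Graph, project_gid: str = DEFAULT_PROJECT) -> CookbookResult:
    """Count somatic mutations per gene in a project's primary-tumor samples.

    Lands on the callset->allele edges (``outE``) so the aggregation reads
    the per-call ``ensembl_gene`` annotation, keeping only calls supported
    by the MUTECT caller."""
    doc = [
        {"op": "V", "args": [project_gid]},
        {"op": "out", "args": ["cases"]},
        {"op": "out", "args": ["samples"]},
        _TUMOR_FILTER,
        {"op": "out", "args": ["aliquots"]},
        {"op": "out", "args": ["somatic_callsets"]},
        {"op": "outE", "args": ["alleles"]},
        {"op": "has", "args": {"op": "contains", "field": "methods", "value": "MUTECT"}},
        {"op": "aggregate", "args": [{"name": "geneCount", "field": "ensembl_gene"}]},
    ]
    return _run("q1", graph, doc)


def q2_gene_pathway_pairs(
    graph: Graph, gene_gids: Sequence[str] | None = None, project_gid: str = DEFAULT_PROJECT
) -> CookbookResult:
    """(gene, pathway) membership tuples for a gene list.

    With ``gene_gids=None``, uses the mutated genes found by q1, in q1's
    bucket order."""
    if gene_gids is None:
        q1 = q1_mutation_counts(graph, project_gid)
        gene_gids = [b["key"] for b in q1.rows[0]["geneCount"]]
    doc = [
        {"op": "V", "args": list(gene_gids)},
        {"op": "as", "args": "gene"},
        {"op": "out", "args": ["pathways"]},
        {"op": "render", "args": ["$gene._gid", "$._gid"]},
    ]
    return _run("q2", graph, doc)


def q3_pathway_gene_counts(graph: Graph) -> CookbookResult:
    """Member-gene count per pathway: mark the pathway, fan out to genes,
    select the mark back, and count travelers per pathway gid."""
    doc = [
        {"op": "V", "args": []},
        {"op": "hasLabel", "args": ["Pathway"]},
        {"op": "as", "args": "pathway"},
        {"op": "out", "args": ["genes"]},
        {"op": "select", "args": "pathway"},
        {"op": "aggregate", "args": [{"name": "pathwayGeneCount", "field": "_gid"}]},
    ]
    return _run("q3", graph, doc)


def q4_publication_counts(graph: Graph, project_gid: str = DEFAULT_PROJECT) -> CookbookResult:
    """Publications backing genotype-to-phenotype associations of the
    cohort's mutations, counted per publication (one count per mutation path)."""
    doc = [
        {"op": "V", "args": [project_gid]},
        {"op": "out", "args": ["cases"]},
        {"op": "out", "args": ["samples"]},
        _TUMOR_FILTER,
        {"op": "out", "args": ["aliquots"]},
        {"op": "out", "args": ["somatic_callsets"]},
        {"op": "out", "args": ["alleles"]},
        {"op": "out", "args": ["g2p_associations"]},
        {"op": "out", "args": ["publications"]},
        {"op": "aggregate", "args": [{"name": "pub", "field": "_gid"}]},
    ]
    return _run("q4", graph, doc)


def q5_compound_case_counts(graph: Graph, project_gid: str = DEFAULT_PROJECT) -> CookbookResult:
    """Compounds linked to the cohort's mutations, counted once per
    (case, compound) pair: ``distinct`` collapses multiple associations or
    alleles tying the same patient to the same drug."""
    doc = [
        {"op": "V", "args": [project_gid]},
        {"op": "out", "args": ["cases"]},
        {"op": "as", "args": "case"},
        {"op": "out", "args": ["samples"]},
        _TUMOR_FILTER,
        {"op": "out", "args": ["aliquots"]},
        {"op": "out", "args": ["somatic_callsets"]},
        {"op": "out", "args": ["alleles"]},
        {"op": "out", "args": ["g2p_associations"]},
        {"op": "out", "args": ["compounds"]},
        {"op": "distinct", "args": ["$case._gid", "_gid"]},
        {"op": "aggregate", "args": [{"name": "compound", "field": "_gid"}]},
    ]
    return _run("q5", graph, doc)


def q6_compounds_in_project(
    graph: Graph,
    compound_gids: Sequence[str] | None = None,
    project_id: str = DEFAULT_PROJECT_ID,
    project_gid: str = DEFAULT_PROJECT,
) -> CookbookResult:
    """Of a compound list, keep those screened in the named cell-line project
    and render (gid, synonym). With ``compound_gids=None``, uses q5's compounds."""
    if compound_gids is None:
        q5 = q5_compound_case_counts(graph, project_gid)
        compound_gids = [b["key"] for b in q5.rows[0]["compound"]]
    doc = [
        {"op": "V", "args": list(compound_gids)},
        {"op": "as", "args": "compound"},
        {"op": "out", "args": ["projects"]},
        {"op": "has", "args": _eq("project_id", project_id)},
        {"op": "select", "args": "compound"},
        {"op": "render", "args": ["_gid", "synonym"]},
    ]
    return _run("q6", graph, doc)


def q7_ec50_for_compound(
    graph: Graph, program_gid: str = DEFAULT_PROGRAM, compound_gid: str = DEFAULT_COMPOUND
) -> CookbookResult:
    """EC50 of every cell line in a screening program against one compound,
    rendered as (sample gid, submitter compound id, ec50) triples."""
    doc = [
        {"op": "V", "args": [program_gid]},
        {"op": "out", "args": ["projects"]},
        {"op": "out", "args": ["cases"]},
        {"op": "out", "args": ["samples"]},
        {"op": "as", "args": "sample"},
        {"op": "out", "args": ["aliquots"]},
        {"op": "out", "args": ["drug_response"]},
        {"op": "as", "args": "response"},
        {"op": "out", "args": ["compounds"]},
        {"op": "hasId", "args": [compound_gid]},
        {"op": "render", "args": ["$sample._gid", "$response.submitter_compound_id", "$response.ec50"]},
    ]
    return _run("q7", graph, doc)


def q8_expression_matrix(
    graph: Graph,
    sample_gids: Sequence[str] | None = None,
    program_gid: str = DEFAULT_PROGRAM,
    compound_gid: str = DEFAULT_COMPOUND,
) -> CookbookResult:
    """Expression vectors for screened cell lines, reached through each
    sample's parent case and its cross-project ``same_as`` partner (the
    screen itself has no RNA data; the partner project does). With
    ``sample_gids=None``, uses the samples found by q7."""
    if sample_gids is None:
        q7 = q7_ec50_for_compound(graph, program_gid, compound_gid)
        sample_gids = list(dict.fromkeys(r[0] for r in q7.rows))
    doc = [
        {"op": "V", "args": list(sample_gids)},
        {"op": "as", "args": "sample"},
        {"op": "out", "args": ["case"]},
        {"op": "out", "args": ["same_as"]},
        {"op": "out", "args": ["samples"]},
        {"op": "out", "args": ["aliquots"]},
        {"op": "out", "args": ["gene_expressions"]},
        {"op": "as", "args": "exp"},
        {"op": "render", "args": ["$sample._gid", "$exp._data.values"]},
    ]
    return _run("q8", graph, doc)


def expression_table(result: CookbookResult) -> pd.DataFrame:
    """Assemble q8's (sample, values-map) rows into a samples x genes DataFrame."""
    if result.query_id != "q8":
        raise ValueError("expression_table expects a q8 result")
    index = [r[0] for r in result.rows]
    return pd.DataFrame([r[1] or {} for r in result.rows], index=index)


ALL_QUERIES = {
    "q1": q1_mutation_counts,
    "q2": q2_gene_pathway_pairs,
    "q3": q3_pathway_gene_counts,
    "q4": q4_publication_counts,
    "q5": q5_compound_case_counts,
    "q6": q6_compounds_in_project,
    "q7": q7_ec50_for_compound,
    "q8": q8_expression_matrix,
}


def run_cookbook(graph: Graph, query_ids: Sequence[str] | None = None) -> dict[str, CookbookResult]:
    """Run the cookbook queries (all by default) with fixture-default arguments."""
    ids = list(query_ids) if query_ids else list(ALL_QUERIES)
    out = {}
    for qid in ids:
        if qid not in ALL_QUERIES:
            raise KeyError(f"unknown cookbook query {qid!r}")
        out[qid] = ALL_QUERIES[qid](graph)
    return out
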