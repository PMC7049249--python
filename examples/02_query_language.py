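"""Write and run traversal queries: travelers, marks, filters, aggregation.

A query is a JSON-serializable list of steps. Travelers start on the V step's
vertices, fan out along edges, can snapshot elements under a mark (as) and
jump back to them (select), and are finally shaped by render / aggregate /
count. The brute-force oracle re-derives every result by naive path
enumeration, so any engine answer can be double-checked.
"""

from evigraph import (
    SyntheticConfig,
    brute_force_execute,
    compile_query,
    execute,
    generate,
    parse_query,
)

graph, _ = generate(SyntheticConfig(seed=42))

# How many tumor samples does the TCGA-BRCA-style project have?
doc = [
    {"op": "V", "args": ["Project:TCGA-BRCA"]},
    {"op": "out", "args": ["cases"]},
    {"op": "out", "args": ["samples"]},
    {"op": "has", "args": {"op": "eq", "field": "gdc_attributes.sample_type",
                           "value": "Primary Tumor"}},
    {"op": "count"},
]
query = compile_query(parse_query(doc))
print("tumor samples:", execute(graph, query)[0])

# Land on callset->allele EDGES and aggregate the per-call gene annotation.
doc = [
    {"op": "V", "args": []},
    {"op": "hasLabel", "args": ["SomaticCallset"]},
    {"op": "outE", "args": ["alleles"]},
    {"op": "has", "args": {"op": "contains", "field": "methods", "value": "MUTECT"}},
    {"op": "aggregate", "args": [{"name": "geneCount", "field": "ensembl_gene"}]},
]
query = compile_query(parse_query(doc))
buckets = execute(graph, query)[0]["geneCount"]
print("top MUTECT-mutated genes (gene, call count):")
for b in buckets[:5]:
    print(f"  {b['key']}  n={b['value']}")

# The oracle agrees with the engine row-for-row.
print("oracle agrees:", execute(graph, query) == brute_force_execute(graph, query))
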