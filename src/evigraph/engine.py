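"""Traversal execution: fold a compiled query's steps over a stream of travelers.

Every step maps an ordered traveler list to an ordered traveler list;
ordering is fully deterministic (vertex/edge insertion order everywhere), so
two runs over the same graph files produce identical output and the engine
can be compared element-wise against the brute-force oracle.

Result rows come in exactly one kind per query:

* element rows ``{"gid", "label", "data"}`` when the query ends mid-traversal,
* render rows (plain lists of resolved values),
* a single count row (int),
* a single aggregation row ``{name: [{"key", "value"}, ...]}`` with buckets
  sorted by count descending, key ascending on ties.
"""

from __future__ import annotations

import json
from collections import Counter
from typing import Any, Iterable

from .graph import Graph, Vertex
from .query import (
    Query,
    QueryError,
    Step,
    TermAggregation,
    Traveler,
    compile_query,
    eval_condition,
    resolve_field,
)

ResultRow = Any


def term_key(value: Any) -> str:
    """Convert a resolved field value to an aggregation bucket key (text)."""
    if isinstance(value, str):
        return value
    return json.dumps(value, sort_keys=True)


def _freeze(value: Any) -> Any:
    """Hashable stand-in for an arbitrary property value (for distinct keys)."""
    if isinstance(value, dict):
        return ("__map__", tuple(sorted((k, _freeze(v)) for k, v in value.items())))
    if isinstance(value, list):
        return ("__list__", tuple(_freeze(v) for v in value))
    return value


def apply_step(graph: Graph, travelers: list[Traveler], step: Step) -> list[Traveler]:
    """Apply one non-terminal step to an ordered traveler list."""
    op = step.op
    if op == "V":
        if step.gids:
            found = (graph.vertex(g) for g in step.gids)
            return [Traveler(v) for v in found if v is not None]
        return [Traveler(v) for v in graph.vertices.values()]
    if op == "hasLabel":
        return [t for t in travelers if t.current.label in step.labels]
    if op == "hasId":
        return [t for t in travelers if t.current.gid in step.gids]
    if op == "has":
        return [t for t in travelers if eval_condition(step.condition, t)]
    if op in ("out", "outE", "in", "inE"):
        result: list[Traveler] = []
        for t in travelers:
            if not isinstance(t.current, Vertex):
                raise QueryError(f"step {op!r} requires a vertex position, not an edge")
            edges = (
                graph.out_edges(t.current.gid, step.labels)
                if op in ("out", "outE")
                else graph.in_edges(t.current.gid, step.labels)
            )
            for e in edges:
                if op == "out":
                    result.append(t.with_current(graph.vertices[e.to_gid]))
                elif op == "in":
                    result.append(t.with_current(graph.vertices[e.from_gid]))
                else:
                    result.append(t.with_current(e))
        return result
    if op == "as":
        return [t.with_mark(step.name) for t in travelers]
    if op == "select":
        return [t.with_current(t.marks[step.name]) for t in travelers]
    if op == "distinct":
        seen: set[Any] = set()
        kept: list[Traveler] = []
        for t in travelers:
            key = tuple(_freeze(resolve_field(t, f)) for f in step.fields)
            if key not in seen:
                seen.add(key)
                kept.append(t)
        return kept
    if op == "limit":
        return travelers[: step.n]
    raise QueryError(f"cannot apply step {op!r} mid-stream")


def aggregate_terms(
    travelers: Iterable[Traveler], aggs: Iterable[TermAggregation]
) -> dict[str, list[dict[str, Any]]]:
    """Term aggregation: multiset counts of non-null field values per traveler.

    Buckets are sorted by count descending, then key ascending; travelers
    whose field resolves to null contribute to no bucket.
    """
    travelers = list(travelers)
    out: dict[str, list[dict[str, Any]]] = {}
    for agg in aggs:
        counts: Counter[str] = Counter()
        for t in travelers:
            v = resolve_field(t, agg.field_path)
            if v is not None:
                counts[term_key(v)] += 1
        buckets = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[agg.name] = [{"key": k, "value": c} for k, c in buckets]
    return out


def render_rows(travelers: Iterable[Traveler], template: Iterable) -> list[list[Any]]:
    """One output tuple per traveler, resolving each template field (null if absent)."""
    template = list(template)
    return [[resolve_field(t, f) for f in template] for t in travelers]


def execute(graph: Graph, query: Query) -> list[ResultRow]:
    """Run a compiled query over a finalized graph and return its result rows."""
    if not graph.finalized:
        raise QueryError("graph must be finalized before querying")
    if not query.compiled:
        query = compile_query(query)
    travelers = apply_step(graph, [], query.steps[0])
    for step in query.steps[1:]:
        if step.op == "count":
            return [len(travelers)]
        if step.op == "aggregate":
            return [aggregate_terms(travelers, step.aggregations)]
        if step.op == "render":
            return render_rows(travelers, step.fields)
        travelers = apply_step(graph, travelers, step)
    # element rows carry gid/label/data regardless of vertex or edge position
    return [
        {"gid": t.current.gid, "label": t.current.label, "data": t.current.data}
        for t in travelers
    ]
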