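"""Brute-force reference executor for differential testing.

Re-derives query results by naive path enumeration: every step fully
materializes the list of (element, marks) path states, adjacency is found by
scanning the whole edge table rather than using the graph's indices, and
field resolution, condition evaluation, distinct, and aggregation are all
re-implemented locally. Output must equal :func:`evigraph.engine.execute`
element-for-element, order included. Intended for graphs of up to a few
hundred vertices.
"""

from __future__ import annotations

import json
from typing import Any

from .graph import Edge, Graph, Vertex
from .query import Condition, FieldPath, Query, QueryError, Step

_State = tuple[Any, dict[str, Any]]  # (current element, marks)


def _lookup(state: _State, path: FieldPath) -> Any:
    elem = state[1][path.mark] if path.mark is not None else state[0]
    comps = list(path.components)
    if comps == ["_gid"]:
        return elem.gid
    if comps == ["_label"]:
        return elem.label
    if comps and comps[0] in ("_gid", "_label"):
        return None
    if comps and comps[0] == "_data":
        comps = comps[1:]
    value: Any = elem.data
    for c in comps:
        if not isinstance(value, dict) or c not in value:
            return None
        value = value[c]
    return value


def _holds(cond: Condition, state: _State) -> bool:
    if cond.op == "and":
        return all(_holds(c, state) for c in cond.children)
    if cond.op == "or":
        return any(_holds(c, state) for c in cond.children)
    if cond.op == "not":
        return not _holds(cond.children[0], state)
    got = _lookup(state, cond.field_path)
    want = cond.value
    if cond.op == "eq":
        return (want is None) if got is None else got == want
    if cond.op == "neq":
        return not ((want is None) if got is None else got == want)
    if cond.op in ("gt", "gte", "lt", "lte"):
        for side in (got, want):
            if isinstance(side, bool) or not isinstance(side, (int, float)):
                return False
        if cond.op == "gt":
            return got > want
        if cond.op == "gte":
            return got >= want
        if cond.op == "lt":
            return got < want
        return got <= want
    if cond.op == "contains":
        return isinstance(got, list) and want in got
    if cond.op == "within":
        return got is not None and isinstance(want, list) and got in want
    raise QueryError(f"unknown condition op {cond.op!r}")


def _edge_scan(graph: Graph, vertex_gid: str, labels: tuple[str, ...], incoming: bool) -> list[Edge]:
    hits = []
    for edge in graph.edges.values():
        anchor = edge.to_gid if incoming else edge.from_gid
        if anchor == vertex_gid and (not labels or edge.label in labels):
            hits.append(edge)
    return hits




def brute_force_execute(graph: Graph, query: Query) -> list[Any]:
    """Execute a query by exhaustive path enumeration; same contract as execute."""
    if not graph.finalized:
        raise QueryError("graph must be finalized before querying")
    steps: list[Step] = query.steps
    if not steps or steps[0].op != "V":
        raise QueryError("query must start with V")

    first = steps[0]
    if first.gids:
        states: list[_State] = [
            (graph.vertices[g], {}) for g in first.gids if g in graph.vertices
        ]
    else:
        states = [(v, {}) for v in graph.vertices.values()]

    for step in steps[1:]:
        if step.op == "count":
            return [len(states)]
        if step.op == "aggregate":
            row: dict[str, list[dict[str, Any]]] = {}
            for agg in step.aggregations:
                tally: dict[str, int] = {}
                for state in states:
                    value = _lookup(state, agg.field_path)
                    if value is None:
                        continue
                    key = value if isinstance(value, str) else json.dumps(value, sort_keys=True)
                    tally[key] = tally.get(key, 0) + 1
                ordered = sorted(tally, key=lambda k: (-tally[k], k))
                row[agg.name] = [{"key": k, "value": tally[k]} for k in ordered]
            return [row]
        if step.op == "render":
            return [[_lookup(s, f) for f in step.fields] for s in states]

        if step.op == "hasLabel":
            states = [s for s in states if s[0].label in step.labels]
        elif step.op == "hasId":
            states = [s for s in states if s[0].gid in step.gids]
        elif step.op == "has":
            states = [s for s in states if _holds(step.condition, s)]
        elif step.op in ("out", "outE", "in", "inE"):
            nxt: list[_State] = []
            incoming = step.op in ("in", "inE")
            for elem, marks in states:
                if not isinstance(elem, Vertex):
                    raise QueryError(f"step {step.op!r} requires a vertex position, not an edge")
                for edge in _edge_scan(graph, elem.gid, step.labels, incoming):
                    if step.op == "out":
                        nxt.append((graph.vertices[edge.to_gid], marks))
                    elif step.op == "in":
                        nxt.append((graph.vertices[edge.from_gid], marks))
                    else:
                        nxt.append((edge, marks))
            states = nxt
        elif step.op == "as":
            states = [(elem, {**marks, step.name: elem}) for elem, marks in states]
        elif step.op == "select":
            states = [(marks[step.name], marks) for _, marks in states]
        elif step.op == "distinct":
            seen_tuples: list[list[Any]] = []
            kept: list[_State] = []
            for state in states:
                values = [_lookup(state, f) for f in step.fields]
                if values not in seen_tuples:  # naive == membership, quadratic on purpose
                    seen_tuples.append(values)
                    kept.append(state)
            states = kept
        elif step.op == "limit":
            states = states[: step.n]
        else:
            raise QueryError(f"cannot apply step {step.op!r} mid-stream")

    return [
        {"gid": elem.gid, "label": elem.label, "data": elem.data} for elem, _ in states
    ]
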