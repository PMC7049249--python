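"""Seeded random graphs and queries for differential testing.

The generators draw vertex/edge property values from small pools so that
filters, aggregations, and distinct steps hit real collisions, and they
only emit *valid* queries (marks defined before use, edge-position steps
never applied on an edge), so any disagreement between the engine and the
brute-force oracle is a semantics bug, not an input error.
"""

from __future__ import annotations

import random
from typing import Any

from .graph import Edge, Graph, Vertex
from .query import Query, compile_query, parse_query

_VLABELS = ("Alpha", "Beta", "Gamma")
_ELABELS = ("links", "feeds", "near")
_SCALARS = (0, 1, 2, 3.5, "a", "b", "c", True, False, None)
_FIELD_KEYS = ("x", "y", "tags", "info")


def _random_value(rng: random.Random, depth: int = 0) -> Any:
    roll = rng.random()
    if depth < 1 and roll < 0.15:
        return {k: _random_value(rng, depth + 1) for k in rng.sample(("z", "w"), rng.randint(1, 2))}
    if roll < 0.35:
        return [rng.choice(_SCALARS[:7]) for _ in range(rng.randint(0, 3))]
    return rng.choice(_SCALARS)


def random_graph(rng: random.Random, max_vertices: int = 40, max_edges: int = 120) -> Graph:
    """A small random property graph with pool-drawn labels and values."""
    n_v = rng.randint(1, max_vertices)
    graph = Graph()
    gids = [f"V{i}" for i in range(n_v)]
    for gid in gids:
        data = {k: _random_value(rng) for k in rng.sample(_FIELD_KEYS, rng.randint(0, 3))}
        graph.add_vertex(Vertex(gid, rng.choice(_VLABELS), data))
    n_e = rng.randint(0, max_edges)
    for i in range(n_e):
        data = {k: _random_value(rng) for k in rng.sample(_FIELD_KEYS, rng.randint(0, 2))}
        graph.add_edge(
            Edge(f"E{i}", rng.choice(gids), rng.choice(gids), rng.choice(_ELABELS), data)
        )
    return graph.finalize()


def _random_field(rng: random.Random, marks: dict[str, str]) -> str:
    pool = ["_gid", "_label", "x", "y", "tags", "info.z", "info", "missing.key"]
    if marks and rng.random() < 0.4:
        mark = rng.choice(sorted(marks))
        return f"${mark}." + rng.choice(pool)
    return rng.choice(pool)


def _random_condition(rng: random.Random, marks: dict[str, str], depth: int = 0) -> dict[str, Any]:
    if depth < 1 and rng.random() < 0.25:
        op = rng.choice(("and", "or", "not"))
        n = 1 if op == "not" else rng.randint(1, 2)
        return {"op": op, "children": [_random_condition(rng, marks, depth + 1) for _ in range(n)]}
    op = rng.choice(("eq", "neq", "gt", "gte", "lt", "lte", "contains", "within"))
    if op == "within":
        value: Any = [rng.choice(_SCALARS) for _ in range(rng.randint(0, 3))]
    elif op in ("gt", "gte", "lt", "lte"):
        value = rng.choice((0, 1, 2, 3.5))
    else:
        value = rng.choice(_SCALARS)
    return {"op": op, "field": _random_field(rng, marks), "value": value}


def random_query(rng: random.Random, graph: Graph, max_depth: int = 6) -> Query:
    """A random valid query document over the given graph, parsed and compiled."""
    doc: list[dict[str, Any]] = []
    vertex_gids = list(graph.vertices)
    if rng.random() < 0.5 or not vertex_gids:
        doc.append({"op": "V", "args": []})
    else:
        k = rng.randint(1, min(3, len(vertex_gids)))
        picks = rng.sample(vertex_gids, k)
        if rng.random() < 0.3:
            picks.append("NoSuchVertex")
        doc.append({"op": "V", "args": picks})

    pos = "v"  # current element kind: vertex or edge
    marks: dict[str, str] = {}
    for _ in range(rng.randint(0, max_depth)):
        choices = ["hasLabel", "hasId", "has", "as", "distinct", "limit"]
        if pos == "v":
            choices += ["out", "in", "outE", "inE", "out"]
        if marks:
            choices.append("select")
        op = rng.choice(choices)
        if op == "hasLabel":
            doc.append({"op": op, "args": rng.sample(_VLABELS + ("Nope",), rng.randint(1, 2))})
        elif op == "hasId":
            args = rng.sample(vertex_gids, min(rng.randint(1, 4), len(vertex_gids)))
            doc.append({"op": op, "args": args})
        elif op == "has":
            doc.append({"op": op, "args": _random_condition(rng, marks)})
        elif op in ("out", "in", "outE", "inE"):
            labels = [] if rng.random() < 0.3 else rng.sample(_ELABELS, rng.randint(1, 2))
            doc.append({"op": op, "args": labels})
            pos = "v" if op in ("out", "in") else "e"
        elif op == "as":
            name = rng.choice(("m1", "m2", "m3"))
            marks[name] = pos
            doc.append({"op": "as", "args": name})
        elif op == "select":
            name = rng.choice(sorted(marks))
            doc.append({"op": "select", "args": name})
            pos = marks[name]
        elif op == "distinct":
            fields = [_random_field(rng, marks) for _ in range(rng.randint(1, 2))]
            doc.append({"op": "distinct", "args": fields})
        elif op == "limit":
            doc.append({"op": "limit", "args": rng.randint(0, 15)})

    terminal = rng.choice(("count", "aggregate", "render", "none"))
    if terminal == "count":
        doc.append({"op": "count"})
    elif terminal == "aggregate":
        n = rng.randint(1, 2)
        doc.append(
            {
                "op": "aggregate",
                "args": [
                    {"name": f"agg{i}", "field": _random_field(rng, marks)} for i in range(n)
                ],
            }
        )
    elif terminal == "render":
        fields = [_random_field(rng, marks) for _ in range(rng.randint(1, 3))]
        doc.append({"op": "render", "args": fields})

    return compile_query(parse_query(doc))


def random_pairs(seed: int, n: int, max_vertices: int = 40, max_edges: int = 120, max_depth: int = 6):
    """Yield n seeded (graph, query) pairs for differential testing."""
    rng = random.Random(seed)
    for _ in range(n):
        graph = random_graph(rng, max_vertices, max_edges)
        yield graph, random_query(rng, graph, max_depth)
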