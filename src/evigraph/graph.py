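"""In-memory property graph with deterministic iteration and JSON Lines persistence.

Vertices and edges carry arbitrarily nested JSON-like property payloads
(scalars, lists, maps), so a single vertex can hold anything from a handful
of clinical attributes to a dense per-gene expression vector. All iteration
orders -- vertex table, edge table, per-vertex adjacency -- follow insertion
order, which makes query results reproducible across runs for the same
input files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

#: JSON-like property payload: scalar, list, or string-keyed map, nested freely.
PropertyValue = Any


class GraphError(Exception):
    """Raised for structural errors: duplicate gids, dangling edges, bad input."""


@dataclass
class Vertex:
    gid: str
    label: str
    data: dict[str, PropertyValue] = field(default_factory=dict)

    def to_record(self) -> dict[str, Any]:
        return {"gid": self.gid, "label": self.label, "data": self.data}


@dataclass
class Edge:
    gid: str
    from_gid: str
    to_gid: str
    label: str
    data: dict[str, PropertyValue] = field(default_factory=dict)

    def to_record(self) -> dict[str, Any]:
        return {
            "gid": self.gid,
            "from": self.from_gid,
            "to": self.to_gid,
            "label": self.label,
            "data": self.data,
        }


#: Closed set of schema-violation kinds reported by ``validate_against_schema``.
VIOLATION_KINDS = frozenset(
    {
        "unknown_vertex_label",
        "dangling_edge",
        "illegal_edge_triple",
        "duplicate_gid",
        "missing_required_field",
    }
)


@dataclass
class Violation:
    kind: str
    subject_gid: str
    message: str

    def __post_init__(self) -> None:
        if self.kind not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind: {self.kind!r}")


class Graph:
    """Property graph keyed by gid, with out/in adjacency indices per edge label.

    Mutate with :meth:`add_vertex` / :meth:`add_edge`, then call
    :meth:`finalize` to verify that every edge endpoint resolves. Queries
    should only run on finalized graphs.
    """

    def __init__(self) -> None:
        self.vertices: dict[str, Vertex] = {}
        self.edges: dict[str, Edge] = {}
        # (vertex gid, edge label) -> list of edge gids, insertion-ordered
        self._out: dict[tuple[str, str], list[str]] = {}
        self._in: dict[tuple[str, str], list[str]] = {}
        self.finalized = False

    # -- construction -------------------------------------------------------

    def add_vertex(self, vertex: Vertex) -> "Graph":
        if not vertex.gid:
            raise GraphError("vertex gid must be non-empty")
        if vertex.gid in self.vertices:
            raise GraphError(f"duplicate vertex gid: {vertex.gid!r}")
        self.vertices[vertex.gid] = vertex
        self.finalized = False
        return self

    def add_edge(self, edge: Edge) -> "Graph":
        if not edge.gid:
            raise GraphError("edge gid must be non-empty")
        if edge.gid in self.edges:
            raise GraphError(f"duplicate edge gid: {edge.gid!r}")
        self.edges[edge.gid] = edge
        self._out.setdefault((edge.from_gid, edge.label), []).append(edge.gid)
        self._in.setdefault((edge.to_gid, edge.label), []).append(edge.gid)
        self.finalized = False
        return self

    def finalize(self) -> "Graph":
        """Verify every edge endpoint exists; mark the graph queryable."""
        dangling = [
            e.gid
            for e in self.edges.values()
            if e.from_gid not in self.vertices or e.to_gid not in self.vertices
        ]
        if dangling:
            raise GraphError(f"dangling edge endpoints: {dangling}")
        self.finalized = True
        return self

    # -- access -------------------------------------------------------------

    def vertex(self, gid: str) -> Vertex | None:
        return self.vertices.get(gid)

    def edge(self, gid: str) -> Edge | None:
        return self.edges.get(gid)

    def out_edges(self, gid: str, labels: Iterable[str] = ()) -> list[Edge]:
        """Out-edges of a vertex under the given labels (all labels if empty),
        in edge insertion order."""
        return self._adjacent(self._out, gid, tuple(labels))

    def in_edges(self, gid: str, labels: Iterable[str] = ()) -> list[Edge]:
        return self._adjacent(self._in, gid, tuple(labels))

    def _adjacent(
        self,
        index: dict[tuple[str, str], list[str]],
        gid: str,
        labels: tuple[str, ...],
    ) -> list[Edge]:
        if labels:
            gids: list[str] = []
            for lbl in labels:
                gids.extend(index.get((gid, lbl), ()))
        else:
            gids = [g for (v, _), lst in index.items() if v == gid for g in lst]
        # multi-label: restore global edge insertion order
        if len(labels) != 1:
            order = {g: i for i, g in enumerate(self.edges)}
            gids.sort(key=order.__getitem__)
        return [self.edges[g] for g in gids]

    def __len__(self) -> int:
        return len(self.vertices)

    def __repr__(self) -> str:
        return f"<Graph |V|={len(self.vertices)} |E|={len(self.edges)}>"


# -- JSON Lines persistence --------------------------------------------------


def _parse_vertex_record(rec: dict[str, Any], where: str) -> Vertex:
    try:
        return Vertex(gid=rec["gid"], label=rec["label"], data=rec.get("data") or {})
    except KeyError as exc:
        raise GraphError(f"{where}: vertex record missing field {exc}") from None


def _parse_edge_record(rec: dict[str, Any], where: str, ordinal: int) -> Edge:
    try:
        from_gid, to_gid, label = rec["from"], rec["to"], rec["label"]
    except KeyError as exc:
        raise GraphError(f"{where}: edge record missing field {exc}") from None
    gid = rec.get("gid")
    if not gid:
        # deterministic synthetic gid for records that omit one
        gid = f"({from_gid})--({label})->({to_gid})#{ordinal}"
    return Edge(gid=gid, from_gid=from_gid, to_gid=to_gid, label=label, data=rec.get("data") or {})


def _iter_jsonl(path: str) -> Iterator[tuple[int, dict[str, Any]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise GraphError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from None
            if not isinstance(rec, dict):
                raise GraphError(f"{path}:{lineno}: record is not a JSON object")
            yield lineno, rec


def load_graph_jsonl(vertex_path: str, edge_path: str) -> Graph:
    """Load and finalize a graph from vertex and edge JSON Lines files.

    Line order defines insertion order. A record carrying a ``"type"``
    discriminator of ``"vertex"``/``"edge"`` is also accepted in either file,
    so single-file dialects split arbitrarily still load.
    """
    graph = Graph()
    edge_ordinal = 0
    for path, default_kind in ((vertex_path, "vertex"), (edge_path, "edge")):
        for lineno, rec in _iter_jsonl(path):
            where = f"{path}:{lineno}"
            kind = rec.get("type", default_kind)
            if kind == "vertex":
                graph.add_vertex(_parse_vertex_record(rec, where))
            elif kind == "edge":
                graph.add_edge(_parse_edge_record(rec, where, edge_ordinal))
                edge_ordinal += 1
            else:
                raise GraphError(f"{where}: unknown record type {kind!r}")
    return graph.finalize()


def write_graph_jsonl(graph: Graph, vertex_path: str, edge_path: str) -> None:
    """Write the graph as two JSON Lines files in insertion order.

    Output is byte-deterministic: re-loading reproduces the graph exactly and
    writing the same graph twice yields identical files.
    """
    with open(vertex_path, "w", encoding="utf-8") as fh:
        for v in graph.vertices.values():
            fh.write(json.dumps(v.to_record(), sort_keys=True) + "\n")
    with open(edge_path, "w", encoding="utf-8") as fh:
        for e in graph.edges.values():
            fh.write(json.dumps(e.to_record(), sort_keys=True) + "\n")


# -- schema validation --------------------------------------------------------


def validate_against_schema(graph: Graph, schema) -> list[Violation]:
    """Check every vertex label and edge (from, label, to) triple against a schema.

    Returns violations in deterministic order (vertices in insertion order,
    then edges in insertion order); an empty list means the graph conforms.
    Dangling edges are reported rather than raised so that unfinalized graphs
    can be audited too.
    """
    violations: list[Violation] = []
    for v in graph.vertices.values():
        if v.label not in schema.vertex_labels:
            violations.append(
                Violation("unknown_vertex_label", v.gid, f"vertex label {v.label!r} not in schema")
            )
        for path in schema.required_fields.get(v.label, ()):
            cur: Any = v.data
            for key in path.split("."):
                if isinstance(cur, dict) and key in cur:
                    cur = cur[key]
                else:
                    violations.append(
                        Violation(
                            "missing_required_field",
                            v.gid,
                            f"vertex {v.gid!r} missing required field {path!r}",
                        )
                    )
                    break
    for e in graph.edges.values():
        src = graph.vertex(e.from_gid)
        dst = graph.vertex(e.to_gid)
        if src is None or dst is None:
            violations.append(
                Violation("dangling_edge", e.gid, f"edge {e.gid!r} has an unresolved endpoint")
            )
            continue
        triple = (src.label, e.label, dst.label)
        if triple not in schema.edge_triples:
            violations.append(
                Violation(
                    "illegal_edge_triple",
                    e.gid,
                    f"edge triple {triple} not allowed by schema",
                )
            )
    return violations
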