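"""Traversal query language: step types, parsing, compilation, field resolution.

A query is an ordered list of steps executed by "travelers" -- cursors that
start on a set of vertices and are split, moved, filtered, and finally
shaped into output rows. The dialect implemented here covers subgraph
selection (``V``, ``hasLabel``, ``hasId``, ``has``, ``out``/``in`` and their
edge-landing variants ``outE``/``inE``), mark bookkeeping (``as``/``select``),
and output shaping (``render``, ``distinct``, ``aggregate``, ``count``,
``limit``).

Field paths address the element under the cursor or a previously marked
element: ``"_gid"`` and ``"_label"`` are reserved for the element identity,
``"_data"`` addresses the property map explicitly, and any other leading key
addresses the property map implicitly (``"gdc_attributes.sample_type"``
walks a nested map). ``"$mark.field"`` reads from the element snapshotted
under ``mark``; ``"$.field"`` and bare ``"field"`` both read from the
current element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

from .graph import Edge, PropertyValue, Vertex


class QueryError(Exception):
    """Raised for malformed or inconsistent query documents."""


# -- field paths --------------------------------------------------------------

_RESERVED = ("_gid", "_label")


@dataclass(frozen=True)
class FieldPath:
    """A parsed field reference: optional mark name plus a component chain."""

    mark: str | None
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise QueryError("field path has no components")
        for comp in self.components[1:]:
            if comp in _RESERVED:
                raise QueryError(
                    f"reserved key {comp!r} only allowed in first position: {self}"
                )

    def __str__(self) -> str:
        if self.mark:
            return f"${self.mark}." + ".".join(self.components)
        return ".".join(self.components)


def parse_field_path(text: str) -> FieldPath:
    """Parse ``"_gid"``, ``"synonym"``, ``"$sample._gid"``, ``"$exp._data.values"``...

    ``$.x`` and bare ``x`` are synonyms for "field x of the current element".
    """
    if not text:
        raise QueryError("empty field path")
    if text.startswith("$"):
        parts = text[1:].split(".")
        mark = parts[0] or None  # "$." means the current element
        comps = tuple(parts[1:])
        if not comps:
            raise QueryError(f"field path {text!r} names a mark but no field")
        return FieldPath(mark, comps)
    return FieldPath(None, tuple(text.split(".")))


def resolve_field(traveler: "Traveler", path: FieldPath) -> PropertyValue:
    """Resolve a field path against a traveler; any missing key yields None."""
    if path.mark is None:
        elem = traveler.current
    else:
        if path.mark not in traveler.marks:
            raise QueryError(f"mark {path.mark!r} was never set")
        elem = traveler.marks[path.mark]
    comps = path.components
    if comps[0] == "_gid":
        return elem.gid if len(comps) == 1 else None
    if comps[0] == "_label":
        return elem.label if len(comps) == 1 else None
    if comps[0] == "_data":
        comps = comps[1:]
    cur: Any = elem.data
    for key in comps:
        if isinstance(cur, dict) and key in cur:
            cur = cur[key]
        else:
            return None
    return cur


# -- conditions ---------------------------------------------------------------

_LEAF_OPS = frozenset({"eq", "neq", "gt", "gte", "lt", "lte", "contains", "within"})
_NODE_OPS = frozenset({"and", "or", "not"})


@dataclass(frozen=True)
class Condition:
    op: str
    field_path: FieldPath | None = None
    value: PropertyValue = None
    children: tuple["Condition", ...] = ()

    def __post_init__(self) -> None:
        if self.op in _LEAF_OPS:
            if self.field_path is None:
                raise QueryError(f"condition {self.op!r} requires a field")
        elif self.op in _NODE_OPS:
            if self.op == "not" and len(self.children) != 1:
                raise QueryError("'not' takes exactly one child condition")
            if self.op in ("and", "or") and not self.children:
                raise QueryError(f"{self.op!r} requires at least one child")
        else:
            raise QueryError(f"unknown condition op {self.op!r}")


def _is_number(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def eval_condition(cond: Condition, traveler: "Traveler") -> bool:
    """Evaluate a condition against a traveler. Total: never raises on data.

    Null (missing) field values satisfy no leaf except ``neq``; numeric
    comparisons between non-numbers are false, as is ``contains`` on a
    non-list field.
    """
    op = cond.op
    if op == "and":
        return all(eval_condition(c, traveler) for c in cond.children)
    if op == "or":
        return any(eval_condition(c, traveler) for c in cond.children)
    if op == "not":
        return not eval_condition(cond.children[0], traveler)

    v = resolve_field(traveler, cond.field_path)
    lit = cond.value
    if op == "eq":
        return lit is None if v is None else v == lit
    if op == "neq":
        return not (lit is None if v is None else v == lit)
    if op in ("gt", "gte", "lt", "lte"):
        if not (_is_number(v) and _is_number(lit)):
            return False
        return {"gt": v > lit, "gte": v >= lit, "lt": v < lit, "lte": v <= lit}[op]
    if op == "contains":
        return isinstance(v, list) and lit in v
    if op == "within":
        return v is not None and isinstance(lit, list) and v in lit
    raise QueryError(f"unknown condition op {op!r}")  # unreachable after __post_init__


# -- steps and queries --------------------------------------------------------

STEP_OPS = frozenset(
    {
        "V", "hasLabel", "hasId", "has", "out", "in", "outE", "inE",
        "as", "select", "render", "distinct", "aggregate", "count", "limit",
    }
)
TERMINAL_OPS = frozenset({"render", "aggregate", "count"})


@dataclass(frozen=True)
class TermAggregation:
    name: str
    field_path: FieldPath


@dataclass(frozen=True)
class Step:
    op: str
    gids: tuple[str, ...] = ()           # V, hasId
    labels: tuple[str, ...] = ()         # hasLabel, out/in/outE/inE
    condition: Condition | None = None   # has
    name: str = ""                       # as, select
    fields: tuple[FieldPath, ...] = ()   # render, distinct
    aggregations: tuple[TermAggregation, ...] = ()  # aggregate
    n: int = 0                           # limit


@dataclass
class Query:
    steps: list[Step]
    compiled: bool = field(default=False, compare=False)


@dataclass(frozen=True)
class Traveler:
    """A query cursor: the current element plus named mark snapshots.

    Marks are captured when an ``as`` step runs and are never mutated by
    later traversal; re-marking a name replaces the snapshot.
    """

    current: Vertex | Edge
    marks: dict[str, Vertex | Edge] = field(default_factory=dict)

    def with_current(self, elem: Vertex | Edge) -> "Traveler":
        return Traveler(elem, self.marks)

    def with_mark(self, name: str) -> "Traveler":
        return Traveler(self.current, {**self.marks, name: self.current})


# -- parsing ------------------------------------------------------------------


def _as_str_list(args: Any, op: str) -> tuple[str, ...]:
    if args is None:
        return ()
    if isinstance(args, str):
        return (args,)
    if isinstance(args, (list, tuple)) and all(isinstance(a, str) for a in args):
        return tuple(args)
    raise QueryError(f"step {op!r}: expected a string or list of strings, got {args!r}")


def parse_condition(doc: Any) -> Condition:
    if not isinstance(doc, dict) or "op" not in doc:
        raise QueryError(f"malformed condition: {doc!r}")
    op = doc["op"]
    if op in _NODE_OPS:
        children = doc.get("children")
        if not isinstance(children, list):
            raise QueryError(f"condition {op!r} requires a children list")
        return Condition(op, children=tuple(parse_condition(c) for c in children))
    if op in _LEAF_OPS:
        if "field" not in doc:
            raise QueryError(f"condition {op!r} missing field")
        return Condition(op, field_path=parse_field_path(doc["field"]), value=doc.get("value"))
    raise QueryError(f"unknown condition op {op!r}")


def _parse_step(rec: Any) -> Step:
    if not isinstance(rec, dict) or "op" not in rec:
        raise QueryError(f"malformed step record: {rec!r}")
    op = rec["op"]
    if op == "as_":  # Python clients spell the mark step with a trailing underscore
        op = "as"
    if op not in STEP_OPS:
        raise QueryError(f"unknown step {op!r}")
    args = rec.get("args")

    if op == "V":
        return Step("V", gids=_as_str_list(args, op))
    if op == "hasId":
        return Step("hasId", gids=_as_str_list(args, op))
    if op in ("hasLabel", "out", "in", "outE", "inE"):
        return Step(op, labels=_as_str_list(args, op))
    if op == "has":
        return Step("has", condition=parse_condition(args))
    if op in ("as", "select"):
        if not isinstance(args, str) or not args:
            raise QueryError(f"step {op!r}: expected a non-empty mark name")
        return Step(op, name=args)
    if op in ("render", "distinct"):
        paths = _as_str_list(args, op)
        if not paths:
            raise QueryError(f"step {op!r}: expected at least one field path")
        return Step(op, fields=tuple(parse_field_path(p) for p in paths))
    if op == "aggregate":
        recs = args if isinstance(args, list) else [args]
        aggs = []
        for a in recs:
            if not isinstance(a, dict) or "name" not in a or "field" not in a:
                raise QueryError(f"aggregate: expected {{name, field}} records, got {a!r}")
            aggs.append(TermAggregation(a["name"], parse_field_path(a["field"])))
        names = [a.name for a in aggs]
        if len(set(names)) != len(names):
            raise QueryError(f"aggregate: duplicate aggregation names in {names}")
        return Step("aggregate", aggregations=tuple(aggs))
    if op == "count":
        return Step("count")
    if op == "limit":
        if not isinstance(args, int) or isinstance(args, bool):
            raise QueryError(f"limit: expected an integer, got {args!r}")
        return Step("limit", n=args)
    raise QueryError(f"unknown step {op!r}")


def parse_query(document: Sequence[Any]) -> Query:
    """Parse a query document (list of ``{"op": ..., "args": ...}`` records)."""
    if not isinstance(document, (list, tuple)) or not document:
        raise QueryError("query document must be a non-empty list of steps")
    return Query([_parse_step(rec) for rec in document])


def compile_query(query: Query) -> Query:
    """Validate a parsed query and mark it executable.

    Checks: the first (and only the first) step is ``V``; terminal steps are
    not followed by further steps; every mark referenced by ``select``,
    ``render``, ``distinct``, ``aggregate``, or a ``has`` condition was
    defined by a preceding ``as``; ``limit`` is non-negative.
    """
    steps = query.steps
    if not steps:
        raise QueryError("empty query")
    if steps[0].op != "V":
        raise QueryError("query must start with V")
    defined: set[str] = set()
    for i, step in enumerate(steps):
        if i > 0 and step.op == "V":
            raise QueryError("V may only appear as the first step")
        if i > 0 and steps[i - 1].op in TERMINAL_OPS:
            raise QueryError(f"step {step.op!r} follows terminal step {steps[i - 1].op!r}")
        if step.op == "limit" and step.n < 0:
            raise QueryError("limit requires a non-negative count")
        if step.op == "as":
            defined.add(step.name)
        marks_used: list[str] = []
        if step.op == "select":
            marks_used.append(step.name)
        for fp in step.fields:
            if fp.mark:
                marks_used.append(fp.mark)
        for agg in step.aggregations:
            if agg.field_path.mark:
                marks_used.append(agg.field_path.mark)
        if step.condition is not None:
            stack = [step.condition]
            while stack:
                c = stack.pop()
                if c.field_path is not None and c.field_path.mark:
                    marks_used.append(c.field_path.mark)
                stack.extend(c.children)
        for m in marks_used:
            if m not in defined:
                raise QueryError(f"mark {m!r} referenced before being set by as")
    query.compiled = True
    return query


def query_to_document(query: Query) -> list[dict[str, Any]]:
    """Serialize a Query back to the step-record document form."""

    def cond_doc(c: Condition) -> dict[str, Any]:
        if c.op in _NODE_OPS:
            return {"op": c.op, "children": [cond_doc(ch) for ch in c.children]}
        return {"op": c.op, "field": str(c.field_path), "value": c.value}

    out: list[dict[str, Any]] = []
    for s in query.steps:
        if s.op in ("V", "hasId"):
            out.append({"op": s.op, "args": list(s.gids)})
        elif s.op in ("hasLabel", "out", "in", "outE", "inE"):
            out.append({"op": s.op, "args": list(s.labels)})
        elif s.op == "has":
            out.append({"op": "has", "args": cond_doc(s.condition)})
        elif s.op in ("as", "select"):
            out.append({"op": s.op, "args": s.name})
        elif s.op in ("render", "distinct"):
            out.append({"op": s.op, "args": [str(f) for f in s.fields]})
        elif s.op == "aggregate":
            out.append(
                {
                    "op": "aggregate",
                    "args": [{"name": a.name, "field": str(a.field_path)} for a in s.aggregations],
                }
            )
        elif s.op == "count":
            out.append({"op": "count"})
        elif s.op == "limit":
            out.append({"op": "limit", "args": s.n})
    return out
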