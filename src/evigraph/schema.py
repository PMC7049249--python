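"""Evidence-graph schema: vertex labels and legal edge triples, shipped as data.

The built-in schema covers the cohort tree (Program/Project/Case/Sample/
Aliquot), somatic callsets and alleles, genes/transcripts/pathways, drug
response, expression, and literature-derived genotype-to-phenotype
associations. It is loaded from a YAML package resource and can be replaced
by any user-supplied YAML/JSON file with the same keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class SchemaError(Exception):
    pass


@dataclass(frozen=True)
class SchemaDef:
    vertex_labels: frozenset[str]
    edge_triples: frozenset[tuple[str, str, str]]
    required_fields: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frm, lbl, to in self.edge_triples:
            if frm not in self.vertex_labels or to not in self.vertex_labels:
                raise SchemaError(
                    f"edge triple ({frm}, {lbl}, {to}) references an undeclared vertex label"
                )

    def to_dict(self) -> dict:
        return {
            "vertex_labels": sorted(self.vertex_labels),
            "edge_triples": [list(t) for t in sorted(self.edge_triples)],
            "required_fields": self.required_fields,
        }


def _schema_from_dict(doc: dict) -> SchemaDef:
    labels = frozenset(doc.get("vertex_labels") or [])
    triples = frozenset(tuple(t) for t in (doc.get("edge_triples") or []))
    for t in triples:
        if len(t) != 3:
            raise SchemaError(f"edge triple must have 3 elements: {t!r}")
    required = {k: list(v) for k, v in (doc.get("required_fields") or {}).items()}
    return SchemaDef(labels, triples, required)


def bmeg_schema() -> SchemaDef:
    """The built-in cancer-genomics evidence-graph schema."""
    text = resources.files("evigraph.data").joinpath("bmeg_schema.yaml").read_text("utf-8")
    return _schema_from_dict(yaml.safe_load(text))


def load_schema(path: str | Path) -> SchemaDef:
    """Load a SchemaDef from a YAML or JSON file and consistency-check it."""
    text = Path(path).read_text(encoding="utf-8")
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: schema document must be a mapping")
    return _schema_from_dict(doc)


def write_schema(schema: SchemaDef, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(schema.to_dict(), sort_keys=False), encoding="utf-8")
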