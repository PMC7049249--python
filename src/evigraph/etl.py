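"""Loaders from standard bioinformatics file formats to graph elements.

Each loader converts one toy-scale source file into schema-conformant
vertices and edges:

* ``load_maf`` -- MAF-like somatic variant TSVs into per-aliquot callsets
  with deduplicated Allele vertices; the calling-method list and gene
  annotation live on the callset->allele edge.
* ``load_pathways_gmt`` -- GMT gene sets into Pathway/Gene vertices with
  membership edges in both directions.
* ``load_expression_matrix`` -- aliquot x gene TPM TSVs into per-aliquot
  GeneExpression vertices holding the dense values map.
* ``load_drug_response`` -- CSV screening tables into DrugResponse and
  Compound vertices, deriving Compound->Project edges from which projects'
  samples tested each compound.
* ``load_g2p`` -- JSON Lines association records wired to existing Allele
  vertices by their chrom:start:ref:alt key.

Loaders return a :class:`GraphElements` bundle; merge bundles into one
:class:`~evigraph.graph.Graph` with :func:`merge_elements` or
``GraphElements.to_graph``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .graph import Edge, Graph, GraphError, Vertex


class EtlError(Exception):
    pass


@dataclass
class GraphElements:
    vertices: list[Vertex] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def vertex(self, gid: str, label: str, data: dict | None = None) -> str:
        self.vertices.append(Vertex(gid, label, data or {}))
        return gid

    def edge(self, from_gid: str, label: str, to_gid: str, data: dict | None = None) -> None:
        gid = f"({from_gid})--({label})->({to_gid})"
        self.edges.append(Edge(gid, from_gid, to_gid, label, data or {}))

    def to_graph(self) -> Graph:
        graph = Graph()
        for v in self.vertices:
            graph.add_vertex(v)
        for e in self.edges:
            graph.add_edge(e)
        return graph.finalize()


def merge_elements(graph: Graph, elements: GraphElements, skip_existing: bool = True) -> Graph:
    """Add loader output to an existing graph.

    With ``skip_existing``, vertices/edges whose gid is already present are
    left untouched (loaders re-create shared anchors such as Aliquot or Gene
    vertices); without it, collisions raise."""
    for v in elements.vertices:
        if skip_existing and v.gid in graph.vertices:
            continue
        graph.add_vertex(v)
    for e in elements.edges:
        if skip_existing and e.gid in graph.edges:
            continue
        graph.add_edge(e)
    return graph.finalize()


# -- MAF ---------------------------------------------------------------------

#: Default source-column names for the minimal MAF dialect.
MAF_COLUMNS = {
    "tumor_aliquot_id": "Tumor_Sample_Barcode",
    "hugo_symbol": "Hugo_Symbol",
    "ensembl_gene": "Gene",
    "chromosome": "Chromosome",
    "start": "Start_Position",
    "reference_allele": "Reference_Allele",
    "alternate_allele": "Tumor_Seq_Allele2",
    "callers": "CENTERS",
}

_ALLELE_CHARS = set("ACGT-")


def allele_gid(chromosome: str, start: int, ref: str, alt: str) -> str:
    return f"Allele:{chromosome}:{start}:{ref}:{alt}"


def load_maf(path: str | Path, project_gid: str, columns: dict[str, str] | None = None) -> GraphElements:
    """Load a MAF-like somatic variant TSV.

    Emits one SomaticCallset per tumor aliquot, Allele vertices deduplicated
    by (chromosome, start, ref, alt) so repeated variants across samples
    share one vertex, and callset->allele edges carrying
    ``{"methods": [...], "ensembl_gene": ...}``. Caller lists are
    pipe-separated in the source (``MUTECT|MUSE``); a trailing ``*`` on a
    caller name is stripped.
    """
    colmap = {**MAF_COLUMNS, **(columns or {})}
    out = GraphElements()
    aliquots: dict[str, str] = {}   # aliquot id -> callset gid
    alleles: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise EtlError(f"{path}: empty file")
        for fld, col in colmap.items():
            if col not in reader.fieldnames:
                raise EtlError(f"{path}: missing required column {col!r} (for {fld})")
        for lineno, row in enumerate(reader, start=2):
            rec = {fld: (row[col] or "").strip() for fld, col in colmap.items()}
            try:
                start = int(rec["start"])
            except ValueError:
                raise EtlError(f"{path}:{lineno}: non-integer start {rec['start']!r}") from None
            if start < 1:
                raise EtlError(f"{path}:{lineno}: start must be >= 1")
            ref, alt = rec["reference_allele"], rec["alternate_allele"]
            for a in (ref, alt):
                if not a or not set(a) <= _ALLELE_CHARS:
                    raise EtlError(f"{path}:{lineno}: malformed allele {a!r}")
            callers = [c.strip().rstrip("*") for c in rec["callers"].split("|") if c.strip()]
            aid = rec["tumor_aliquot_id"]
            if not aid:
                raise EtlError(f"{path}:{lineno}: empty tumor aliquot id")
            if aid not in aliquots:
                a_gid = out.vertex(f"Aliquot:{aid}", "Aliquot", {"aliquot_id": aid})
                cs_gid = out.vertex(f"SomaticCallset:{aid}", "SomaticCallset", {})
                out.edge(a_gid, "somatic_callsets", cs_gid)
                aliquots[aid] = cs_gid
            v_gid = allele_gid(rec["chromosome"], start, ref, alt)
            if v_gid not in alleles:
                alleles.add(v_gid)
                out.vertex(
                    v_gid,
                    "Allele",
                    {
                        "chromosome": rec["chromosome"],
                        "start": start,
                        "reference_allele": ref,
                        "alternate_allele": alt,
                        "hugo_symbol": rec["hugo_symbol"],
                    },
                )
            out.edge(
                aliquots[aid], "alleles", v_gid,
                {"methods": callers, "ensembl_gene": rec["ensembl_gene"]},
            )
    return out


# -- GMT ---------------------------------------------------------------------


def load_pathways_gmt(path: str | Path) -> GraphElements:
    """Load GMT gene sets: one Pathway per line, membership edges both ways."""
    out = GraphElements()
    genes_seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EtlError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, description = fields[0], fields[1]
            pw_gid = out.vertex(f"Pathway:{name}", "Pathway", {"name": name, "description": description})
            members = list(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            for g in members:
                if g not in genes_seen:
                    genes_seen.add(g)
                    out.vertex(g, "Gene", {})
                out.edge(pw_gid, "genes", g)
                out.edge(g, "pathways", pw_gid)
    return out


# -- expression matrix -------------------------------------------------------


def load_expression_matrix(
    path: str | Path, program_gid: str = "", create_missing_aliquots: bool = True
) -> GraphElements:
    """Load an aliquot x gene TPM matrix (TSV; first column = aliquot id).

    One GeneExpression vertex per row holding the dense
    ``{"values": {gene: tpm}, "metric": "TPM"}`` payload."""
    out = GraphElements()
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EtlError(f"{path}: empty file") from None
        genes = [g.strip() for g in header[1:]]
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            aid = row[0].strip()
            if len(row) != len(genes) + 1:
                raise EtlError(f"{path}:{lineno}: expected {len(genes) + 1} columns, got {len(row)}")
            values: dict[str, float] = {}
            for g, cell in zip(genes, row[1:]):
                try:
                    tpm = float(cell)
                except ValueError:
                    raise EtlError(f"{path}:{lineno}: non-numeric TPM {cell!r}") from None
                if tpm < 0:
                    raise EtlError(f"{path}:{lineno}: negative TPM {tpm} for {g}")
                values[g] = tpm
            a_gid = f"Aliquot:{aid}"
            if create_missing_aliquots:
                out.vertex(a_gid, "Aliquot", {"aliquot_id": aid})
            ge_gid = out.vertex(
                f"GeneExpression:{aid}", "GeneExpression", {"values": values, "metric": "TPM"}
            )
            out.edge(a_gid, "gene_expressions", ge_gid)
    return out


# -- drug response -----------------------------------------------------------

DRUG_RESPONSE_COLUMNS = ("sample_id", "project_id", "compound_id", "submitter_compound_id", "ec50")


def load_drug_response(path: str | Path, program_gid: str = "") -> GraphElements:
    """Load a CSV drug-response table.

    Required columns: sample_id, project_id, compound_id,
    submitter_compound_id, ec50; optional: auc, synonym. Emits DrugResponse
    vertices per row, Compound vertices deduplicated by compound id, and the
    derived Compound->Project edge for each project whose samples tested the
    compound."""
    out = GraphElements()
    aliquots: set[str] = set()
    compounds: dict[str, str] = {}
    projects: set[str] = set()
    compound_projects: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EtlError(f"{path}: empty file")
        for col in DRUG_RESPONSE_COLUMNS:
            if col not in reader.fieldnames:
                raise EtlError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            sid = (row["sample_id"] or "").strip()
            cid = (row["compound_id"] or "").strip()
            pid = (row["project_id"] or "").strip()
            submitter = (row["submitter_compound_id"] or "").strip()
            if not sid or not cid or not pid:
                raise EtlError(f"{path}:{lineno}: empty sample/compound/project id")
            try:
                ec50 = float(row["ec50"])
            except (TypeError, ValueError):
                raise EtlError(f"{path}:{lineno}: non-numeric ec50 {row['ec50']!r}") from None
            if ec50 <= 0:
                raise EtlError(f"{path}:{lineno}: ec50 must be positive, got {ec50}")
            auc_raw = (row.get("auc") or "").strip()
            try:
                auc = float(auc_raw) if auc_raw else None
            except ValueError:
                raise EtlError(f"{path}:{lineno}: non-numeric auc {auc_raw!r}") from None

            a_gid = f"Aliquot:{sid}"
            if a_gid not in aliquots:
                aliquots.add(a_gid)
                out.vertex(a_gid, "Aliquot", {"aliquot_id": sid})
            p_gid = f"Project:{pid}"
            if p_gid not in projects:
                projects.add(p_gid)
                out.vertex(p_gid, "Project", {"project_id": pid})
            c_gid = f"Compound:{cid}"
            if c_gid not in compounds:
                synonym = (row.get("synonym") or "").strip() or submitter.upper()
                compounds[c_gid] = out.vertex(c_gid, "Compound", {"synonym": synonym})
            dr_gid = out.vertex(
                f"DrugResponse:{sid}:{cid}",
                "DrugResponse",
                {"ec50": ec50, "auc": auc, "submitter_compound_id": submitter},
            )
            out.edge(a_gid, "drug_response", dr_gid)
            out.edge(dr_gid, "compounds", c_gid)
            if (c_gid, p_gid) not in compound_projects:
                compound_projects.add((c_gid, p_gid))
                out.edge(c_gid, "projects", p_gid)
    return out


# -- genotype-to-phenotype associations --------------------------------------


def load_g2p(path: str | Path, graph: Graph) -> GraphElements:
    """Load JSON Lines association records against an existing graph.

    Each record links an allele (by its ``chrom:start:ref:alt`` key) to
    compounds, publications, and a phenotype. Records whose allele key
    matches no Allele vertex in ``graph`` are skipped with a warning rather
    than failing the load."""
    out = GraphElements()
    allele_index = {
        v.gid.split(":", 1)[1]: v.gid for v in graph.vertices.values() if v.label == "Allele"
    }
    seen_compounds: set[str] = set()
    seen_pubs: set[str] = set()
    seen_phenos: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EtlError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from None
            try:
                assoc_id = rec["association_id"]
                allele_key = rec["allele_key"]
            except KeyError as exc:
                raise EtlError(f"{path}:{lineno}: record missing field {exc}") from None
            compound_ids = rec.get("compound_ids") or []
            publication_urls = rec.get("publication_urls") or []
            if not compound_ids and not publication_urls:
                raise EtlError(
                    f"{path}:{lineno}: association needs at least one compound or publication"
                )
            if allele_key not in allele_index:
                out.warnings.append(
                    f"{path}:{lineno}: allele key {allele_key!r} matches no Allele vertex; skipped"
                )
                continue
            assoc_gid = out.vertex(
                f"G2PAssociation:{assoc_id}",
                "G2PAssociation",
                {"description": rec.get("description", ""), "phenotype": rec.get("phenotype", "")},
            )
            out.edge(allele_index[allele_key], "g2p_associations", assoc_gid)
            for url in publication_urls:
                pub_gid = f"Publication:{url}"
                if pub_gid not in seen_pubs:
                    seen_pubs.add(pub_gid)
                    out.vertex(pub_gid, "Publication", {"url": url})
                out.edge(assoc_gid, "publications", pub_gid)
            for cid in compound_ids:
                c_gid = f"Compound:{cid}"
                if c_gid not in seen_compounds:
                    seen_compounds.add(c_gid)
                    out.vertex(c_gid, "Compound", {})
                out.edge(assoc_gid, "compounds", c_gid)
            phenotype = (rec.get("phenotype") or "").strip()
            if phenotype:
                ph_gid = f"Phenotype:{phenotype}"
                if ph_gid not in seen_phenos:
                    seen_phenos.add(ph_gid)
                    out.vertex(ph_gid, "Phenotype", {"term": phenotype})
                out.edge(assoc_gid, "phenotypes", ph_gid)
    return out
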