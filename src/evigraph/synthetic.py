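"""Seeded generator of a schema-conformant miniature evidence graph.

The generated graph emulates, at desk scale, the shape of the public
cancer-genomics resources the full evidence graph integrates:

* a patient-like program (TCGA-style) whose projects hold cases with
  tumor/normal samples, aliquots, and MC3-style somatic callsets whose
  callset->allele edges carry the calling ``methods`` list and the
  ``ensembl_gene`` of the hit;
* a cell-line-like program (CTRP/CCLE-style) whose first project carries
  drug-response experiments (EC50, AUC) and whose second project carries
  per-aliquot TPM expression vectors, with ``same_as`` links pairing the
  same cell line across the two screens;
* gene/pathway membership edges in both directions (Pathway Commons-style);
* literature-derived genotype-to-phenotype associations wiring alleles to
  compounds, publications, and phenotypes.

Alongside the graph, :func:`generate` records a :class:`GroundTruth` with
the exact expected result rows of the eight cookbook queries, computed by
direct bookkeeping over the side tables built during generation -- never by
the query engine. Agreement of the engine with this bookkeeping is the
package's core end-to-end check.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from .graph import Edge, Graph, Vertex, write_graph_jsonl

COOKBOOK_IDS = ("q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8")

#: Conventional gids of the default fixture, used as cookbook defaults.
DEFAULT_PROJECT = "Project:TCGA-BRCA"
DEFAULT_PROGRAM = "Program:CTRP"
DEFAULT_PROJECT_ID = "CTRP_Breast_Cancer"
#: The generator guarantees this compound is both G2P-associated and screened.
DEFAULT_COMPOUND = "Compound:CID000001"


class SyntheticError(Exception):
    pass


@dataclass
class SyntheticConfig:
    """Knobs of the miniature cohort; defaults give a ~500-vertex graph."""

    seed: int = 42
    n_programs: int = 2                      # first patient-like, second cell-line-like
    n_projects_per_program: int = 2
    n_cases_per_project: int = 20
    tumor_fraction: float = 0.8
    n_genes: int = 50
    n_alleles: int = 60                      # distinct-variant pool
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (3, 12)
    mutations_per_case_range: tuple[int, int] = (1, 15)
    caller_pool: tuple[str, ...] = ("MUTECT", "MUSE", "VARSCAN")
    p_mutect: float = 0.7
    n_compounds: int = 8
    compounds_tested_range: tuple[int, int] = (2, 5)
    n_g2p: int = 30
    n_publications: int = 12
    n_phenotypes: int = 6
    p_same_as: float = 0.5
    ec50_log10_range: tuple[float, float] = (-5.0, 0.0)
    expression_mu: float = 2.0               # log-normal of TPM values
    expression_sigma: float = 1.0

    def validate(self) -> None:
        for name in (
            "n_programs", "n_projects_per_program", "n_cases_per_project",
            "n_genes", "n_alleles", "n_pathways", "n_compounds", "n_g2p",
            "n_publications", "n_phenotypes",
        ):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")
        for name in ("tumor_fraction", "p_mutect", "p_same_as"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SyntheticError(f"{name} must be in [0, 1]")
        wants_mutations = (
            self.n_programs > 0
            and self.n_cases_per_project > 0
            and self.mutations_per_case_range[1] > 0
        )
        if wants_mutations and (self.n_genes == 0 or self.n_alleles == 0):
            raise SyntheticError("mutations requested but gene/allele pool is empty")
        if self.n_pathways > 0 and self.n_genes == 0:
            raise SyntheticError("pathways requested but gene pool is empty")


@dataclass
class GroundTruth:
    """Expected cookbook results recorded during generation, plus the inputs
    (gene/compound/sample lists) each chained query starts from and a few
    conservation tallies used by integrity checks."""

    rows: dict[str, list[Any]] = field(default_factory=dict)
    inputs: dict[str, Any] = field(default_factory=dict)
    tallies: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"rows": self.rows, "inputs": self.inputs, "tallies": self.tallies}

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "GroundTruth":
        return cls(rows=doc["rows"], inputs=doc["inputs"], tallies=doc["tallies"])


def _buckets(counts: Counter) -> list[dict[str, Any]]:
    """Aggregation buckets: count descending, key ascending on ties."""
    return [
        {"key": k, "value": counts[k]}
        for k in sorted(counts, key=lambda k: (-counts[k], k))
    ]


_SYLLABLES = ("VE", "LU", "TRA", "MI", "SO", "RA", "PA", "NI", "DO", "FE")


def _compound_synonym(rng: random.Random, index: int) -> str:
    stem = "".join(rng.choice(_SYLLABLES) for _ in range(3))
    return f"{stem}{'TINIB' if index % 2 else 'MAB'}"


class _Builder:
    """Accumulates vertices/edges in a fixed order plus bookkeeping tables."""

    def __init__(self) -> None:
        self.vertices: list[Vertex] = []
        self.edges: list[Edge] = []
        self._vseen: set[str] = set()

    def vertex(self, gid: str, label: str, data: dict | None = None) -> str:
        if gid in self._vseen:
            raise SyntheticError(f"generator emitted duplicate vertex gid {gid!r}")
        self._vseen.add(gid)
        self.vertices.append(Vertex(gid, label, data or {}))
        return gid

    def edge(self, from_gid: str, label: str, to_gid: str, data: dict | None = None) -> None:
        gid = f"({from_gid})--({label})->({to_gid})"
        self.edges.append(Edge(gid, from_gid, to_gid, label, data or {}))

    def build(self) -> Graph:
        g = Graph()
        for v in self.vertices:
            g.add_vertex(v)
        for e in self.edges:
            g.add_edge(e)
        return g.finalize()


def generate(config: SyntheticConfig | None = None) -> tuple[Graph, GroundTruth]:
    """Generate the miniature evidence graph and its recorded ground truth."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = random.Random(cfg.seed)
    b = _Builder()

    # ---- cohort tree: programs, projects, cases, samples, aliquots ---------
    patient_names = ["TCGA-BRCA", "TCGA-LUAD"] + [
        f"TCGA-X{i:02d}" for i in range(max(0, cfg.n_projects_per_program - 2))
    ]
    screen_tags = ["CTRP", "CCLE"] + [
        f"SCREEN{i:02d}" for i in range(max(0, cfg.n_projects_per_program - 2))
    ]

    project_cases: dict[str, list[str]] = {}
    project_id_of: dict[str, str] = {}
    case_sample: dict[str, str] = {}
    case_is_tumor: dict[str, bool] = {}
    sample_aliquot: dict[str, str] = {}
    case_same_as: dict[str, list[str]] = {}
    patient_projects: list[str] = []
    cellline_projects: list[str] = []

    for p in range(cfg.n_programs):
        is_cellline = p == 1
        program_name = "CTRP" if is_cellline else ("TCGA" if p == 0 else f"PRG{p}")
        program_gid = b.vertex(f"Program:{program_name}", "Program", {"program_id": program_name})
        for j in range(cfg.n_projects_per_program):
            if is_cellline:
                name = f"{screen_tags[j]}_Breast_Cancer"
            elif p == 0:
                name = patient_names[j]
            else:
                name = f"{program_name}-P{j:02d}"
            project_gid = b.vertex(f"Project:{name}", "Project", {"project_id": name})
            project_id_of[project_gid] = name
            b.edge(program_gid, "projects", project_gid)
            (cellline_projects if is_cellline else patient_projects if p == 0 else []).append(
                project_gid
            )
            project_cases[project_gid] = []
            for i in range(cfg.n_cases_per_project):
                if is_cellline:
                    local = f"{screen_tags[j]}:ACH-{i + 1:06d}"
                else:
                    local = f"{name}-{i + 1:04d}"
                case_gid = b.vertex(f"Case:{local}", "Case", {"case_id": local})
                b.edge(project_gid, "cases", case_gid)
                project_cases[project_gid].append(case_gid)
                tumor = rng.random() < cfg.tumor_fraction
                stype = "Primary Tumor" if tumor else "Blood Derived Normal"
                sample_gid = b.vertex(
                    f"Sample:{local}", "Sample", {"gdc_attributes": {"sample_type": stype}}
                )
                b.edge(case_gid, "samples", sample_gid)
                b.edge(sample_gid, "case", case_gid)
                case_sample[case_gid] = sample_gid
                case_is_tumor[case_gid] = tumor
                aliquot_gid = b.vertex(f"Aliquot:{local}", "Aliquot", {"aliquot_id": local})
                b.edge(sample_gid, "aliquots", aliquot_gid)
                sample_aliquot[sample_gid] = aliquot_gid
        # same_as pairs: the same cell line indexed across the screen projects
        if is_cellline and cfg.n_projects_per_program >= 2:
            projs = cellline_projects
            for i in range(cfg.n_cases_per_project):
                if rng.random() >= cfg.p_same_as:
                    continue
                anchor = project_cases[projs[0]][i]
                for other in projs[1:]:
                    partner = project_cases[other][i]
                    b.edge(anchor, "same_as", partner)
                    b.edge(partner, "same_as", anchor)
                    case_same_as.setdefault(anchor, []).append(partner)
                    case_same_as.setdefault(partner, []).append(anchor)

    # ---- genes and distinct-allele pool ------------------------------------
    gene_gids = [
        b.vertex(f"ENSG{i + 1:011d}", "Gene", {"symbol": f"SYG{i + 1}"})
        for i in range(cfg.n_genes)
    ]
    allele_gids: list[str] = []
    allele_gene: dict[str, str] = {}
    seen_keys: set[tuple] = set()
    while len(allele_gids) < cfg.n_alleles:
        chrom = str(rng.randint(1, 22))
        start = rng.randint(1, 50_000_000)
        ref, alt = rng.sample("ACGT", 2)
        key = (chrom, start, ref, alt)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        gid = b.vertex(
            f"Allele:{chrom}:{start}:{ref}:{alt}",
            "Allele",
            {
                "chromosome": chrom,
                "start": start,
                "reference_allele": ref,
                "alternate_allele": alt,
            },
        )
        allele_gids.append(gid)
        allele_gene[gid] = rng.choice(gene_gids)

    # ---- pathways (membership edges in both directions) --------------------
    pathway_members: dict[str, list[str]] = {}
    gene_pathways: dict[str, list[str]] = {g: [] for g in gene_gids}
    for k in range(cfg.n_pathways):
        pw = b.vertex(f"Pathway:synthetic.pc/PW{k + 1:04d}", "Pathway", {"name": f"PW{k + 1}"})
        size = rng.randint(*cfg.pathway_size_range)
        members = [gene_gids[i] for i in sorted(rng.sample(range(cfg.n_genes), min(size, cfg.n_genes)))]
        pathway_members[pw] = members
        for g in members:
            b.edge(pw, "genes", g)
            b.edge(g, "pathways", pw)
            gene_pathways[g].append(pw)

    # ---- somatic callsets: patient program only ----------------------------
    callset_alleles: dict[str, list[tuple[str, list[str], str]]] = {}
    for project_gid in patient_projects:
        for case_gid in project_cases[project_gid]:
            if not case_is_tumor[case_gid]:
                continue
            aliquot_gid = sample_aliquot[case_sample[case_gid]]
            local = aliquot_gid.split(":", 1)[1]
            callset_gid = b.vertex(f"SomaticCallset:{local}", "SomaticCallset", {})
            b.edge(aliquot_gid, "somatic_callsets", callset_gid)
            n_mut = rng.randint(*cfg.mutations_per_case_range)
            chosen = sorted(rng.sample(range(cfg.n_alleles), min(n_mut, cfg.n_alleles)))
            hits: list[tuple[str, list[str], str]] = []
            for idx in chosen:
                allele = allele_gids[idx]
                methods = [c for c in cfg.caller_pool
                           if rng.random() < (cfg.p_mutect if c == "MUTECT" else 0.5)]
                if not methods:
                    methods = [rng.choice(cfg.caller_pool)]
                gene = allele_gene[allele]
                b.edge(callset_gid, "alleles", allele,
                       {"methods": methods, "ensembl_gene": gene})
                hits.append((allele, methods, gene))
            callset_alleles[case_gid] = hits

    # ---- compounds, publications, phenotypes -------------------------------
    compound_gids = []
    compound_synonym: dict[str, str] = {}
    for i in range(cfg.n_compounds):
        syn = _compound_synonym(rng, i)
        gid = b.vertex(f"Compound:CID{i + 1:06d}", "Compound", {"synonym": syn})
        compound_gids.append(gid)
        compound_synonym[gid] = syn
    pub_gids = []
    pmids = rng.sample(range(10_000_000, 40_000_000), cfg.n_publications)
    for pmid in pmids:
        pub_gids.append(
            b.vertex(f"Publication:ncbi.nlm.nih.gov/pubmed/{pmid}", "Publication", {})
        )
    pheno_gids = [
        b.vertex(f"Phenotype:PH{i + 1:02d}", "Phenotype", {"term": f"synthetic phenotype {i + 1}"})
        for i in range(cfg.n_phenotypes)
    ]

    # ---- genotype-to-phenotype associations --------------------------------
    # The first tumor-emitted BRCA allele is guaranteed to be linked to the
    # first compound so that the q5 -> q6 chain is non-empty by construction.
    anchor_allele: str | None = None
    if patient_projects:
        for case_gid in project_cases[patient_projects[0]]:
            if case_gid in callset_alleles and callset_alleles[case_gid]:
                anchor_allele = callset_alleles[case_gid][0][0]
                break

    allele_assocs: dict[str, list[str]] = {a: [] for a in allele_gids}
    assoc_pubs: dict[str, list[str]] = {}
    assoc_compounds: dict[str, list[str]] = {}
    for a in range(cfg.n_g2p):
        assoc_gid = b.vertex(
            f"G2PAssociation:A{a + 1:04d}",
            "G2PAssociation",
            {"description": f"synthetic association {a + 1}"},
        )
        if a == 0 and anchor_allele is not None and compound_gids:
            allele = anchor_allele
            compounds = [compound_gids[0]]
            if cfg.n_compounds > 1 and rng.random() < 0.5:
                compounds.append(rng.choice(compound_gids[1:]))
        else:
            allele = rng.choice(allele_gids) if allele_gids else None
            k = rng.randint(1, min(2, cfg.n_compounds)) if cfg.n_compounds else 0
            compounds = rng.sample(compound_gids, k) if k else []
        pubs = rng.sample(pub_gids, rng.randint(1, min(2, cfg.n_publications))) if pub_gids else []
        if allele is not None:
            b.edge(allele, "g2p_associations", assoc_gid)
            allele_assocs[allele].append(assoc_gid)
        for pub in pubs:
            b.edge(assoc_gid, "publications", pub)
        for c in compounds:
            b.edge(assoc_gid, "compounds", c)
        if pheno_gids:
            b.edge(assoc_gid, "phenotypes", rng.choice(pheno_gids))
        assoc_pubs[assoc_gid] = pubs
        assoc_compounds[assoc_gid] = compounds

    # ---- drug response: first cell-line project ----------------------------
    aliquot_responses: dict[str, list[tuple[str, str, float, float, str]]] = {}
    compound_projects: dict[str, list[str]] = {c: [] for c in compound_gids}
    if cellline_projects and compound_gids:
        screen_project = cellline_projects[0]
        for i, case_gid in enumerate(project_cases[screen_project]):
            aliquot_gid = sample_aliquot[case_sample[case_gid]]
            k = rng.randint(*cfg.compounds_tested_range)
            idxs = sorted(rng.sample(range(cfg.n_compounds), min(k, cfg.n_compounds)))
            if i == 0 and 0 not in idxs:  # guarantee the shared compound is screened
                idxs = sorted([0] + idxs)
            rows = []
            for idx in idxs:
                compound = compound_gids[idx]
                ec50 = round(10 ** rng.uniform(*cfg.ec50_log10_range), 10)
                auc = round(rng.uniform(0.1, 0.95), 4)
                submitter = compound_synonym[compound].lower()
                local = aliquot_gid.split(":", 1)[1]
                dr_gid = b.vertex(
                    f"DrugResponse:{local}:{compound.split(':', 1)[1]}",
                    "DrugResponse",
                    {"ec50": ec50, "auc": auc, "submitter_compound_id": submitter},
                )
                b.edge(aliquot_gid, "drug_response", dr_gid)
                b.edge(dr_gid, "compounds", compound)
                if screen_project not in compound_projects[compound]:
                    b.edge(compound, "projects", screen_project)
                    compound_projects[compound].append(screen_project)
                rows.append((dr_gid, compound, ec50, auc, submitter))
            aliquot_responses[aliquot_gid] = rows

    # ---- expression: remaining cell-line projects --------------------------
    aliquot_expression: dict[str, dict[str, float]] = {}
    for project_gid in cellline_projects[1:]:
        for case_gid in project_cases[project_gid]:
            aliquot_gid = sample_aliquot[case_sample[case_gid]]
            values = {g: round(rng.lognormvariate(cfg.expression_mu, cfg.expression_sigma), 4)
                      for g in gene_gids}
            local = aliquot_gid.split(":", 1)[1]
            ge_gid = b.vertex(
                f"GeneExpression:{local}", "GeneExpression", {"values": values, "metric": "TPM"}
            )
            b.edge(aliquot_gid, "gene_expressions", ge_gid)
            aliquot_expression[aliquot_gid] = values

    graph = b.build()

    # ---- ground truth by direct bookkeeping (no engine) --------------------
    gt = GroundTruth()
    brca = patient_projects[0] if patient_projects else None

    def tumor_hits(project_gid: str):
        """(case, allele, methods, gene) per callset->allele edge, traversal order."""
        for case_gid in project_cases.get(project_gid, []):
            if not case_is_tumor.get(case_gid, False):
                continue
            for allele, methods, gene in callset_alleles.get(case_gid, []):
                yield case_gid, allele, methods, gene

    # q1: per-gene MUTECT mutation counts in the patient project
    q1_counts: Counter = Counter()
    mutect_pairs = 0
    if brca:
        for _case, _allele, methods, gene in tumor_hits(brca):
            if "MUTECT" in methods:
                q1_counts[gene] += 1
                mutect_pairs += 1
    gt.rows["q1"] = [{"geneCount": _buckets(q1_counts)}]
    gt.tallies["q1_mutect_edge_pairs"] = mutect_pairs

    # q2: (gene, pathway) membership tuples for the q1 genes, in bucket order
    q2_genes = [bkt["key"] for bkt in gt.rows["q1"][0]["geneCount"]]
    gt.inputs["q2_genes"] = q2_genes
    gt.rows["q2"] = [[g, pw] for g in q2_genes for pw in gene_pathways.get(g, [])]

    # q3: per-pathway member-gene counts
    q3_counts = Counter({pw: len(members) for pw, members in pathway_members.items() if members})
    gt.rows["q3"] = [{"pathwayGeneCount": _buckets(q3_counts)}]

    # q4: publication counts over case->allele->association->publication paths
    q4_counts: Counter = Counter()
    if brca:
        for _case, allele, _methods, _gene in tumor_hits(brca):
            for assoc in allele_assocs.get(allele, []):
                for pub in assoc_pubs[assoc]:
                    q4_counts[pub] += 1
    gt.rows["q4"] = [{"pub": _buckets(q4_counts)}]

    # q5: compound counts after distinct (case, compound) pairs
    q5_pairs: list[tuple[str, str]] = []
    pair_seen: set[tuple[str, str]] = set()
    q5_all_paths: Counter = Counter()
    if brca:
        for case_gid, allele, _methods, _gene in tumor_hits(brca):
            for assoc in allele_assocs.get(allele, []):
                for compound in assoc_compounds[assoc]:
                    q5_all_paths[compound] += 1
                    pair = (case_gid, compound)
                    if pair not in pair_seen:
                        pair_seen.add(pair)
                        q5_pairs.append(pair)
    q5_counts = Counter(c for _, c in q5_pairs)
    gt.rows["q5"] = [{"compound": _buckets(q5_counts)}]
    gt.tallies["q5_paths_without_distinct"] = sum(q5_all_paths.values())

    # q6: of the q5 compounds, those screened in the named cell-line project
    q6_compounds = [bkt["key"] for bkt in gt.rows["q5"][0]["compound"]]
    gt.inputs["q6_compounds"] = q6_compounds
    rows6 = []
    for compound in q6_compounds:
        for project_gid in compound_projects.get(compound, []):
            if project_id_of[project_gid] == DEFAULT_PROJECT_ID:
                rows6.append([compound, compound_synonym[compound]])
    gt.rows["q6"] = rows6

    # q7: (sample, submitter id, ec50) for the guaranteed compound, program-wide
    target_compound = compound_gids[0] if compound_gids else None
    gt.inputs["q7_compound"] = target_compound
    rows7 = []
    for project_gid in cellline_projects:
        for case_gid in project_cases[project_gid]:
            sample_gid = case_sample[case_gid]
            for _dr, compound, ec50, _auc, submitter in aliquot_responses.get(
                sample_aliquot[sample_gid], []
            ):
                if compound == target_compound:
                    rows7.append([sample_gid, submitter, ec50])
    gt.rows["q7"] = rows7

    # q8: expression vectors of same_as partners of the q7 samples
    q8_samples = list(dict.fromkeys(r[0] for r in rows7))
    gt.inputs["q8_samples"] = q8_samples
    rows8 = []
    for sample_gid in q8_samples:
        case_gid = f"Case:{sample_gid.split(':', 1)[1]}"
        for partner in case_same_as.get(case_gid, []):
            partner_aliquot = sample_aliquot[case_sample[partner]]
            if partner_aliquot in aliquot_expression:
                rows8.append([sample_gid, aliquot_expression[partner_aliquot]])
    gt.rows["q8"] = rows8

    gt.inputs["q1_project"] = brca
    gt.inputs["q6_project_id"] = DEFAULT_PROJECT_ID
    gt.inputs["q7_program"] = DEFAULT_PROGRAM if cfg.n_programs > 1 else None
    return graph, gt


def write_fixture(config: SyntheticConfig, directory: str | Path) -> None:
    """Write v.jsonl, e.jsonl, groundtruth.json, config.json into a directory.

    Output is byte-deterministic for a fixed config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    graph, gt = generate(config)
    write_graph_jsonl(graph, str(directory / "v.jsonl"), str(directory / "e.jsonl"))
    (directory / "groundtruth.json").write_text(
        json.dumps(gt.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    (directory / "config.json").write_text(
        json.dumps(asdict(config), sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
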