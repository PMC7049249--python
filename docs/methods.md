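# Methods

## The graph model

The store is an in-memory property graph: vertices and edges keyed by a
global identifier string (gid), each carrying a nested JSON-like property
map (scalars, ordered lists, string-keyed maps). Two adjacency indices —
(vertex gid, edge label) → edge list, outgoing and incoming — exactly
mirror the edge table. All iteration orders are insertion order: the vertex
table, the edge table, and every index list. This is a deliberate
over-specification. The traversal semantics only need *some* order, but
fixing it everywhere makes results reproducible byte-for-byte and lets the
differential tests demand exact, order-included equality instead of
multiset equality.

Graphs are built mutably (`add_vertex`/`add_edge`), then `finalize()`
verifies that every edge endpoint resolves before queries run. Duplicate
gids are a hard error rather than last-wins: silently overwriting a vertex
or edge would corrupt the path counts that term aggregations report.
Persistence is JSON Lines, one record per line, written with sorted keys so
the same graph always serializes to the same bytes; a record-level `"type"`
discriminator is accepted on read so single-file dumps also load. Edge
records without a gid get a deterministic synthesized one from their
endpoints, label, and ordinal.

## Query semantics

A query is an ordered step list starting with `V`. Execution folds each
step over an ordered traveler list; a traveler is (current element, mark
map). The choices that were genuinely open, and how they were fixed:

- **Term aggregation** skips null (absent) field values rather than
  bucketing them under a sentinel: an absent annotation is not a term.
  Buckets sort by count descending, key ascending on ties; non-string
  values become JSON-serialized keys.
- **Numeric comparisons** (`gt` etc.) between non-numbers are `false`, not
  errors, keeping predicate evaluation total over heterogeneous real-world
  payloads. Booleans do not count as numbers. A null field satisfies no
  leaf predicate except `neq` (and `eq` against an explicit null literal).
- **`contains`** is list membership only; on a scalar field it is `false`,
  not scalar equality.
- **Marks** snapshot the element reference at `as`-time and are never
  mutated by later traversal; re-marking a name overwrites it; `select`
  replaces the current element but keeps all marks. `distinct` resolves its
  field tuple exactly like `render`, so it can deduplicate on mark/current
  combinations such as (case, compound).
- **`in`/`inE`** are implemented for completeness alongside `out`/`outE`;
  moving from an edge position is an error naming the step.
- A query ending without a terminal step returns element rows
  (gid/label/data) for both vertex- and edge-positioned travelers —
  mirrors exploratory use.
- `"$.field"` and bare `"field"` are treated as exact synonyms for "field
  of the current element"; `"_gid"`/`"_label"` address element identity,
  `"_data"` addresses the property map explicitly, any other leading key
  implicitly.
- `V` with explicit gids silently skips unknown gids (an unknown project
  yields an empty result, not an error); compile-time validation rejects
  undefined mark references, steps after a terminal, misplaced `V`, and
  negative limits.

## The brute-force oracle

`brute_force_execute` re-derives results by naive enumeration: every step
materializes the full path-state list, adjacency is found by scanning the
whole edge table, and field resolution, predicates, distinct (quadratic
`==` membership), and aggregation are re-implemented locally rather than
shared with the engine. It is the independent second route in all
differential tests and is intended for graphs up to a few hundred vertices.

## Schema

The shipped schema (a YAML package resource) declares 20 vertex labels and
the 20 legal (from, edge label, to) triples the cookbook traversals and
generator use, including both membership directions between Gene and
Pathway and the symmetric `Case-same_as-Case` link. Labels for reference
annotation (Exon, Protein, PfamFamily, GeneOntologyTerm) are declared but
not exercised by any query; edge multiplicity is unconstrained — only type
triples are checked. Validation is a separate explicit pass returning
violation records (unknown label, dangling edge, illegal triple, missing
required field) in deterministic order; the shipped schema marks no
required fields beyond gid/label, which the store itself enforces.

## ETL loaders

The loaders accept minimal dialects of MAF (8 mapped columns, names
configurable), GMT, a TSV expression matrix, a drug-response CSV, and JSON
Lines association records. Fixed conventions:

- Coordinates are 1-based inclusive; allele gid =
  `Allele:(chrom):(start):(ref):(alt)`, and alleles are deduplicated on that
  key so the same variant across samples shares one vertex.
- The caller list and gene annotation live on the callset→allele **edge**
  (`methods`, `ensembl_gene`), not on the Allele vertex — the mutation-count
  aggregation reads them after an edge-landing step, and a duplicate copy on
  the vertex would create a second source of truth.
- The drug-response CSV must carry a `project_id` column: Compound→Project
  edges are *derived* (a compound is linked to every project whose samples
  tested it), and the project must therefore be identifiable per row.
- Association records resolve their `allele_key` against the existing
  graph; unmatched records are skipped with a warning rather than failing
  the load, since knowledge bases routinely reference variants absent from
  any given cohort.

## The synthetic cohort

`generate(SyntheticConfig(seed))` emits a miniature integrated resource
from a single seeded RNG, in a fixed construction order so the output is
byte-deterministic. Defaults: 2 programs (one patient-like, one
cell-line-like) × 2 projects × 20 cases, one sample and aliquot per case,
80% tumor fraction; 50 genes, a pool of 60 distinct alleles, 10 pathways of
3–12 genes; 1–15 mutations per tumor case with MUTECT support at
probability 0.7 (other callers at 0.5); 8 compounds, 30 associations, 12
publications, 6 phenotypes; each screened cell line tests 2–5 compounds
with EC50 drawn log-uniform over 10⁻⁵–10⁰ µM; expression is log-normal
(µ=2, σ=1 on the log scale) rounded to 4 decimals, labeled TPM; cell lines
are mirrored across the two screen projects with probability 0.5 via
paired directed `same_as` edges. The distinct-allele pool size and the
per-line compound count are explicit config fields because nothing else
pins them down; 60 alleles over 50 genes gives realistic recurrence (the
same variant hitting multiple cases) at this scale.

Structural choices: mutations attach only to the patient-like program;
drug response only to the first cell-line project and expression only to
the second, mirroring how screening and RNA assays live in complementary
resources and making the cross-project `same_as` hop load-bearing for the
expression query. Gene gids follow the `ENSG`+zero-padded pattern so
aggregation keys look like real annotation. The generator guarantees by
construction that the first compound is both literature-associated with a
mutated allele of the patient cohort and screened in the cell-line project,
so the compound-intersection analysis is non-empty at any seed.

**Ground truth is computed without the engine.** During generation the
module keeps plain side tables (case→alleles, allele→associations,
pathway→members, aliquot→responses, …) and derives the expected rows of all
eight cookbook queries by direct loops over them, applying the same
ordering contract (insertion order, bucket sort). Engine agreement with
this bookkeeping — plus agreement with the brute-force oracle — is the
package's core end-to-end property.

What the generator does *not* emulate: realistic mutation spectra or
genomic coordinates of real genes, clinical covariates, copy number,
multi-sample cases, or missing-data patterns of real consortium files.
Passing tests therefore demonstrate the correctness of the graph/query
machinery and the loaders' contracts, not robustness to the full
messiness of production data.

## Problem sizes and numerical choices

The differential suite runs 220+ seeded random pairs (graphs ≤ 40
vertices / ≤ 120 edges, query depth ≤ 6 over all step types) — small
enough that the quadratic oracle stays instant, large enough that every
step type and collision case is exercised many times; the whole test suite
runs in seconds. All equality checks are exact: the engine is
deterministic, floats are carried verbatim (never re-derived through
arithmetic), and aggregation counts are integers, so no tolerances are
needed anywhere. EC50 values are rounded to 10 decimals and expression to
4 at generation time only to keep serialized fixtures tidy.

## Known limitations

Single-threaded, fully in-memory, no mutation steps, no query optimizer or
cost model, no pagination or server protocol, no on-disk backend. The query
dialect covers the selection/aggregation core demonstrated by the cookbook;
regex predicates and property-level schema typing are out of scope. Term
aggregation materializes the traveler list; graphs are expected to fit
comfortably in memory (≲10⁵ elements).
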