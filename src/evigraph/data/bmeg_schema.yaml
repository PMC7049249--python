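# Cancer-genomics evidence-graph schema: allowed vertex labels and the legal
# (from_label, edge_label, to_label) triples. The cohort tree is
# Program -> Project -> Case -> Sample -> Aliquot; molecular and knowledge-base
# vertices hang off the aliquots and alleles.
vertex_labels:
  - Program
  - Project
  - Case
  - Sample
  - Aliquot
  - SomaticCallset
  - Allele
  - Gene
  - Transcript
  - Exon
  - Protein
  - PfamFamily
  - GeneOntologyTerm
  - Pathway
  - Compound
  - DrugResponse
  - GeneExpression
  - G2PAssociation
  - Publication
  - Phenotype
edge_triples:
  - [Program, projects, Project]
  - [Project, cases, Case]
  - [Case, samples, Sample]
  - [Sample, case, Case]
  - [Case, same_as, Case]
  - [Sample, aliquots, Aliquot]
  - [Aliquot, somatic_callsets, SomaticCallset]
  - [SomaticCallset, alleles, Allele]
  - [Allele, g2p_associations, G2PAssociation]
  - [G2PAssociation, publications, Publication]
  - [G2PAssociation, compounds, Compound]
  - [G2PAssociation, phenotypes, Phenotype]
  - [Gene, pathways, Pathway]
  - [Pathway, genes, Gene]
  - [Compound, projects, Project]
  - [Aliquot, drug_response, DrugResponse]
  - [DrugResponse, compounds, Compound]
  - [Aliquot, gene_expressions, GeneExpression]
  - [Transcript, gene, Gene]
  - [Gene, transcripts, Transcript]
required_fields: {}
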