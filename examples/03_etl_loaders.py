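"""Load standard bioinformatics formats into graph elements.

Each loader converts one source file (MAF-like variants, GMT gene sets,
drug-response CSV) into schema-conformant vertices and edges that can be
merged into one graph and queried.
"""

import tempfile
from pathlib import Path

from evigraph import (
    bmeg_schema,
    load_drug_response,
    load_maf,
    load_pathways_gmt,
    validate_against_schema,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)

    maf = tmp / "toy.maf"
    maf.write_text(
        "Tumor_Sample_Barcode\tHugo_Symbol\tGene\tChromosome\tStart_Position\t"
        "Reference_Allele\tTumor_Seq_Allele2\tCENTERS\n"
        "a1\tTP53\tENSG3\t17\t7578406\tC\tT\tMUTECT|MUSE\n"
        "a2\tTP53\tENSG3\t17\t7578406\tC\tT\tMUTECT\n"
        "a1\tPIK3CA\tENSG7\t3\t178936091\tG\tA\tVARSCAN\n"
    )
    elements = load_maf(str(maf), "Project:P")
    alleles = sum(v.label == "Allele" for v in elements.vertices)
    print(f"MAF: 3 variant rows -> {alleles} distinct Allele vertices "
          f"({sum(e.label == 'alleles' for e in elements.edges)} call edges); "
          "the same variant seen in two samples shares one vertex")

    gmt = tmp / "sets.gmt"
    gmt.write_text("CELL_CYCLE\tsrc\tG1\tG2\tG3\tG4\nAPOPTOSIS\tsrc\tG1\tG5\n")
    elements = load_pathways_gmt(str(gmt))
    print(f"GMT: 2 gene sets -> {sum(v.label == 'Pathway' for v in elements.vertices)} "
          f"Pathway vertices, {sum(e.label == 'genes' for e in elements.edges)} "
          "membership edges each way (G1 belongs to both)")

    csv = tmp / "dr.csv"
    csv.write_text(
        "sample_id,project_id,compound_id,submitter_compound_id,ec50,auc\n"
        "S1,CTRP_Breast_Cancer,CID1,fulvestrant,0.31,0.8\n"
        "S2,CTRP_Breast_Cancer,CID1,fulvestrant,0.02,0.6\n"
    )
    elements = load_drug_response(str(csv))
    print(f"drug response: 2 rows -> "
          f"{sum(v.label == 'DrugResponse' for v in elements.vertices)} DrugResponse, "
          f"{sum(v.label == 'Compound' for v in elements.vertices)} Compound "
          "(deduplicated), plus a derived Compound->Project edge")

    ok = validate_against_schema(elements.to_graph(), bmeg_schema()) == []
    print("loader output schema-conformant:", ok)
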