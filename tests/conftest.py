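import pytest

from evigraph import SyntheticConfig, bmeg_schema, generate
from evigraph.graph import Edge, Graph, Vertex


@pytest.fixture(scope="session")
def schema():
    return bmeg_schema()


@pytest.fixture(scope="session")
def fixture42():
    """The default seed-42 synthetic cohort and its recorded ground truth."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture()
def cohort_graph():
    """A hand-built mini cohort: one project, two tumor + one normal sample,
    each with an aliquot; used for step-semantics examples with hand counts."""
    g = Graph()
    g.add_vertex(Vertex("Project:P1", "Project", {"project_id": "P1"}))
    for i, stype in enumerate(["Primary Tumor", "Primary Tumor", "Blood Derived Normal"], 1):
        g.add_vertex(Vertex(f"Case:C{i}", "Case", {}))
        g.add_vertex(Vertex(f"Sample:S{i}", "Sample", {"gdc_attributes": {"sample_type": stype}}))
        g.add_vertex(Vertex(f"Aliquot:A{i}", "Aliquot", {}))
        g.add_edge(Edge(f"pc{i}", "Project:P1", f"Case:C{i}", "cases"))
        g.add_edge(Edge(f"cs{i}", f"Case:C{i}", f"Sample:S{i}", "samples"))
        g.add_edge(Edge(f"sa{i}", f"Sample:S{i}", f"Aliquot:A{i}", "aliquots"))
    return g.finalize()
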