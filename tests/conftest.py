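import pytest

from wpinteract import (
    FixtureSpec,
    InteractionStore,
    build_interactions,
    generate_fixture,
    load_mappings,
)
from wpinteract.examples import (
    AKT2_MAPPING_TSV,
    akt2_inhibition_pathway,
    enzyme_cascade_pathway,
)


@pytest.fixture
def akt2_doc():
    """The microRNA ⊣ AKT2 worked example: Rna node, GeneProduct node,
    one T-bar edge from the former to the latter."""
    return akt2_inhibition_pathway()


@pytest.fixture
def akt2_index():
    """Equivalence index mapping AKT2's Ensembl, NCBI Gene, and UniProt URIs."""
    return load_mappings(AKT2_MAPPING_TSV)


@pytest.fixture
def akt2_store(akt2_doc, akt2_index):
    return InteractionStore.from_documents([akt2_doc], idmap=akt2_index)


@pytest.fixture
def cascade_doc():
    """E1 catalyzes M1->M2, E2 catalyzes M2->M3, drawn with anchors."""
    return enzyme_cascade_pathway()


@pytest.fixture
def cascade_records(cascade_doc):
    return build_interactions(cascade_doc)


def random_doc(seed, **overrides):
    """A generated pathway exercising the full arrowhead palette, groups,
    anchors, and catalyst edges."""
    defaults = dict(
        n_nodes=8,
        n_edges=6,
        n_groups=1,
        anchor_probability=0.4,
        catalysis_probability=0.8,
        pathway_id=f"WP{8000 + seed % 1000}",
    )
    defaults.update(overrides)
    return generate_fixture(FixtureSpec(**defaults), seed=seed)
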