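"""Edge normalization, interaction building, and cascade inference."""

import pytest

from wpinteract import (
    EntityType,
    InteractionType,
    build_interactions,
    classify_entity,
    infer_enzyme_cascade,
    normalize_arrowhead,
)
from wpinteract.gpml import GpmlDataNode
from wpinteract.semantics import (
    NORMALIZATION_TABLE,
    ROLE_PARTICIPANT,
    ROLE_SOURCE,
    ROLE_TARGET,
)

from conftest import random_doc


@pytest.mark.parametrize(
    "name,expected",
    [
        ("mim-inhibition", InteractionType.INHIBITION),
        ("TBar", InteractionType.INHIBITION),
        ("Inhibition", InteractionType.INHIBITION),  # SBGN notation
        ("mim-stimulation", InteractionType.STIMULATION),
        ("mim-necessary-stimulation", InteractionType.STIMULATION),
        ("mim-catalysis", InteractionType.CATALYSIS),
        ("mim-conversion", InteractionType.CONVERSION),
        ("mim-binding", InteractionType.BINDING),
        ("mim-modification", InteractionType.DIRECTED),
        ("Arrow", InteractionType.DIRECTED),
        ("", InteractionType.UNDIRECTED),
        ("never-heard-of-it", InteractionType.DIRECTED),
    ],
)
def test_normalize_arrowhead_table(name, expected):
    """The MIM, SBGN, and basic drawing notations collapse onto one
    closed type set; all three inhibition drawings become one type."""
    assert normalize_arrowhead(name) is expected


def test_normalization_total_and_idempotent():
    for name in list(NORMALIZATION_TABLE) + ["", "junk-arrow"]:
        t = normalize_arrowhead(name)
        assert isinstance(t, InteractionType)
        # normalizing the already-normalized name is stable
        assert normalize_arrowhead(t.value) in (t, InteractionType.DIRECTED)


def test_inhibition_notations_indistinguishable():
    collapsed = {
        normalize_arrowhead(n) for n in ("mim-inhibition", "TBar", "Inhibition")
    }
    assert collapsed == {InteractionType.INHIBITION}


@pytest.mark.parametrize(
    "node_class,expected",
    [
        ("GeneProduct", EntityType.GENE_PRODUCT),
        ("Metabolite", EntityType.METABOLITE),
        ("Pathway", EntityType.PATHWAY),
        ("Unknown", EntityType.UNKNOWN),
    ],
)
def test_classify_entity(node_class, expected):
    node = GpmlDataNode(graph_id="x", node_class=node_class)
    assert classify_entity(node) is expected


def test_akt2_fixture_yields_single_inhibition(akt2_doc):
    """One Rna source, one GeneProduct target, type Inhibition."""
    records = build_interactions(akt2_doc)
    assert len(records) == 1
    rec = records[0]
    assert rec.interaction_type is InteractionType.INHIBITION
    (src,) = rec.sources()
    (tgt,) = rec.targets()
    assert src.label == "hsa-let-7b" and src.entity_type is EntityType.RNA
    assert tgt.label == "AKT2" and tgt.entity_type is EntityType.GENE_PRODUCT


def test_group_endpoint_expands_to_members():
    """An edge drawn from a 2-node group to a third node yields one
    record with two sources and one target."""
    from wpinteract.gpml import (
        GpmlDataNode,
        GpmlDocument,
        GpmlEdge,
        GpmlGroup,
        GpmlPoint,
        Xref,
    )

    doc = GpmlDocument(pathway_id="WP1")
    for gid, label in [("a", "A"), ("b", "B"), ("c", "C")]:
        doc.nodes[gid] = GpmlDataNode(
            gid, label, "Protein", Xref("UniProt", f"P0000{gid}"),
            group_ref="g1" if gid in "ab" else None,
        )
    doc.groups["g1"] = GpmlGroup("g1", frozenset({"a", "b"}))
    doc.edges["e1"] = GpmlEdge(
        "e1",
        points=(
            GpmlPoint(graph_ref="g1"),
            GpmlPoint(graph_ref="c", arrowhead="Arrow"),
        ),
    )
    (rec,) = build_interactions(doc)
    assert rec.interaction_type is InteractionType.DIRECTED
    assert {p.label for p in rec.sources()} == {"A", "B"}
    assert {p.label for p in rec.targets()} == {"C"}


def test_empty_document_yields_no_records():
    from wpinteract.gpml import GpmlDocument

    assert build_interactions(GpmlDocument(pathway_id="WP0")) == []


def test_undirected_edge_has_only_participants(akt2_doc):
    from dataclasses import replace

    edge = akt2_doc.edges["e1"]
    akt2_doc.edges["e1"] = replace(
        edge,
        points=(edge.points[0], replace(edge.points[1], arrowhead="")),
    )
    (rec,) = build_interactions(akt2_doc)
    assert rec.interaction_type is InteractionType.UNDIRECTED
    assert all(p.role == ROLE_PARTICIPANT for p in rec.participants)
    assert len(rec.participants) == 2


def test_reversed_drawing_flips_direction(akt2_doc):
    """An arrowhead on the first point means the edge was drawn backwards."""
    from dataclasses import replace

    edge = akt2_doc.edges["e1"]
    akt2_doc.edges["e1"] = replace(
        edge,
        points=(
            replace(edge.points[0], arrowhead="TBar"),
            replace(edge.points[1], arrowhead=""),
        ),
    )
    (rec,) = build_interactions(akt2_doc)
    (src,) = rec.sources()
    assert src.label == "AKT2"


def test_directed_records_always_have_source_and_target():
    for seed in range(20):
        for rec in build_interactions(random_doc(seed)):
            if rec.interaction_type is InteractionType.UNDIRECTED:
                assert len(rec.participants) >= 2
                assert not rec.sources() and not rec.targets()
            else:
                assert rec.sources() and rec.targets()


def test_record_count_bounded_by_edge_count():
    for seed in range(20):
        doc = random_doc(seed)
        assert len(build_interactions(doc)) <= len(doc.edges)


def test_catalysis_targets_are_reaction_participants(cascade_records):
    cats = [
        r
        for r in cascade_records
        if r.interaction_type is InteractionType.CATALYSIS
    ]
    assert len(cats) == 2
    by_enzyme = {r.sources()[0].label: r for r in cats}
    assert {p.label for p in by_enzyme["E1"].targets()} == {"M1", "M2"}
    assert {p.label for p in by_enzyme["E2"].targets()} == {"M2", "M3"}
    assert all(r.conversion_uri for r in cats)


# --- cascade inference vs brute-force oracle -------------------------------


def brute_force_cascade(doc):
    """Independent enumeration of expected derived links, straight from
    the drawing: find every catalyst edge (mim-catalysis head landing on
    an anchor), read its conversion's substrate/product node refs, and
    enumerate all pairs."""
    def node_uris(ref):
        from wpinteract.idmap import identifiers_org_uri

        refs = []
        if ref in doc.nodes:
            refs = [doc.nodes[ref]]
        elif ref in doc.groups:
            refs = [doc.nodes[m] for m in sorted(doc.groups[ref].member_ids)]
        out = set()
        for n in refs:
            uri = identifiers_org_uri(n.xref.datasource, n.xref.identifier)
            out.add(
                uri
                or f"https://identifiers.org/wikipathways/{doc.pathway_id}"
                f"/DataNode/{n.graph_id}"
            )
        return out

    catalyses = []  # (enzyme uris, substrate uris, product uris)
    for edge in doc.edges.values():
        if len(edge.points) < 2:
            continue
        last = edge.points[-1]
        if last.arrowhead != "mim-catalysis":
            continue
        anchor = doc.find_anchor(last.graph_ref or "")
        if anchor is None:
            continue
        conv = doc.edges[anchor.owner_edge]
        if conv.points[-1].arrowhead != "mim-conversion":
            continue
        enzymes = node_uris(edge.points[0].graph_ref)
        substrates = node_uris(conv.points[0].graph_ref)
        products = node_uris(conv.points[-1].graph_ref)
        if enzymes and substrates and products:
            catalyses.append((enzymes, substrates, products))

    expected = set()
    for enzymes, _, products in catalyses:
        expected.add((frozenset(enzymes), frozenset(products)))
    for i, (e1, _, p1) in enumerate(catalyses):
        for j, (e2, s2, _) in enumerate(catalyses):
            if i != j and p1 & s2:
                expected.add((frozenset(e1), frozenset(e2)))
    return expected


def derived_pairs(records):
    return {
        (
            frozenset(p.entity_uri for p in r.sources()),
            frozenset(p.entity_uri for p in r.targets()),
        )
        for r in records
    }


def test_cascade_chain_example(cascade_doc, cascade_records):
    """E1: M1->M2 and E2: M2->M3 yield exactly E1->M2, E2->M3, E1->E2."""
    derived = infer_enzyme_cascade(cascade_records)
    labels = {
        (
            frozenset(p.label for p in r.sources()),
            frozenset(p.label for p in r.targets()),
        )
        for r in derived
    }
    assert labels == {
        (frozenset({"E1"}), frozenset({"M2"})),
        (frozenset({"E2"}), frozenset({"M3"})),
        (frozenset({"E1"}), frozenset({"E2"})),
    }
    assert all(r.derived for r in derived)
    assert derived_pairs(derived) == brute_force_cascade(cascade_doc)


def test_cascade_no_shared_metabolite():
    """Two catalyzed conversions with disjoint chemistry: the two
    enzyme->product records appear but no enzyme->enzyme link."""
    from wpinteract.examples import enzyme_cascade_pathway
    from wpinteract.gpml import Xref
    from dataclasses import replace

    doc = enzyme_cascade_pathway()
    # decouple the chain: second conversion starts from a fresh metabolite
    doc.nodes["m4"] = replace(
        doc.nodes["m2"], graph_id="m4", label="M4",
        xref=Xref("HMDB", "HMDB0009999"),
    )
    edge = doc.edges["c2"]
    doc.edges["c2"] = replace(
        edge, points=(replace(edge.points[0], graph_ref="m4"), edge.points[1])
    )
    records = build_interactions(doc)
    derived = infer_enzyme_cascade(records)
    labels = {
        (
            frozenset(p.label for p in r.sources()),
            frozenset(p.label for p in r.targets()),
        )
        for r in derived
    }
    assert labels == {
        (frozenset({"E1"}), frozenset({"M2"})),
        (frozenset({"E2"}), frozenset({"M3"})),
    }
    assert derived_pairs(derived) == brute_force_cascade(doc)


def test_uncatalyzed_conversion_derives_nothing():
    from wpinteract.examples import enzyme_cascade_pathway

    doc = enzyme_cascade_pathway()
    del doc.edges["k1"], doc.edges["k2"]  # conversions remain, no catalysts
    assert infer_enzyme_cascade(build_interactions(doc)) == []


def test_cascade_matches_oracle_on_generated_documents():
    """Agreement with brute-force pair enumeration on random drawings."""
    for seed in range(30):
        doc = random_doc(
            seed,
            n_edges=8,
            anchor_probability=0.7,
            catalysis_probability=1.0,
            arrowheads=("mim-conversion", "Arrow", ""),
        )
        records = build_interactions(doc)
        derived = infer_enzyme_cascade(records)
        assert derived_pairs(derived) == brute_force_cascade(doc)


def test_cascade_monotone_under_unrelated_edge(cascade_doc):
    """Adding an unrelated edge never removes a derived record."""
    from wpinteract.gpml import GpmlDataNode, GpmlEdge, GpmlPoint, Xref

    before = derived_pairs(
        infer_enzyme_cascade(build_interactions(cascade_doc))
    )
    cascade_doc.nodes["x1"] = GpmlDataNode(
        "x1", "X1", "Protein", Xref("UniProt", "Q99999")
    )
    cascade_doc.edges["extra"] = GpmlEdge(
        "extra",
        points=(
            GpmlPoint(graph_ref="x1"),
            GpmlPoint(graph_ref="enz1", arrowhead="Arrow"),
        ),
    )
    after = derived_pairs(
        infer_enzyme_cascade(build_interactions(cascade_doc))
    )
    assert before <= after


def test_cascade_inputs_unchanged(cascade_records):
    snapshot = list(cascade_records)
    infer_enzyme_cascade(cascade_records)
    assert cascade_records == snapshot
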