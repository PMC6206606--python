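"""Small hand-built example pathways.

These are synthetic documents constructed in code (no downloads): a
microRNA inhibiting a kinase gene — the classic hsa-let-7b ⊣ AKT2
regulation drawn with a T-bar — and a two-step enzymatic cascade drawn
with anchors and mim-catalysis arrows.  They double as documentation
and as compact inputs for tests and the worked examples.
"""

from __future__ import annotations

from .gpml import (
    GpmlAnchor,
    GpmlDataNode,
    GpmlDocument,
    GpmlEdge,
    GpmlPoint,
    Xref,
)

#: identifiers used by the AKT2 example, equivalent across three schemes
AKT2_ENSEMBL = "https://identifiers.org/ensembl/ENSG00000105221"
AKT2_NCBIGENE = "https://identifiers.org/ncbigene/208"
AKT2_UNIPROT = "https://identifiers.org/uniprot/P31751"
LET7B_URI = "https://identifiers.org/mirbase/MI0000063"

AKT2_MAPPING_TSV = "\t".join([AKT2_ENSEMBL, AKT2_NCBIGENE, AKT2_UNIPROT])


def akt2_inhibition_pathway() -> GpmlDocument:
    """A microRNA silencing a kinase: hsa-let-7b ⊣ AKT2 (T-bar edge).

    The let-7b RNA is the source, the AKT2 gene product the target, and
    the T-bar arrowhead normalizes to an inhibition.
    """
    doc = GpmlDocument(
        pathway_id="WP1544",
        title="MicroRNAs in cardiomyocyte hypertrophy",
        organism="Homo sapiens",
    )
    doc.nodes["n1"] = GpmlDataNode(
        graph_id="n1",
        label="hsa-let-7b",
        node_class="Rna",
        xref=Xref("miRBase Sequence", "MI0000063"),
    )
    doc.nodes["n2"] = GpmlDataNode(
        graph_id="n2",
        label="AKT2",
        node_class="GeneProduct",
        xref=Xref("Ensembl", "ENSG00000105221"),
    )
    doc.edges["e1"] = GpmlEdge(
        graph_id="e1",
        points=(
            GpmlPoint(graph_ref="n1", x=0.0, y=0.0),
            GpmlPoint(graph_ref="n2", arrowhead="TBar", x=0.0, y=100.0),
        ),
    )
    return doc


def enzyme_cascade_pathway() -> GpmlDocument:
    """A two-step enzymatic chain: E1 catalyzes M1 -> M2, E2 catalyzes
    M2 -> M3, drawn the WikiPathways way — conversion edges between the
    metabolites, each with an anchor that the enzyme's mim-catalysis
    arrow attaches to.  No single drawn line connects E1 to E2; the
    cascade query has to infer that link.
    """
    doc = GpmlDocument(
        pathway_id="WP9100",
        title="Two-step enzymatic cascade",
        organism="Homo sapiens",
    )
    for gid, label, cls, xref in [
        ("m1", "M1", "Metabolite", Xref("HMDB", "HMDB0000122")),
        ("m2", "M2", "Metabolite", Xref("HMDB", "HMDB0000516")),
        ("m3", "M3", "Metabolite", Xref("HMDB", "HMDB0000660")),
        ("enz1", "E1", "Protein", Xref("UniProt", "P06744")),
        ("enz2", "E2", "Protein", Xref("UniProt", "P60174")),
    ]:
        doc.nodes[gid] = GpmlDataNode(gid, label, cls, xref)
    doc.edges["c1"] = GpmlEdge(
        graph_id="c1",
        points=(
            GpmlPoint(graph_ref="m1", x=0.0, y=0.0),
            GpmlPoint(graph_ref="m2", arrowhead="mim-conversion", x=100.0, y=0.0),
        ),
        anchors=(GpmlAnchor("anchor1", "c1", 0.5),),
    )
    doc.edges["c2"] = GpmlEdge(
        graph_id="c2",
        points=(
            GpmlPoint(graph_ref="m2", x=100.0, y=0.0),
            GpmlPoint(graph_ref="m3", arrowhead="mim-conversion", x=200.0, y=0.0),
        ),
        anchors=(GpmlAnchor("anchor2", "c2", 0.5),),
    )
    doc.edges["k1"] = GpmlEdge(
        graph_id="k1",
        points=(
            GpmlPoint(graph_ref="enz1", x=50.0, y=50.0),
            GpmlPoint(graph_ref="anchor1", arrowhead="mim-catalysis", x=50.0, y=0.0),
        ),
    )
    doc.edges["k2"] = GpmlEdge(
        graph_id="k2",
        points=(
            GpmlPoint(graph_ref="enz2", x=150.0, y=50.0),
            GpmlPoint(graph_ref="anchor2", arrowhead="mim-catalysis", x=150.0, y=0.0),
        ),
    )
    return doc
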