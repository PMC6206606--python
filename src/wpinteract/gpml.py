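"""Reading, writing, and synthesizing GPML pathway documents.

GPML (Graphical Pathway Markup Language) is the native XML dialect of
WikiPathways: a pathway is a drawing whose DataNodes stand for genes,
gene products, RNAs, metabolites, or nested pathways, and whose edges
(Interaction elements) connect them, optionally decorated with MIM or
SBGN arrowheads that carry biological meaning.  This module is the only
place that knows the XML dialect; everything downstream works on the
:class:`GpmlDocument` object model.

The target dialect is GPML2013a.  Documents in a different GPML
namespace still parse (with a warning), since the elements used here are
stable across dialects.  Coordinates and other graphics are carried
through for round-tripping but have no semantic weight, with the single
exception of anchor positions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace

from lxml import etree

logger = logging.getLogger(__name__)

GPML_2013A_NS = "http://pathvisio.org/GPML/2013a"

NODE_CLASSES = ("GeneProduct", "Protein", "Rna", "Metabolite", "Pathway", "Unknown")

#: Comment @Source under which the WikiPathways accession is stored.
_WPID_COMMENT_SOURCE = "WikiPathways-id"


class GpmlParseError(ValueError):
    """Raised for XML that cannot be read as GPML (line/column included)."""


class GpmlValidationError(ValueError):
    """Raised when a document violates its structural invariants."""


@dataclass(frozen=True)
class Xref:
    """A cross-reference: datasource name plus opaque accession."""

    datasource: str = ""
    identifier: str = ""

    def __bool__(self) -> bool:
        return bool(self.datasource and self.identifier)


@dataclass(frozen=True)
class GpmlDataNode:
    graph_id: str
    label: str = ""
    node_class: str = "Unknown"
    xref: Xref = Xref()
    group_ref: str | None = None


@dataclass(frozen=True)
class GpmlPoint:
    """One endpoint (or waypoint) of an edge.

    ``graph_ref`` may name a DataNode, an anchor on another edge, or a
    group; ``arrowhead`` is the drawn head at this point ("" = none).
    """

    graph_ref: str | None = None
    arrowhead: str = ""
    x: float = 0.0
    y: float = 0.0


@dataclass(frozen=True)
class GpmlAnchor:
    """A point on an edge that other edges may attach to (e.g. the spot
    where a catalyst's arrow meets a conversion reaction)."""

    anchor_id: str
    owner_edge: str
    position: float = 0.5


@dataclass(frozen=True)
class GpmlEdge:
    graph_id: str
    points: tuple[GpmlPoint, ...] = ()
    anchors: tuple[GpmlAnchor, ...] = ()


@dataclass(frozen=True)
class GpmlGroup:
    """A drawn group (complex); membership mirrors the GroupRef
    attributes of the member DataNodes."""

    group_id: str
    member_ids: frozenset[str] = frozenset()


@dataclass
class GpmlDocument:
    pathway_id: str = ""
    title: str = ""
    organism: str = ""
    nodes: dict[str, GpmlDataNode] = field(default_factory=dict)
    edges: dict[str, GpmlEdge] = field(default_factory=dict)
    groups: dict[str, GpmlGroup] = field(default_factory=dict)
    #: structured warnings (dangling references etc.); not part of equality
    warnings: list[str] = field(default_factory=list, compare=False)

    def referencable_ids(self) -> set[str]:
        ids = set(self.nodes) | set(self.groups)
        for edge in self.edges.values():
            ids.update(a.anchor_id for a in edge.anchors)
        return ids

    def find_anchor(self, anchor_id: str) -> GpmlAnchor | None:
        for edge in self.edges.values():
            for anchor in edge.anchors:
                if anchor.anchor_id == anchor_id:
                    return anchor
        return None


def validate(doc: GpmlDocument) -> list[str]:
    """Hard invariant violations (duplicate ids, degenerate edges,
    self-containing groups).  Dangling references are warnings, not
    errors, and are reported on ``doc.warnings`` at parse time instead."""
    errors: list[str] = []
    seen: set[str] = set()
    for gid in list(_all_ids(doc)):
        if gid in seen:
            errors.append(f"duplicate graph id {gid!r}")
        seen.add(gid)
    for edge in doc.edges.values():
        if len(edge.points) < 2:
            errors.append(f"edge {edge.graph_id!r} has fewer than 2 points")
        for anchor in edge.anchors:
            if not 0.0 <= anchor.position <= 1.0:
                errors.append(
                    f"anchor {anchor.anchor_id!r} position outside [0, 1]"
                )
            if anchor.owner_edge != edge.graph_id:
                errors.append(
                    f"anchor {anchor.anchor_id!r} owner mismatch"
                )
    for group in doc.groups.values():
        if group.group_id in group.member_ids:
            errors.append(f"group {group.group_id!r} contains itself")
    return errors


def _all_ids(doc: GpmlDocument):
    yield from doc.nodes
    yield from doc.edges
    yield from doc.groups
    for edge in doc.edges.values():
        for anchor in edge.anchors:
            yield anchor.anchor_id


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def parse_gpml(xml_text: str | bytes) -> GpmlDocument:
    """Parse GPML XML into a :class:`GpmlDocument`.

    Malformed XML raises :class:`GpmlParseError` naming line and column.
    Dangling graph references (edge points naming an id that does not
    exist — decorative lines are common in community-drawn pathways)
    are kept and recorded in ``doc.warnings`` rather than failing.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise GpmlParseError(f"malformed XML: {exc}") from exc

    ns = etree.QName(root).namespace or GPML_2013A_NS
    if etree.QName(root).localname != "Pathway":
        raise GpmlParseError(
            f"root element is {etree.QName(root).localname!r}, expected 'Pathway'"
        )
    doc = GpmlDocument(
        title=root.get("Name", ""),
        organism=root.get("Organism", ""),
    )
    if ns != GPML_2013A_NS:
        doc.warnings.append(f"non-2013a GPML namespace {ns!r}; parsing anyway")
        logger.warning("gpml: %s", doc.warnings[-1])

    for comment in root.findall(_q(ns, "Comment")):
        if comment.get("Source") == _WPID_COMMENT_SOURCE:
            doc.pathway_id = (comment.text or "").strip()

    group_members: dict[str, set[str]] = {}
    for el in root.findall(_q(ns, "DataNode")):
        xref_el = el.find(_q(ns, "Xref"))
        xref = Xref(
            datasource=xref_el.get("Database", "") if xref_el is not None else "",
            identifier=xref_el.get("ID", "") if xref_el is not None else "",
        )
        node_class = el.get("Type", "Unknown")
        if node_class not in NODE_CLASSES:
            doc.warnings.append(
                f"DataNode {el.get('GraphId')!r}: unknown class {node_class!r},"
                " treated as Unknown"
            )
            node_class = "Unknown"
        node = GpmlDataNode(
            graph_id=el.get("GraphId", ""),
            label=el.get("TextLabel", ""),
            node_class=node_class,
            xref=xref,
            group_ref=el.get("GroupRef"),
        )
        if not node.graph_id:
            doc.warnings.append("DataNode without GraphId skipped")
            continue
        if node.graph_id in doc.nodes:
            raise GpmlParseError(f"duplicate GraphId {node.graph_id!r}")
        doc.nodes[node.graph_id] = node
        if node.group_ref:
            group_members.setdefault(node.group_ref, set()).add(node.graph_id)

    for el in root.findall(_q(ns, "Interaction")):
        gid = el.get("GraphId", "")
        graphics = el.find(_q(ns, "Graphics"))
        points: list[GpmlPoint] = []
        anchors: list[GpmlAnchor] = []
        if graphics is not None:
            for pt in graphics.findall(_q(ns, "Point")):
                points.append(
                    GpmlPoint(
                        graph_ref=pt.get("GraphRef"),
                        arrowhead=pt.get("ArrowHead", ""),
                        x=float(pt.get("X", "0")),
                        y=float(pt.get("Y", "0")),
                    )
                )
            for an in graphics.findall(_q(ns, "Anchor")):
                anchors.append(
                    GpmlAnchor(
                        anchor_id=an.get("GraphId", ""),
                        owner_edge=gid,
                        position=float(an.get("Position", "0.5")),
                    )
                )
        if not gid:
            doc.warnings.append("Interaction without GraphId skipped")
            continue
        doc.edges[gid] = GpmlEdge(
            graph_id=gid, points=tuple(points), anchors=tuple(anchors)
        )

    for el in root.findall(_q(ns, "Group")):
        group_id = el.get("GroupId", "")
        if not group_id:
            doc.warnings.append("Group without GroupId skipped")
            continue
        doc.groups[group_id] = GpmlGroup(
            group_id=group_id,
            member_ids=frozenset(group_members.get(group_id, set())),
        )
    for group_id, members in group_members.items():
        if group_id not in doc.groups:
            doc.warnings.append(
                f"GroupRef {group_id!r} on nodes {sorted(members)} has no Group"
            )

    known = doc.referencable_ids()
    for edge in doc.edges.values():
        for point in edge.points:
            if point.graph_ref is not None and point.graph_ref not in known:
                doc.warnings.append(
                    f"edge {edge.graph_id!r}: dangling reference"
                    f" {point.graph_ref!r}"
                )
    for w in doc.warnings:
        logger.debug("gpml warning: %s", w)
    return doc


def write_gpml(doc: GpmlDocument) -> str:
    """Serialize a document to GPML2013a XML.

    ``parse_gpml(write_gpml(doc))`` reproduces the document field by
    field.  Invariant violations raise :class:`GpmlValidationError`
    listing the offending ids.
    """
    errors = validate(doc)
    if errors:
        raise GpmlValidationError("; ".join(errors))

    nsmap = {None: GPML_2013A_NS}
    root = etree.Element(_q(GPML_2013A_NS, "Pathway"), nsmap=nsmap)
    root.set("Name", doc.title)
    if doc.organism:
        root.set("Organism", doc.organism)
    if doc.pathway_id:
        comment = etree.SubElement(root, _q(GPML_2013A_NS, "Comment"))
        comment.set("Source", _WPID_COMMENT_SOURCE)
        comment.text = doc.pathway_id

    for node in doc.nodes.values():
        el = etree.SubElement(root, _q(GPML_2013A_NS, "DataNode"))
        el.set("TextLabel", node.label)
        el.set("GraphId", node.graph_id)
        el.set("Type", node.node_class)
        if node.group_ref:
            el.set("GroupRef", node.group_ref)
        xref_el = etree.SubElement(el, _q(GPML_2013A_NS, "Xref"))
        xref_el.set("Database", node.xref.datasource)
        xref_el.set("ID", node.xref.identifier)

    for edge in doc.edges.values():
        el = etree.SubElement(root, _q(GPML_2013A_NS, "Interaction"))
        el.set("GraphId", edge.graph_id)
        graphics = etree.SubElement(el, _q(GPML_2013A_NS, "Graphics"))
        for point in edge.points:
            pt = etree.SubElement(graphics, _q(GPML_2013A_NS, "Point"))
            pt.set("X", repr(point.x))
            pt.set("Y", repr(point.y))
            if point.graph_ref is not None:
                pt.set("GraphRef", point.graph_ref)
            if point.arrowhead:
                pt.set("ArrowHead", point.arrowhead)
        for anchor in edge.anchors:
            an = etree.SubElement(graphics, _q(GPML_2013A_NS, "Anchor"))
            an.set("Position", repr(anchor.position))
            an.set("GraphId", anchor.anchor_id)

    for group in doc.groups.values():
        el = etree.SubElement(root, _q(GPML_2013A_NS, "Group"))
        el.set("GroupId", group.group_id)

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="utf-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# Fixture generation

_ARROWHEAD_PALETTE = (
    "Arrow",
    "TBar",
    "mim-inhibition",
    "mim-stimulation",
    "mim-conversion",
    "mim-binding",
    "",  # no arrowhead: undirected edge
)

_DATASOURCE_PALETTE = (
    ("Ensembl", "ENSG{:011d}"),
    ("Entrez Gene", "{}"),
    ("UniProt", "P{:05d}"),
    ("HMDB", "HMDB{:07d}"),
    ("ChEBI", "CHEBI:{}"),
    ("ChemSpider", "{}"),
)

_NODE_CLASS_WEIGHTS = (
    ("GeneProduct", 4),
    ("Protein", 3),
    ("Metabolite", 3),
    ("Rna", 1),
    ("Pathway", 1),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for synthetic GPML generation.

    Defaults describe a small human pathway sketch: a handful of nodes
    of mixed biological classes, mostly-directed edges drawn from the
    full MIM/SBGN/basic arrowhead palette, no groups, no anchors.
    """

    n_nodes: int = 8
    n_edges: int = 6
    n_groups: int = 0
    arrowheads: tuple[str, ...] = _ARROWHEAD_PALETTE
    anchor_probability: float = 0.0
    catalysis_probability: float = 0.0
    group_edge_probability: float = 0.5
    organism: str = "Homo sapiens"
    pathway_id: str = "WP9001"
    title: str = "Synthetic test pathway"


def generate_fixture(spec: FixtureSpec, seed: int) -> GpmlDocument:
    """Deterministically synthesize a GPML document from a spec and seed.

    Every edge endpoint resolves to a node, group, or anchor; xrefs are
    drawn from the standard datasource palette with unique accessions.
    With ``anchor_probability`` each edge gains an anchor; anchored
    conversion edges additionally attract a catalyst edge (a node
    connected to the anchor with a mim-catalysis arrowhead) with
    ``catalysis_probability`` — the drawing idiom for enzymatic
    reactions.  Catalyst edges are extra, on top of ``n_edges``.

    Raises ValueError for infeasible specs (edges with <2 nodes, more
    groups than node pairs).
    """
    if spec.n_edges > 0 and spec.n_nodes < 2:
        raise ValueError("edges require at least 2 nodes")
    if spec.n_groups > spec.n_nodes // 2:
        raise ValueError("each group needs at least 2 member nodes")

    rng = random.Random(seed)
    doc = GpmlDocument(
        pathway_id=spec.pathway_id, title=spec.title, organism=spec.organism
    )

    classes = [c for c, w in _NODE_CLASS_WEIGHTS for _ in range(w)]
    for i in range(spec.n_nodes):
        datasource, pattern = _DATASOURCE_PALETTE[
            rng.randrange(len(_DATASOURCE_PALETTE))
        ]
        node = GpmlDataNode(
            graph_id=f"n{i}",
            label=f"NODE{i}",
            node_class=rng.choice(classes),
            xref=Xref(datasource, pattern.format(10000 + i)),
        )
        doc.nodes[node.graph_id] = node

    # groups claim disjoint pairs of the first 2*n_groups nodes
    for gi in range(spec.n_groups):
        members = {f"n{2 * gi}", f"n{2 * gi + 1}"}
        group = GpmlGroup(group_id=f"g{gi}", member_ids=frozenset(members))
        doc.groups[group.group_id] = group
        for m in members:
            doc.nodes[m] = replace(doc.nodes[m], group_ref=group.group_id)

    def pick_endpoint(exclude: str | None) -> str:
        pool: list[str] = list(doc.nodes)
        if doc.groups and rng.random() < spec.group_edge_probability:
            pool = list(doc.groups)
        candidates = [c for c in pool if c != exclude]
        if not candidates:
            candidates = [c for c in doc.nodes if c != exclude]
        return rng.choice(candidates)

    catalyst_edges: list[GpmlEdge] = []
    for ei in range(spec.n_edges):
        src = pick_endpoint(exclude=None)
        tgt = pick_endpoint(exclude=src)
        arrowhead = rng.choice(spec.arrowheads)
        anchors: tuple[GpmlAnchor, ...] = ()
        gid = f"e{ei}"
        if rng.random() < spec.anchor_probability:
            anchors = (
                GpmlAnchor(
                    anchor_id=f"a{ei}",
                    owner_edge=gid,
                    position=round(rng.uniform(0.2, 0.8), 3),
                ),
            )
        doc.edges[gid] = GpmlEdge(
            graph_id=gid,
            points=(
                GpmlPoint(graph_ref=src, x=float(ei), y=0.0),
                GpmlPoint(
                    graph_ref=tgt, arrowhead=arrowhead, x=float(ei), y=100.0
                ),
            ),
            anchors=anchors,
        )
        if (
            anchors
            and arrowhead == "mim-conversion"
            and rng.random() < spec.catalysis_probability
        ):
            enzyme = rng.choice(list(doc.nodes))
            catalyst_edges.append(
                GpmlEdge(
                    graph_id=f"cat{ei}",
                    points=(
                        GpmlPoint(graph_ref=enzyme, x=float(ei), y=50.0),
                        GpmlPoint(
                            graph_ref=anchors[0].anchor_id,
                            arrowhead="mim-catalysis",
                            x=float(ei),
                            y=50.0,
                        ),
                    ),
                )
            )
    for edge in catalyst_edges:
        doc.edges[edge.graph_id] = edge
    return doc
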