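"""WikiPathways-style RDF: serialization and loading of interactions.

The RDF export keeps two controlled vocabularies deliberately apart: a
graphical one (``gpml:``) describing the drawing — DataNodes, lines,
groups — and a biological one (``wp:``) describing what the drawing
means — gene products, metabolites, inhibitions, catalyses.  The split
lets the biological layer integrate with other pathway resources
regardless of drawing notation.  Each biological resource is linked to
its graphical counterpart by a single ``wp:isAbout`` cross-link; apart
from that, no statement mixes the two namespaces.

Entity URIs are identifiers.org-formatted from the drawn
cross-references.  Interaction URIs are minted as
``<pathway>/Interaction/<edge id>`` so they are stable and diffable.

:func:`write_turtle` is deterministic — equal triple sets produce
byte-identical Turtle — which makes exports diffable across runs.
"""

from __future__ import annotations

import logging

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS, RDF, RDFS
from rdflib.plugins.parsers.notation3 import BadSyntax

from .gpml import GpmlDocument
from .idmap import EMPTY_INDEX, UriEquivalenceIndex
from .semantics import (
    EntityType,
    InteractionRecord,
    InteractionType,
    Participant,
    ROLE_PARTICIPANT,
    ROLE_SOURCE,
    ROLE_TARGET,
    entity_uri_for,
    pathway_uri_for,
)

logger = logging.getLogger(__name__)

WP = Namespace("https://vocabularies.wikipathways.org/wp#")
GPML = Namespace("https://vocabularies.wikipathways.org/gpml#")

#: extra type marking cascade-inferred interactions
_INFERRED = WP["InferredInteraction"]
#: catalysis record -> the conversion interaction it acts on
_CATALYZED_CONVERSION = WP["catalyzedConversion"]

_PREFIXES = {
    "wp": WP,
    "gpml": GPML,
    "dcterms": DCTERMS,
    "rdf": RDF,
    "rdfs": RDFS,
}


class RdfConsistencyError(ValueError):
    """A record references an entity that the document cannot supply."""


class RdfParseError(ValueError):
    """Turtle that does not parse; message carries the line number."""


def _bind(graph: Graph) -> Graph:
    for prefix, ns in _PREFIXES.items():
        graph.bind(prefix, ns, replace=True)
    return graph


def to_rdf(
    doc: GpmlDocument,
    records: list[InteractionRecord],
    idmap: UriEquivalenceIndex = EMPTY_INDEX,
) -> Graph:
    """Serialize a document and its interaction records to RDF.

    Emits the graphical layer (one ``gpml:``-typed resource per DataNode,
    edge, and group), the biological layer (one ``wp:``-typed resource
    per entity and per interaction, with ``wp:source``/``wp:target`` on
    directed records and ``wp:participants`` on all), and the pathway
    resource itself.  Raises :class:`RdfConsistencyError` if a record
    names an entity that no document node maps to.
    """
    g = _bind(Graph())
    pw = URIRef(pathway_uri_for(doc.pathway_id))
    g.add((pw, RDF.type, WP.Pathway))
    g.add((pw, DCTERMS.identifier, Literal(doc.pathway_id)))
    g.add((pw, DCTERMS.title, Literal(doc.title, lang="en")))
    if doc.organism:
        g.add((pw, WP.organismName, Literal(doc.organism)))

    # graphical layer
    entity_to_graphical: dict[str, URIRef] = {}
    for node in doc.nodes.values():
        g_uri = URIRef(f"{pw}/gpml/DataNode/{node.graph_id}")
        g.add((g_uri, RDF.type, GPML.DataNode))
        g.add((g_uri, RDFS.label, Literal(node.label)))
        g.add((g_uri, DCTERMS.isPartOf, pw))
        euri = entity_uri_for(node, str(pw), idmap)
        # first graph id in sorted order wins when several nodes share an xref
        if euri not in entity_to_graphical or str(g_uri) < str(
            entity_to_graphical[euri]
        ):
            entity_to_graphical[euri] = g_uri
    for edge in doc.edges.values():
        e_uri = URIRef(f"{pw}/gpml/Interaction/{edge.graph_id}")
        g.add((e_uri, RDF.type, GPML.Interaction))
        g.add((e_uri, DCTERMS.isPartOf, pw))
    for group in doc.groups.values():
        grp_uri = URIRef(f"{pw}/gpml/Group/{group.group_id}")
        g.add((grp_uri, RDF.type, GPML.Group))
        g.add((grp_uri, DCTERMS.isPartOf, pw))

    # biological layer
    seen_entities: set[str] = set()
    for record in records:
        i_uri = URIRef(record.interaction_uri)
        g.add((i_uri, RDF.type, WP.Interaction))
        g.add((i_uri, RDF.type, WP[record.interaction_type.value]))
        g.add((i_uri, DCTERMS.isPartOf, URIRef(record.pathway_uri)))
        if record.derived:
            g.add((i_uri, RDF.type, _INFERRED))
        if record.conversion_uri:
            g.add((i_uri, _CATALYZED_CONVERSION, URIRef(record.conversion_uri)))
        edge_id = record.interaction_uri.rsplit("/", 1)[-1]
        if not record.derived and edge_id in doc.edges:
            g.add((i_uri, WP.isAbout, URIRef(f"{pw}/gpml/Interaction/{edge_id}")))
        for p in record.participants:
            e_uri = URIRef(p.entity_uri)
            g.add((i_uri, WP.participants, e_uri))
            if p.role == ROLE_SOURCE:
                g.add((i_uri, WP.source, e_uri))
            elif p.role == ROLE_TARGET:
                g.add((i_uri, WP.target, e_uri))
            if p.entity_uri not in seen_entities:
                if (
                    not p.entity_uri.startswith(str(pw) + "/DataNode/")
                    and p.entity_uri not in entity_to_graphical
                ):
                    raise RdfConsistencyError(
                        f"record {record.interaction_uri} references entity"
                        f" {p.entity_uri} absent from the document"
                    )
                seen_entities.add(p.entity_uri)
                g.add((e_uri, RDF.type, WP.DataNode))
                if p.entity_type is not EntityType.UNKNOWN:
                    g.add((e_uri, RDF.type, WP[p.entity_type.value]))
                g.add((e_uri, RDFS.label, Literal(p.label)))
                g.add((e_uri, DCTERMS.isPartOf, URIRef(record.pathway_uri)))
                graphical = entity_to_graphical.get(p.entity_uri)
                if graphical is not None:
                    g.add((e_uri, WP.isAbout, graphical))
    return g


def write_turtle(graph: Graph) -> str:
    """Deterministic Turtle: a sorted prefix block, then one line per
    triple, sorted by (subject, predicate, object) in N3 form."""
    nm = _bind(Graph()).namespace_manager
    lines = sorted(
        f"{s.n3(nm)} {p.n3(nm)} {o.n3(nm)} ." for s, p, o in graph
    )
    prefix_block = [
        f"@prefix {prefix}: <{ns}> ."
        for prefix, ns in sorted(_PREFIXES.items())
    ]
    return "\n".join(prefix_block + [""] + lines) + "\n"


def write_ntriples(graph: Graph) -> str:
    """Line-oriented N-Triples export, sorted for diffability."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )
    return "\n".join(lines) + ("\n" if lines else "")


def parse_turtle(text: str) -> Graph:
    """Parse Turtle into a graph; bad syntax raises
    :class:`RdfParseError` carrying the line number."""
    g = _bind(Graph())
    try:
        g.parse(data=text, format="turtle")
    except BadSyntax as exc:
        raise RdfParseError(f"turtle syntax error: {exc}") from exc
    return g


def graphs_equal(a: Graph, b: Graph) -> bool:
    """Triple-set equality (the graphs here are ground: no blank nodes)."""
    return set(a) == set(b)


def rdf_to_records(graph: Graph) -> list[InteractionRecord]:
    """Reconstruct interaction records from the biological layer.

    Inverse of :func:`to_rdf` on that layer: records fed through
    ``to_rdf`` then ``rdf_to_records`` come back equal (order aside).
    Interactions without participants are flagged and skipped.
    """
    type_values = {t.value for t in InteractionType}
    entity_values = {t.value for t in EntityType}

    def entity_info(uri: URIRef) -> tuple[str, EntityType]:
        labels = sorted(str(o) for o in graph.objects(uri, RDFS.label))
        etype = EntityType.UNKNOWN
        for o in graph.objects(uri, RDF.type):
            local = str(o)
            if local.startswith(str(WP)):
                name = local[len(str(WP)):]
                if name in entity_values and name != "Unknown":
                    etype = EntityType(name)
        return (labels[0] if labels else "", etype)

    records = []
    for subj in sorted(set(graph.subjects(RDF.type, WP.Interaction))):
        itype = None
        derived = False
        for o in graph.objects(subj, RDF.type):
            if o == _INFERRED:
                derived = True
                continue
            if str(o).startswith(str(WP)):
                name = str(o)[len(str(WP)):]
                if name in type_values:
                    itype = InteractionType(name)
        if itype is None:
            logger.warning("interaction %s has no recognized type; skipped", subj)
            continue
        sources = set(graph.objects(subj, WP.source))
        targets = set(graph.objects(subj, WP.target))
        everyone = set(graph.objects(subj, WP.participants))
        if not everyone:
            logger.warning("interaction %s has no participants; skipped", subj)
            continue
        participants = []
        for e in everyone:
            label, etype = entity_info(e)
            roles = []
            if e in sources:
                roles.append(ROLE_SOURCE)
            if e in targets:
                roles.append(ROLE_TARGET)
            if not roles:
                roles.append(ROLE_PARTICIPANT)
            for role in roles:
                participants.append(
                    Participant(str(e), label, etype, role)
                )
        pathways = sorted(str(o) for o in graph.objects(subj, DCTERMS.isPartOf))
        conversion = sorted(
            str(o) for o in graph.objects(subj, _CATALYZED_CONVERSION)
        )
        records.append(
            InteractionRecord(
                interaction_uri=str(subj),
                pathway_uri=pathways[0] if pathways else "",
                interaction_type=itype,
                participants=tuple(
                    sorted(participants, key=Participant.sort_key)
                ),
                derived=derived,
                conversion_uri=conversion[0] if conversion else None,
            )
        )
    return records
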