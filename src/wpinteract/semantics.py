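"""Normalization of drawn edges into typed biological interactions.

A pathway drawing encodes biology in its arrowheads: a T-bar or a
mim-inhibition head means inhibition, mim-catalysis marks an enzyme
acting on a reaction, a bare arrow says only "directed, source to
target".  MIM and SBGN draw the same biology differently, so the first
job here is to collapse both notations (plus the basic drawing tools)
onto one closed set of interaction types.  The second job is structural:
expand groups into multi-participant interactions, resolve edges that
end on another edge's anchor (the enzyme-catalysis drawing idiom), and
orient each interaction as sources acting on targets.

Cascade inference (:func:`infer_enzyme_cascade`) derives the implicit
links of enzymatic chains — enzyme to product, and enzyme to enzyme
where one reaction's product is the next one's substrate.  Derived
records are flagged and kept apart from drawn ones.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from enum import Enum

from .gpml import GpmlDataNode, GpmlDocument, GpmlEdge
from .idmap import EMPTY_INDEX, UriEquivalenceIndex, identifiers_org_uri

logger = logging.getLogger(__name__)


class InteractionType(str, Enum):
    """Closed set of normalized interaction types (WikiPathways ontology)."""

    INHIBITION = "Inhibition"
    STIMULATION = "Stimulation"
    CATALYSIS = "Catalysis"
    CONVERSION = "Conversion"
    BINDING = "Binding"
    DIRECTED = "DirectedInteraction"
    UNDIRECTED = "UndirectedInteraction"
    COMPLEX_BINDING = "ComplexBinding"


class EntityType(str, Enum):
    GENE_PRODUCT = "GeneProduct"
    PROTEIN = "Protein"
    RNA = "Rna"
    METABOLITE = "Metabolite"
    PATHWAY = "Pathway"
    COMPLEX = "Complex"
    UNKNOWN = "Unknown"


#: Arrowhead name -> interaction type.  MIM, SBGN, and the basic drawing
#: tools all feed the same table; the three inhibition notations
#: (mim-inhibition, T-bar, SBGN Inhibition) collapse onto one type.
NORMALIZATION_TABLE: dict[str, InteractionType] = {
    "mim-inhibition": InteractionType.INHIBITION,
    "TBar": InteractionType.INHIBITION,
    "Inhibition": InteractionType.INHIBITION,  # SBGN arc
    "mim-stimulation": InteractionType.STIMULATION,
    "Stimulation": InteractionType.STIMULATION,  # SBGN arc
    "mim-necessary-stimulation": InteractionType.STIMULATION,
    "mim-catalysis": InteractionType.CATALYSIS,
    "Catalysis": InteractionType.CATALYSIS,  # SBGN arc
    "mim-conversion": InteractionType.CONVERSION,
    "mim-binding": InteractionType.BINDING,
    "mim-modification": InteractionType.DIRECTED,
    "Arrow": InteractionType.DIRECTED,
}


def normalize_arrowhead(name: str) -> InteractionType:
    """Map an arrowhead name to its interaction type (total function).

    The empty string — no arrowhead on either end — means the edge is
    undirected.  Unrecognized non-empty arrowheads degrade to the
    generic directed interaction, with a logged notice.
    """
    if not name:
        return InteractionType.UNDIRECTED
    try:
        return NORMALIZATION_TABLE[name]
    except KeyError:
        logger.info(
            "unrecognized arrowhead %r treated as DirectedInteraction", name
        )
        return InteractionType.DIRECTED


def classify_entity(node: GpmlDataNode) -> EntityType:
    """Map a DataNode's drawn class onto its biological entity type."""
    try:
        return EntityType(node.node_class)
    except ValueError:
        return EntityType.UNKNOWN


ROLE_SOURCE = "source"
ROLE_TARGET = "target"
ROLE_PARTICIPANT = "participant"

_ROLE_ORDER = {ROLE_SOURCE: 0, ROLE_TARGET: 1, ROLE_PARTICIPANT: 2}


@dataclass(frozen=True)
class Participant:
    """One entity taking part in an interaction, with its role."""

    entity_uri: str
    label: str = ""
    entity_type: EntityType = EntityType.UNKNOWN
    role: str = ROLE_PARTICIPANT

    def sort_key(self) -> tuple:
        return (_ROLE_ORDER[self.role], self.entity_uri, self.label)


@dataclass(frozen=True)
class InteractionRecord:
    """One normalized biological interaction.

    Directed types carry at least one source and one target; undirected
    interactions carry only role=participant entries.  ``derived`` marks
    records produced by cascade inference rather than drawn edges.  For
    catalysis records, ``conversion_uri`` points at the interaction
    record of the catalyzed conversion, which is what cascade inference
    chains on.
    """

    interaction_uri: str
    pathway_uri: str
    interaction_type: InteractionType
    participants: tuple[Participant, ...]
    derived: bool = False
    conversion_uri: str | None = None

    def with_sorted_participants(self) -> "InteractionRecord":
        ordered = tuple(sorted(self.participants, key=Participant.sort_key))
        if ordered == self.participants:
            return self
        return InteractionRecord(
            self.interaction_uri,
            self.pathway_uri,
            self.interaction_type,
            ordered,
            self.derived,
            self.conversion_uri,
        )

    def sources(self) -> tuple[Participant, ...]:
        return tuple(p for p in self.participants if p.role == ROLE_SOURCE)

    def targets(self) -> tuple[Participant, ...]:
        return tuple(p for p in self.participants if p.role == ROLE_TARGET)

    def involves(self, uri: str) -> bool:
        return any(p.entity_uri == uri for p in self.participants)


def pathway_uri_for(pathway_id: str) -> str:
    return f"https://identifiers.org/wikipathways/{pathway_id}"


def entity_uri_for(
    node: GpmlDataNode, pathway_uri: str, idmap: UriEquivalenceIndex
) -> str:
    """Canonical URI of a node: identifiers.org from its xref when
    present (run through the equivalence index), a pathway-local URI
    otherwise."""
    uri = identifiers_org_uri(node.xref.datasource, node.xref.identifier)
    if uri is None:
        return f"{pathway_uri}/DataNode/{node.graph_id}"
    return idmap.canonicalize(uri)


def _participant(
    node: GpmlDataNode, role: str, pathway_uri: str, idmap: UriEquivalenceIndex
) -> Participant:
    return Participant(
        entity_uri=entity_uri_for(node, pathway_uri, idmap),
        label=node.label,
        entity_type=classify_entity(node),
        role=role,
    )


def build_interactions(
    doc: GpmlDocument, idmap: UriEquivalenceIndex = EMPTY_INDEX
) -> list[InteractionRecord]:
    """Turn every semantic edge of a document into an interaction record.

    The first endpoint's entities become sources and the last endpoint's
    become targets (drawing order; if only the first point carries the
    arrowhead the edge was drawn backwards and is flipped).  A group
    endpoint expands to all group members with that endpoint's role.  An
    edge ending on another edge's anchor attaches to that reaction: a
    mim-catalysis head there yields a Catalysis record whose targets are
    the substrate and product of the anchored conversion.  Edges with no
    resolvable biological node at a required end are dropped with a
    notice; identifier-mapping misses are not errors — the raw
    identifiers.org URI is kept.
    """
    pw_uri = pathway_uri_for(doc.pathway_id)
    records: list[InteractionRecord] = []

    def resolve_nodes(ref: str | None) -> tuple[list[GpmlDataNode], str | None]:
        """Nodes behind a point reference, plus the owner edge id when
        the reference is an anchor (nodes then come from both ends of
        the anchored edge)."""
        if ref is None:
            return [], None
        if ref in doc.nodes:
            return [doc.nodes[ref]], None
        if ref in doc.groups:
            members = [
                doc.nodes[m]
                for m in sorted(doc.groups[ref].member_ids)
                if m in doc.nodes
            ]
            return members, None
        anchor = doc.find_anchor(ref)
        if anchor is not None:
            owner = doc.edges[anchor.owner_edge]
            nodes: list[GpmlDataNode] = []
            for endpoint in (owner.points[0], owner.points[-1]):
                got, _ = resolve_nodes(endpoint.graph_ref)
                nodes.extend(got)
            return nodes, owner.graph_id
        return [], None

    for edge in doc.edges.values():
        if len(edge.points) < 2:
            logger.info("edge %r has no endpoints; skipped", edge.graph_id)
            continue
        first, last = edge.points[0], edge.points[-1]
        if last.arrowhead or not first.arrowhead:
            src_pt, tgt_pt, arrowhead = first, last, last.arrowhead
        else:  # arrowhead drawn on the first point: edge runs backwards
            src_pt, tgt_pt, arrowhead = last, first, first.arrowhead

        itype = normalize_arrowhead(arrowhead)
        src_nodes, _ = resolve_nodes(src_pt.graph_ref)
        tgt_nodes, anchored_edge = resolve_nodes(tgt_pt.graph_ref)
        group_involved = (
            src_pt.graph_ref in doc.groups or tgt_pt.graph_ref in doc.groups
        )
        if itype is InteractionType.BINDING and group_involved:
            itype = InteractionType.COMPLEX_BINDING

        uri = f"{pw_uri}/Interaction/{edge.graph_id}"
        conversion_uri = (
            f"{pw_uri}/Interaction/{anchored_edge}"
            if anchored_edge is not None and itype is InteractionType.CATALYSIS
            else None
        )

        if itype is InteractionType.UNDIRECTED:
            participants = tuple(
                sorted(
                    {
                        _participant(n, ROLE_PARTICIPANT, pw_uri, idmap)
                        for n in src_nodes + tgt_nodes
                    },
                    key=Participant.sort_key,
                )
            )
            if len(participants) < 2:
                logger.info(
                    "undirected edge %r has <2 resolvable participants; dropped",
                    edge.graph_id,
                )
                continue
            records.append(
                InteractionRecord(uri, pw_uri, itype, participants)
            )
            continue

        if not src_nodes or not tgt_nodes:
            logger.info(
                "edge %r lacks a resolvable source or target; dropped",
                edge.graph_id,
            )
            continue
        participants = tuple(
            sorted(
                {_participant(n, ROLE_SOURCE, pw_uri, idmap) for n in src_nodes}
                | {_participant(n, ROLE_TARGET, pw_uri, idmap) for n in tgt_nodes},
                key=Participant.sort_key,
            )
        )
        records.append(
            InteractionRecord(
                uri, pw_uri, itype, participants, conversion_uri=conversion_uri
            )
        )
    return records


def _derived_uri(pathway_uri: str, sources, targets) -> str:
    key = "|".join(sorted(p.entity_uri for p in sources))
    key += "||" + "|".join(sorted(p.entity_uri for p in targets))
    digest = hashlib.sha1(key.encode("utf-8")).hexdigest()[:12]
    return f"{pathway_uri}/Interaction/derived-{digest}"


def infer_enzyme_cascade(
    records: list[InteractionRecord],
    idmap: UriEquivalenceIndex = EMPTY_INDEX,
) -> list[InteractionRecord]:
    """Derive the implicit directed links of enzymatic cascades.

    From each catalysis record and its conversion M1 -> M2: the enzyme
    is upstream of the product (enzyme -> M2).  From each pair of
    catalyses whose conversions share chemistry — a product of one is a
    substrate of the other under identifier equivalence — the first
    enzyme is upstream of the second (enzyme1 -> enzyme2).  Derived
    records are flagged ``derived=True``, typed as generic directed
    interactions, deduplicated on (sources, targets), and returned
    without modifying the input.
    """
    conversions = {
        r.interaction_uri: r
        for r in records
        if r.interaction_type is InteractionType.CONVERSION
    }
    catalyses = [
        r
        for r in records
        if r.interaction_type is InteractionType.CATALYSIS
        and r.conversion_uri in conversions
    ]

    def canon(p: Participant) -> str:
        return idmap.canonicalize(p.entity_uri)

    derived: dict[tuple, InteractionRecord] = {}

    def emit(pw_uri: str, sources, targets) -> None:
        if not sources or not targets:
            return
        participants = tuple(
            sorted(
                {
                    Participant(p.entity_uri, p.label, p.entity_type, ROLE_SOURCE)
                    for p in sources
                }
                | {
                    Participant(p.entity_uri, p.label, p.entity_type, ROLE_TARGET)
                    for p in targets
                },
                key=Participant.sort_key,
            )
        )
        record = InteractionRecord(
            interaction_uri=_derived_uri(pw_uri, sources, targets),
            pathway_uri=pw_uri,
            interaction_type=InteractionType.DIRECTED,
            participants=participants,
            derived=True,
        )
        key = (
            pw_uri,
            frozenset(p.entity_uri for p in sources),
            frozenset(p.entity_uri for p in targets),
        )
        derived.setdefault(key, record)

    for cat in catalyses:
        conv = conversions[cat.conversion_uri]
        emit(cat.pathway_uri, cat.sources(), conv.targets())

    for cat1 in catalyses:
        conv1 = conversions[cat1.conversion_uri]
        products1 = {canon(p) for p in conv1.targets()}
        for cat2 in catalyses:
            if cat1.interaction_uri == cat2.interaction_uri:
                continue
            if cat1.pathway_uri != cat2.pathway_uri:
                continue
            conv2 = conversions[cat2.conversion_uri]
            substrates2 = {canon(p) for p in conv2.sources()}
            if products1 & substrates2:
                emit(cat1.pathway_uri, cat1.sources(), cat2.sources())

    return sorted(derived.values(), key=lambda r: r.interaction_uri)
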