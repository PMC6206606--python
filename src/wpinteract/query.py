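"""Interaction queries: by pathway, by entity (with direction), counts.

Three operations mirror the platform calls they re-implement locally:
all interactions of a pathway; the interactions adjacent to an entity,
optionally restricted to upstream (entity is a target — something acts
on it) or downstream (entity is a source — it acts on something); and a
count helper that always equals the length of the corresponding list
call.  Entities may be named through any URI scheme covered by the
loaded equivalence index; results are invariant under substituting an
equivalent URI.

Undirected interactions carry no direction, so they appear only when no
direction filter is applied (``both``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum

from .gpml import GpmlDocument
from .idmap import EMPTY_INDEX, UriEquivalenceIndex
from .semantics import (
    InteractionRecord,
    InteractionType,
    ROLE_SOURCE,
    ROLE_TARGET,
    build_interactions,
    infer_enzyme_cascade,
    pathway_uri_for,
)

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    BOTH = "both"


def _as_direction(value) -> Direction:
    if isinstance(value, Direction):
        return value
    try:
        return Direction(str(value).lower())
    except ValueError:
        valid = ", ".join(d.value for d in Direction)
        raise ValueError(
            f"invalid direction {value!r}; valid values: {valid}"
        ) from None


def _as_type(value) -> InteractionType | None:
    if value is None or isinstance(value, InteractionType):
        return value
    try:
        return InteractionType(str(value))
    except ValueError:
        valid = ", ".join(t.value for t in InteractionType)
        raise ValueError(
            f"invalid interaction type {value!r}; valid values: {valid}"
        ) from None


@dataclass(frozen=True)
class PathwayInfo:
    uri: str
    pathway_id: str = ""
    title: str = ""
    organism: str = ""


@dataclass
class InteractionStore:
    """Loaded interaction records plus per-pathway metadata."""

    records: list[InteractionRecord] = field(default_factory=list)
    pathways: dict[str, PathwayInfo] = field(default_factory=dict)

    @classmethod
    def from_documents(
        cls,
        docs,
        idmap: UriEquivalenceIndex = EMPTY_INDEX,
        cascade: bool = False,
    ) -> "InteractionStore":
        """Build a store from parsed GPML documents.  With ``cascade``
        the inferred enzyme-cascade records are added alongside the
        drawn ones."""
        store = cls()
        for doc in docs:
            uri = pathway_uri_for(doc.pathway_id)
            store.pathways[uri] = PathwayInfo(
                uri=uri,
                pathway_id=doc.pathway_id,
                title=doc.title,
                organism=doc.organism,
            )
            records = build_interactions(doc, idmap)
            store.records.extend(records)
            if cascade:
                store.records.extend(infer_enzyme_cascade(records, idmap))
        return store

    @classmethod
    def from_turtle(cls, text: str) -> "InteractionStore":
        """Build a store from WikiPathways-style Turtle."""
        from rdflib.namespace import DCTERMS, RDF

        from .wprdf import WP, parse_turtle, rdf_to_records

        graph = parse_turtle(text)
        store = cls()
        for pw in graph.subjects(RDF.type, WP.Pathway):
            ids = sorted(str(o) for o in graph.objects(pw, DCTERMS.identifier))
            titles = sorted(str(o) for o in graph.objects(pw, DCTERMS.title))
            organisms = sorted(
                str(o) for o in graph.objects(pw, WP.organismName)
            )
            store.pathways[str(pw)] = PathwayInfo(
                uri=str(pw),
                pathway_id=ids[0] if ids else "",
                title=titles[0] if titles else "",
                organism=organisms[0] if organisms else "",
            )
        store.records.extend(rdf_to_records(graph))
        return store


@dataclass
class QueryResult:
    """JSON-shaped query answer: matched items, their count, the echoed
    query parameters, and a status distinguishing e.g. unknown pathways
    from genuinely empty results."""

    items: list[InteractionRecord]
    echo: dict
    status: str = "ok"

    @property
    def count(self) -> int:
        return len(self.items)


def _sorted_items(records) -> list[InteractionRecord]:
    return sorted(records, key=lambda r: (r.pathway_uri, r.interaction_uri))


def get_interactions(store: InteractionStore, pathway_uri: str) -> QueryResult:
    """All interactions of one pathway, with direction and participants.

    Unknown pathway URIs yield an empty result with status
    ``"unknown-pathway"`` rather than an error.
    """
    echo = {"pathway_uri": pathway_uri}
    if pathway_uri not in store.pathways:
        return QueryResult(items=[], echo=echo, status="unknown-pathway")
    items = _sorted_items(
        r for r in store.records if r.pathway_uri == pathway_uri
    )
    return QueryResult(items=items, echo=echo)


def _matches_entity(record: InteractionRecord, uris: frozenset[str],
                    direction: Direction) -> bool:
    member = {p.entity_uri for p in record.participants} & uris
    if not member:
        return False
    if direction is Direction.BOTH:
        return True
    if record.interaction_type is InteractionType.UNDIRECTED:
        return False
    role = ROLE_SOURCE if direction is Direction.DOWNSTREAM else ROLE_TARGET
    return any(
        p.entity_uri in uris and p.role == role for p in record.participants
    )


def interactions_by_entity(
    store: InteractionStore,
    entity_uri: str,
    direction: Direction | str = Direction.BOTH,
    type_filter: InteractionType | str | None = None,
    organism: str | None = None,
    idmap: UriEquivalenceIndex = EMPTY_INDEX,
) -> QueryResult:
    """Interactions adjacent to an entity, under any equivalent URI.

    ``downstream`` keeps records where the entity acts as a source,
    ``upstream`` where it is a target; ``both`` keeps any adjacency
    including undirected interactions.  ``type_filter`` and ``organism``
    (case-insensitive exact match on the pathway organism) intersect
    further.
    """
    direction = _as_direction(direction)
    type_filter = _as_type(type_filter)
    # equivalents of the query URI, plus their canonical forms, since
    # stored participant URIs are canonicalized at load time
    eqs = set(idmap.equivalents(entity_uri))
    eqs.add(idmap.canonicalize(entity_uri))
    uris = frozenset(eqs)
    echo = {
        "entity_uri": entity_uri,
        "direction": direction.value,
        "type": type_filter.value if type_filter else None,
        "organism": organism,
    }
    items = []
    for record in store.records:
        if not _matches_entity(record, uris, direction):
            continue
        if type_filter is not None and record.interaction_type is not type_filter:
            continue
        if organism is not None:
            info = store.pathways.get(record.pathway_uri)
            if info is None or info.organism.lower() != organism.lower():
                continue
        items.append(record)
    return QueryResult(items=_sorted_items(items), echo=echo)


def interactions_by_entity_count(
    store: InteractionStore,
    entity_uri: str,
    direction: Direction | str = Direction.BOTH,
    type_filter: InteractionType | str | None = None,
    organism: str | None = None,
    idmap: UriEquivalenceIndex = EMPTY_INDEX,
) -> int:
    """Number of interactions the entity participates in; always equal
    to the length of :func:`interactions_by_entity` under the same
    filters."""
    return interactions_by_entity(
        store, entity_uri, direction, type_filter, organism, idmap
    ).count


def record_to_dict(record: InteractionRecord) -> dict:
    return {
        "interaction_uri": record.interaction_uri,
        "pathway_uri": record.pathway_uri,
        "type": record.interaction_type.value,
        "derived": record.derived,
        "participants": [
            {
                "uri": p.entity_uri,
                "label": p.label,
                "entity_type": p.entity_type.value,
                "role": p.role,
            }
            for p in record.participants
        ],
    }


def to_json(result: QueryResult) -> str:
    """Serialize a result to JSON with a fixed, deterministic key order
    (items, count, status, echo; see README for the schema)."""
    payload = {
        "items": [record_to_dict(r) for r in result.items],
        "count": result.count,
        "status": result.status,
        "echo": result.echo,
    }
    return json.dumps(payload, indent=2, sort_keys=False)
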