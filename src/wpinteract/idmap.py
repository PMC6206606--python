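"""Identifier equivalence mapping across URI schemes.

Biological entities are named by many registries at once: a gene may be
referred to through Ensembl, NCBI Gene (Entrez), or — as a protein —
UniProt; a metabolite through HMDB, ChEBI, CAS, or PubChem.  Queries
should return the same answer no matter which scheme the caller uses.
This module loads a plain-text table of equivalent URIs and builds a
partition of the URI space into identity classes, mimicking the role of
an identifier mapping service with purely local data.

The table format is tab-separated text: one equivalence class per line,
each field a URI (scheme-less ``identifiers.org/...`` shorthand is
accepted).  Lines sharing any URI are merged transitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

IDENTIFIERS_ORG = "https://identifiers.org/"

#: GPML datasource name -> identifiers.org collection prefix.
DATASOURCE_PREFIXES: dict[str, str] = {
    "Ensembl": "ensembl",
    "Entrez Gene": "ncbigene",
    "NCBI Gene": "ncbigene",
    "UniProt": "uniprot",
    "UniProtKB": "uniprot",
    "HMDB": "hmdb",
    "ChEBI": "chebi",
    "ChemSpider": "chemspider",
    "PubChem-compound": "pubchem.compound",
    "CAS": "cas",
    "KEGG Compound": "kegg.compound",
    "miRBase Sequence": "mirbase",
    "miRBase mature sequence": "mirbase.mature",
    "Wikidata": "wikidata",
    "WikiPathways": "wikipathways",
}

#: Known non-identifiers.org URL patterns, rewritten to identifiers.org
#: so that raw registry URLs hit the same equivalence class.
_SCHEME_TRANSLATION: tuple[tuple[str, str], ...] = (
    ("http://identifiers.org/", IDENTIFIERS_ORG),
    ("http://www.ensembl.org/id/", IDENTIFIERS_ORG + "ensembl/"),
    ("https://www.ensembl.org/id/", IDENTIFIERS_ORG + "ensembl/"),
    ("http://purl.uniprot.org/uniprot/", IDENTIFIERS_ORG + "uniprot/"),
    ("https://purl.uniprot.org/uniprot/", IDENTIFIERS_ORG + "uniprot/"),
    ("https://www.ncbi.nlm.nih.gov/gene/", IDENTIFIERS_ORG + "ncbigene/"),
    ("http://www.ncbi.nlm.nih.gov/gene/", IDENTIFIERS_ORG + "ncbigene/"),
)


def identifiers_org_uri(datasource: str, identifier: str) -> str | None:
    """Format an (datasource, accession) cross-reference as an
    identifiers.org URI, or None when either part is missing.

    Unknown datasources fall back to a slug of the datasource name so
    the pair still yields a stable, resolvable-looking URI.
    """
    if not datasource or not identifier:
        return None
    prefix = DATASOURCE_PREFIXES.get(datasource)
    if prefix is None:
        prefix = datasource.lower().replace(" ", ".")
    return f"{IDENTIFIERS_ORG}{prefix}/{identifier}"


def normalize_uri(uri: str) -> str:
    """Bring a URI into the canonical form used for lookups.

    identifiers.org URIs are forced to https and scheme-less shorthand
    (``identifiers.org/ensembl/ENSG...``) gains a scheme; a handful of
    well-known registry URL patterns are rewritten onto identifiers.org.
    Anything else passes through untouched.
    """
    uri = uri.strip()
    if uri.startswith("identifiers.org/"):
        uri = IDENTIFIERS_ORG + uri[len("identifiers.org/"):]
    for src, dst in _SCHEME_TRANSLATION:
        if uri.startswith(src):
            return dst + uri[len(src):]
    return uri


def _valid_uri(uri: str) -> bool:
    return "://" in uri and " " not in uri and len(uri.split("://", 1)[1]) > 0


def _canonical_key(uri: str) -> tuple[int, str]:
    # identifiers.org URIs outrank other schemes; ties break lexicographically
    return (0 if uri.startswith(IDENTIFIERS_ORG) else 1, uri)


@dataclass
class UriEquivalenceIndex:
    """Partition of entity URIs into identity classes.

    Unknown URIs are implicit singletons, so lookups are total.  The
    canonical representative of a class is its lexicographically least
    identifiers.org member (least member overall if none).
    """

    _class_of: dict[str, frozenset[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list, compare=False)

    def equivalents(self, uri: str) -> frozenset[str]:
        """All URIs equivalent to *uri*, including itself."""
        uri = normalize_uri(uri)
        return self._class_of.get(uri, frozenset({uri}))

    def canonicalize(self, uri: str) -> str:
        """Deterministic representative; equal for all members of a class."""
        return min(self.equivalents(uri), key=_canonical_key)

    def __len__(self) -> int:
        return len(self._class_of)


#: Shared empty index: every URI is its own singleton class.
EMPTY_INDEX = UriEquivalenceIndex()


def load_mappings(table_text: str) -> UriEquivalenceIndex:
    """Build an equivalence index from tab-separated mapping text.

    Each line lists the URIs of one entity; lines sharing any URI are
    merged (transitive closure).  Lines containing a malformed URI are
    rejected whole, with a warning recorded on the returned index.
    """
    parent: dict[str, str] = {}

    def find(u: str) -> str:
        root = u
        while parent[root] != root:
            root = parent[root]
        while parent[u] != root:  # path compression
            parent[u], u = root, parent[u]
        return root

    def union(u: str, v: str) -> None:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru

    warnings: list[str] = []
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        uris = [normalize_uri(tok) for tok in line.split("\t") if tok.strip()]
        bad = [u for u in uris if not _valid_uri(u)]
        if bad:
            msg = f"line {lineno}: malformed URI(s) {bad!r}; line rejected"
            warnings.append(msg)
            logger.warning("idmap: %s", msg)
            continue
        for u in uris:
            parent.setdefault(u, u)
        for u in uris[1:]:
            union(uris[0], u)

    members: dict[str, set[str]] = {}
    for u in parent:
        members.setdefault(find(u), set()).add(u)
    class_of = {
        u: frozenset(cls) for cls in members.values() for u in cls
    }
    return UriEquivalenceIndex(class_of, warnings)


def equivalents(index: UriEquivalenceIndex, uri: str) -> frozenset[str]:
    """Functional wrapper around :meth:`UriEquivalenceIndex.equivalents`."""
    return index.equivalents(uri)


def canonicalize(index: UriEquivalenceIndex, uri: str) -> str:
    """Functional wrapper around :meth:`UriEquivalenceIndex.canonicalize`."""
    return index.canonicalize(uri)
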