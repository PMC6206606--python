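# Methods

## The problem

A pathway drawing encodes a directed biological network implicitly.
DataNodes carry a biological class (GeneProduct, Protein, Rna,
Metabolite, Pathway) and a cross-reference into a registry (Ensembl,
Entrez/NCBI Gene, UniProt, HMDB, ChEBI, ChemSpider, ...).  Edges carry
their meaning in arrowheads drawn from three conventions at once: MIM
(`mim-inhibition`, `mim-stimulation`, `mim-catalysis`,
`mim-conversion`, `mim-binding`, ...), SBGN arc names (used by
Reactome-derived pathways, e.g. `Inhibition`), and the basic drawing
tools (`Arrow`, `TBar`, or no head at all).  This package normalizes
the drawing into typed interaction records and answers adjacency
queries over them.

## Normalization model

Arrowhead normalization is a total table lookup onto a closed type set:

| drawn | type |
|---|---|
| `mim-inhibition`, `TBar`, SBGN `Inhibition` | Inhibition |
| `mim-stimulation`, SBGN `Stimulation`, `mim-necessary-stimulation` | Stimulation |
| `mim-catalysis`, SBGN `Catalysis` | Catalysis |
| `mim-conversion` | Conversion |
| `mim-binding` | Binding (ComplexBinding when a group participates) |
| `Arrow`, `mim-modification`, any unrecognized head | DirectedInteraction |
| no head on either end | UndirectedInteraction |

Unrecognized arrowheads degrade to the generic directed type with a
logged notice rather than failing: community-drawn content contains
heads outside any published palette.  `mim-necessary-stimulation` is
read as a stimulation and `mim-modification` as a generic directed
interaction; both are close judgment calls on notations whose semantics
sit between the named types, and both are logged.

Direction follows drawing order: the first endpoint's entities are
sources, the last endpoint's are targets.  If the only arrowhead sits
on the *first* point the edge was drawn backwards and is flipped.  A
group endpoint expands to all group members with that endpoint's role,
which is how one record acquires multiple sources or targets.  Directed
records always have ≥1 source and ≥1 target; edges that cannot supply
both are dropped with a notice (never silently).  Undirected edges
yield records whose participants all carry the neutral `participant`
role; a direction filter therefore never returns them.

### Catalysis and the anchor idiom

An enzyme is drawn as a line from the enzyme node to an *anchor* — a
fractional position on the conversion edge — ending in a
`mim-catalysis` head.  Such an edge becomes a Catalysis record whose
sources are the enzyme(s) and whose targets are the substrate and
product of the anchored conversion (the record is flattened; the
alternative of pointing at the conversion as a reified target was
considered and rejected to keep query results flat).  The record keeps
a `conversion_uri` reference to the conversion record, which is what
cascade inference chains on, and which the RDF layer serializes so the
information survives a round trip.

### Cascade inference

Enzymatic cascades have no single drawn line between consecutive
enzymes.  `infer_enzyme_cascade` derives, for each catalysis of a
conversion M1 → M2: enzyme → M2 (the enzyme is upstream of its
product); and for each ordered pair of catalyses where a product of the
first conversion is a substrate of the second (under identifier
equivalence): enzyme₁ → enzyme₂.  Derived records are typed as generic
directed interactions, flagged `derived=True`, deduplicated on
(pathway, source set, target set), and minted stable URIs from a hash
of their participant sets.  Inference is off by default and enabled
explicitly (`cascade=True`, `--cascade`): derived links are a
query-layer enrichment, not drawn content, and consumers must be able
to distinguish the two.  The composition rule is a reconstruction of
how such cascade queries are posed over this data model, verified in
the tests against exhaustive enumeration of catalysis pairs.

## RDF layer

Two namespaces are kept strictly apart:
`https://vocabularies.wikipathways.org/wp#` for biology (entities typed
by their biological class, interactions typed `wp:Interaction` plus
their specific type, `wp:source` / `wp:target` on directed records,
`wp:participants` on all) and `.../gpml#` for the drawing (DataNodes,
lines, groups, labels).  The single bridge is a `wp:isAbout` cross-link
from each biological resource to its graphical counterpart.  Two
book-keeping terms extend the biological namespace:
`wp:InferredInteraction` (an extra type marking derived records) and
`wp:catalyzedConversion` (catalysis → conversion link); both exist so
that records ↔ RDF is lossless.

Entity URIs are identifiers.org-formatted from the node's
cross-reference via a bundled datasource → prefix table; nodes without
a usable xref get a pathway-local URI
(`<pathway>/DataNode/<graph id>`).  Interaction URIs are minted as
`<pathway>/Interaction/<edge graph id>` — stable and diffable.
Literals are plain strings except pathway titles, which carry an `@en`
language tag.

Turtle output is deterministic by construction: a fixed sorted prefix
block, then one line per triple sorted by (subject, predicate, object)
in prefixed N3 form.  Equal triple sets produce byte-identical files.
Parsing uses rdflib; the writer emits standard Turtle that rdflib reads
back losslessly.

## Identifier mapping

The equivalence index is a union-find partition built from a local TSV
(one class per line; lines sharing a URI merge transitively).  Lookup
of an unknown URI returns a singleton, so mapping is enrichment, never
a gate.  The canonical representative of a class is its
lexicographically least identifiers.org member (least member overall if
none), which makes canonicalization independent of load order.  URIs
are normalized before lookup — scheme-less `identifiers.org/...`
shorthand, `http://identifiers.org`, and a few well-known raw registry
URL patterns all map onto `https://identifiers.org/...`.  One-to-many
cross-species ambiguity is out of scope: the model is a disjoint
partition.

## Query semantics

`downstream` ≙ the entity is a source (it acts on what lies downstream
of it); `upstream` ≙ the entity is a target.  The unfiltered default
(`both`) returns all adjacency including undirected interactions.  A
record in which the entity is both source and target (a self-loop, e.g.
via group expansion) counts once, not once per role.  Organism
filtering is case-insensitive exact match on the pathway's organism
string.  The count call is implemented as the length of the list call,
making their consistency structural.  Unknown pathway URIs yield an
empty result with status `unknown-pathway` rather than an error, so
callers can distinguish "no such pathway" from "pathway with no
interactions".  Result items are stable-sorted by
(pathway URI, interaction URI); JSON key order is fixed.

## Synthetic data

The fixture generator emulates the structural variety of community
pathway content: nodes of mixed biological classes (weighted toward
gene products and proteins) with unique cross-references drawn from six
registries, edges over the full arrowhead palette including headless
(undirected) lines, optional groups wired into edges as endpoints,
optional anchors, and catalyst edges attached to anchored conversions.
Defaults (8 nodes, 6 edges, human) are desk-scale; tests and the
acceptance script run hundreds of such documents in seconds.  It is a
pure function of (spec, seed).

What it does **not** emulate: drawn layout semantics (coordinates are
arbitrary), Label/Shape/State decoration, nested complex states,
multi-point waypoint geometry, and the label/xref inconsistencies of
real community content (every generated node has a well-formed, unique
xref).  Passing round-trip and oracle tests on generated documents
therefore demonstrates correctness of the structural semantics, not
robustness to every curation artifact in the wild — the parser's
warning pathway (dangling references, unknown classes, unknown heads)
is exercised by dedicated hand-built cases instead.

## Numerical and degenerate-input choices

- Anchor positions are fractions in [0, 1]; violations are validation
  errors at write time.
- Coordinates round-trip through `repr`/`float` exactly; they carry no
  semantics.
- Edges with fewer than two points, undirected edges with fewer than
  two resolvable participants, and directed edges missing a resolvable
  side are dropped with logged notices.
- Pathway-class DataNodes participate as entities of type Pathway and
  are never expanded.
- Duplicate participants (same entity, same role) collapse to one.

## Known limitations

- GPML Labels, Shapes, and States do not participate in interactions;
  nested pathway nodes are opaque endpoints.
- The RDF layer targets this package's round-trip fidelity, not
  predicate-for-predicate fidelity to published WikiPathways RDF dumps
  (no named graphs, no VoID provenance).
- Cascade inference chains only through catalyzed conversions; it does
  not follow stimulation/inhibition edges or mixed chains.
- The equivalence model cannot represent context-dependent (lens-like)
  mappings.
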