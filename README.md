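# wpinteract

Extracting typed biological interactions from pathway drawings, and
querying them by entity and direction.

Pathway databases such as WikiPathways store their content as drawings:
GPML (Graphical Pathway Markup Language) documents whose DataNodes are
genes, gene products, RNAs, metabolites, or nested pathways, and whose
edges carry arrowheads from the MIM notation (`mim-inhibition`,
`mim-catalysis`, ...), the SBGN arc vocabulary, or the basic drawing
tools (plain arrows and T-bars).  A drawing is a poor query substrate:
the same inhibition can be drawn three different ways, an enzyme is
attached to its reaction through an anchor on another line rather than
to its substrates, and a complex acting on something is one edge from a
group box.

`wpinteract` turns such drawings into a normalized interaction network
and answers the questions a drug-discovery or systems-biology user
actually asks: *what interactions make up this pathway?* — *what acts
upstream (or downstream) of this gene product, and how?* — *in how many
interactions does this metabolite participate?*  It is a self-contained
library + CLI: no remote service, no downloads; a built-in fixture
generator synthesizes arbitrarily rich GPML inputs for testing.

## What it does

- **GPML I/O** (`wpinteract.gpml`) — parse and write GPML2013a; dangling
  references degrade to warnings (real pathways contain decorative
  lines); a deterministic fixture generator emits valid documents with
  configurable node counts, arrowhead palettes, groups, and anchors.
- **Interaction normalization** (`wpinteract.semantics`) — every drawn
  edge becomes one `InteractionRecord` with a type from a closed set
  (Inhibition, Stimulation, Catalysis, Conversion, Binding,
  DirectedInteraction, UndirectedInteraction, ComplexBinding).  The
  three inhibition notations (`mim-inhibition`, `TBar`, SBGN
  `Inhibition`) collapse onto one common type.  The first endpoint's
  entities are sources, the last endpoint's are targets; group
  endpoints expand to their members, giving interactions with multiple
  sources and targets; an edge ending on a conversion's anchor with a
  `mim-catalysis` head becomes a Catalysis record.
- **Enzyme-cascade inference** (`infer_enzyme_cascade`, off by default,
  `--cascade` on the CLI) — derives the links no single line draws:
  enzyme → product for each catalyzed conversion, and enzyme₁ → enzyme₂
  whenever one reaction's product is the next one's substrate.
- **Dual-vocabulary RDF** (`wpinteract.wprdf`) — serializes to Turtle
  using two deliberately separate vocabularies: `gpml:` for the drawing
  and `wp:` for the biology (interactions typed, with `wp:source` /
  `wp:target` / `wp:participants`), bridged only by `wp:isAbout`
  cross-links.  Output is deterministic (diffable); the biological
  layer round-trips back into records.
- **Identifier mapping** (`wpinteract.idmap`) — a local equivalence
  index over URI schemes (Ensembl ↔ NCBI Gene ↔ UniProt for genes and
  proteins; HMDB, ChEBI, CAS, PubChem for metabolites), loaded from a
  TSV file, so any equivalent URI yields identical query results.
- **Queries** (`wpinteract.query`) — `get_interactions(pathway)`,
  `interactions_by_entity(entity, direction, type, organism)`, and a
  count helper guaranteed equal to the list call's length.
  `downstream` keeps interactions where the entity is a source (it acts
  on what lies downstream); `upstream` keeps those where it is a
  target; the default `both` includes undirected adjacency.

## Worked example

The classic microRNA silencing case: hsa-let-7b inhibits the kinase
gene AKT2, drawn as a T-bar edge from an Rna node to a GeneProduct
node.  Build the pathway and an identifier table, then ask what lies
upstream of AKT2 — using its **NCBI Gene** URI even though the drawing
cross-references **Ensembl**:

```python
from wpinteract import write_gpml
from wpinteract.examples import akt2_inhibition_pathway, AKT2_MAPPING_TSV

open("WP1544.gpml", "w").write(write_gpml(akt2_inhibition_pathway()))
open("mappings.tsv", "w").write(AKT2_MAPPING_TSV + "\n")
```

```
$ wpinteract by-entity https://identifiers.org/ncbigene/208 \
    --gpml WP1544.gpml --mappings mappings.tsv --direction upstream
{
  "items": [
    {
      "interaction_uri": "https://identifiers.org/wikipathways/WP1544/Interaction/e1",
      "pathway_uri": "https://identifiers.org/wikipathways/WP1544",
      "type": "Inhibition",
      "derived": false,
      "participants": [
        {
          "uri": "https://identifiers.org/mirbase/MI0000063",
          "label": "hsa-let-7b",
          "entity_type": "Rna",
          "role": "source"
        },
        {
          "uri": "https://identifiers.org/ensembl/ENSG00000105221",
          "label": "AKT2",
          "entity_type": "GeneProduct",
          "role": "target"
        }
      ]
    }
  ],
  "count": 1,
  "status": "ok",
  "echo": {
    "entity_uri": "https://identifiers.org/ncbigene/208",
    "direction": "upstream",
    "type": null,
    "organism": null
  }
}
```

One interaction: an **Inhibition**, directed from source `hsa-let-7b`
(an Rna) to target `AKT2` (a GeneProduct) — the query matched the
Ensembl-referenced node through the NCBI Gene URI via the mapping
table.  The count helper agrees (`wpinteract count ...` prints `1`),
and `wpinteract convert WP1544.gpml -o WP1544.ttl` writes 36 Turtle
triples including

```
<https://identifiers.org/wikipathways/WP1544/Interaction/e1> rdf:type wp:Inhibition .
```

Other subcommands: `wpinteract interactions WP1544 --gpml ...` lists a
whole pathway; `wpinteract fixtures -o dir/ --seed 42 ...` writes
synthetic GPML files; add `--cascade` anywhere to include inferred
enzyme-cascade links.

### Mapping file format

One equivalence class per line, tab-separated URIs (scheme-less
`identifiers.org/...` shorthand allowed); lines sharing a URI merge:

```
https://identifiers.org/ensembl/ENSG00000105221	https://identifiers.org/ncbigene/208	https://identifiers.org/uniprot/P31751
```

### JSON result schema

`items` (list of interactions: `interaction_uri`, `pathway_uri`,
`type`, `derived`, `participants` with `uri` / `label` / `entity_type`
/ `role`), `count`, `status` (`ok` or `unknown-pathway`), `echo` (the
query parameters).  Key order is fixed; items are sorted by
`(pathway_uri, interaction_uri)`.

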