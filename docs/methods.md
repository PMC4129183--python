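# Methods

## Model

The package represents annotations as information content entities
(ICEs) extending the Information Artifact Ontology. Two subclasses of
`kiao:Annotation` cover everything an RDF store can hold: a resource
annotation denotes a single resource, a graph annotation denotes the
content of a named graph of one or more statements. Denotation uses
`iao:denotes`; following the named-graph semantics of Carroll et al.,
an assertion about a named graph is read as referring to the underlying
graph content, so the graph annotation denotes what the graph *says*,
not the graph-as-container. Content graphs are kept disjoint from the
default graph, which holds all annotation, reification and provenance
assertions; this separation is what lets a consumer read annotations
without committing to their propositions.

Provenance is the transitive relation `kiao:basedOn`, with domain and
range ICE and no cardinality restrictions. At the coarse level it links
annotations to the annotations they were built from. At the fine level,
content statements are reified as `kiao:RdfStatement` (attached to
their graph annotation via `obo:has_part`) and their positions as
`kiao:RdfStatementElement` via `kiao:subjectElement` /
`kiao:propertyElement` / `kiao:objectElement`, each an
`rdfs:subPropertyOf obo:has_part` with domain `RdfStatement` and range
`RdfStatementElement`. Elements denote the term at their position, so a
fully reified statement is exactly reconstructible from its elements;
`basedOn` edges from elements (to annotations or to other elements)
record which piece of which statement came from where. The element
properties deliberately mirror `rdf:subject`/`rdf:property`/`rdf:object`
in name, but classic `rdf:Statement` reification is *not* emitted in
parallel — doing so would double every reification count.

## Assumptions and representational choices

- **Blank nodes are disallowed.** Element-level provenance requires
  every statement position to denote a referable term; callers must
  skolemize. The reader rejects documents containing blank nodes.
- **One graph per annotation.** Whether two graph annotations may
  denote the same named graph is not settled by the model; this package
  forbids it, so a content graph has a unique owning annotation and the
  cost accounting has an unambiguous partition.
- **Targets are out of scope.** How an annotation anchors to a text
  span or sequence region (`oa:hasTarget`-style links) is a separate
  concern; builders accept only an opaque `note` string, never target
  quads. Consequently the count report's text-span column is `n/a`.
- **Type quads are materialized but tagged.** The `rdf:type` quads the
  builders emit all follow from declared domains/ranges (or from the
  builder itself), so they are tagged *inferable* and every count is
  reported both without and with them — the `N (M)` convention.
- **Transitivity is declared, never materialized.** The TBox declares
  `basedOn` transitive; closures are computed at query time (the SPARQL
  equivalents use `basedOn+` property paths). Mixed-granularity chains
  (element → element → annotation) are traced through a single closure,
  since there is a single relation; `granularity="annotation"` filters
  results, not paths.
- **Cycles warn, strict mode rejects.** The relation is declared
  transitive but not acyclic, so cycles are representable; they almost
  always indicate a modeling error, so `assert_based_on` warns by
  default and `strict_cycles=True` refuses. `retraction_set` falls back
  to a deterministic sorted order (with a warning) when a cycle makes a
  topological order impossible.
- **Literal-denoting elements are allowed** for object positions and
  flagged as warnings by the validator: the worked examples use only
  IRIs, but real content graphs carry literals.
- **Shared statements are reified per graph.** A triple reused verbatim
  in two content graphs gets separate statement/element instances under
  each annotation; a `copyOf`-style shortcut between them is a possible
  future optimization, not implemented.

## Triple-cost accounting

Each builder-emitted quad belongs to exactly one annotation and one
category: **A** (denotes + content quads; + own type), **B** (direct
annotation-level `basedOn` quads), **C** (per statement: `has_part`,
element links, element denotes, element `basedOn`; + statement and
element types). `partition_check` verifies exhaustiveness and
exclusivity against the raw quad count. The analytic worst case per
statement is C = 1 + 3·2 + 3 = 10 (14 with the 4 type quads), of which
7 are pure reification; the syntactic example's `ga1` costs
2 (3) | 4 | 9 (13) because the property element carries no provenance.

Parts of the semantic example are **reconstructions**: the published
account fixes `ga2` (2 content quads, 2 bases, both statements fully
reified, element edges se6→ra7 plus one for the positive-regulation
class) but for `ga3` gives only its ingredients and the totals
6 (7) | 3 | 32 (48). The store built here satisfies that arithmetic
with five content quads in `g3` (including the statement shared
verbatim with `g2`), a third annotation-level basis `ra7` (motivated by
`g3` referencing STAT6 directly), reification of four of the five
statements, and four element-level edges including the chain
`se9 basedOn se6`. These rows are therefore regression checks on the
documented reconstruction, not independently attested values.

## Synthetic annotation stacks

`generate_stack(StackSpec)` emulates pipeline layering: layer *k*
annotations may only be `basedOn` layers < *k*, so stacks are acyclic
by construction. Defaults — 3 layers, 4 annotations per layer, half
graph annotations, 2 bases per annotation, element provenance on half
the element positions of fully reified statements, 1–3 statements per
graph — approximate the density of the worked examples (a tokenizer /
tagger / parser pipeline). Generation is fully driven by
`random.Random(seed)`.

What the generator does *not* emulate: partially reified statements,
literal objects, non-model quads mixed into the store, very deep (>4
layer) or very wide stacks, and semantically meaningful content graphs.
Passing property tests on stacks therefore demonstrate structural
correctness of closure, reconstruction, serialization and validation —
not robustness to arbitrary real-world RDF, which is instead covered by
the opaque-quad preservation path of the reader.

## Numerical and procedural choices

- Closure and ordering use networkx (`ancestors`/`descendants`,
  `lexicographical_topological_sort`); test oracles recompute them by
  brute-force path enumeration.
- Serialization is canonical: prefixes sorted, default graph first,
  named graphs sorted by IRI, quads sorted by term; term text is
  produced by rdflib's N3 writer with only the model's seven prefixes
  bound. This makes write→read→write byte-identical, which the tests
  and golden comparisons rely on.
- Reading recovers each reified statement's source triple by matching
  element denotations against the parent's content quads. The model
  itself never asserts this binding; an ambiguous or empty match leaves
  the statement unresolved and the validator reports it.
- Validation findings are data (`code`, `severity`, `subject`,
  `message`; JSON-lines export), not exceptions, so damaged stores can
  be loaded and inspected.
- Problem sizes in `scripts/acceptance.py` (200 stacks of ≤3 layers ×
  ≤3 annotations, ≤2 statements per graph annotation) keep the full
  recomputation in the low seconds while exercising every edge-type
  combination the generator can produce.

## Known limitations

- No OWL reasoning beyond the declared axioms; `infer_types` applies
  only the element-link domain/range entailments, and `infer_has_part`
  only the annotation→statement→element chain, not general partonomy.
- JSON-LD and RDF/XML are not supported; TriG and N-Quads (and Turtle
  for the TBox) cover the model's needs.
- The `kro:` namespace is reserved for relation-ontology extensions but
  defines no terms.
- Annotation metadata (author, date, confidence) and target anchoring
  are intentionally absent; they compose orthogonally via existing
  annotation models.
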