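"""Model vocabulary: namespaces, term IRIs, and the TBox.

Every IRI belonging to the annotation model resolves through a
:class:`Vocab` instance.  The model extends the Information Artifact
Ontology (IAO): annotations are information content entities (ICEs)
that *denote* the knowledge they carry — a single resource for resource
annotations, the content of a named graph for graph annotations — and
the transitive relation ``kiao:basedOn`` records provenance between
ICEs at any granularity (annotation, reified statement, or statement
element).

Base IRIs are configurable; the defaults below are documented choices,
since the model is defined in terms of prefixes.  The ``iao:`` and
``obo:`` terms use readable local names (``iao:denotes``,
``obo:has_part``) rather than numeric OBO PURLs so that serialized
stores are human-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
# Used for the basedOn transitivity declaration; deliberately not part of
# the prefix map, which is fixed to the model's seven prefixes.
OWL_TRANSITIVE_PROPERTY = "http://www.w3.org/2002/07/owl#TransitiveProperty"

DEFAULT_NAMESPACES: dict[str, str] = {
    "kiao": "http://kabob.ucdenver.edu/iao/",
    "kro": "http://kabob.ucdenver.edu/ro/",  # reserved, no terms defined
    "iao": "http://purl.obolibrary.org/obo/iao/",
    "obo": "http://purl.obolibrary.org/obo/",
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "ex": "http://example.org/",
}

#: model term -> (prefix, local name)
_TERMS: dict[str, tuple[str, str]] = {
    "Annotation": ("kiao", "Annotation"),
    "RdfResourceAnnotation": ("kiao", "RdfResourceAnnotation"),
    "RdfGraphAnnotation": ("kiao", "RdfGraphAnnotation"),
    "RdfStatement": ("kiao", "RdfStatement"),
    "RdfStatementElement": ("kiao", "RdfStatementElement"),
    "basedOn": ("kiao", "basedOn"),
    "subjectElement": ("kiao", "subjectElement"),
    "propertyElement": ("kiao", "propertyElement"),
    "objectElement": ("kiao", "objectElement"),
    "denotes": ("iao", "denotes"),
    "informationContentEntity": ("iao", "informationContentEntity"),
    "has_part": ("obo", "has_part"),
    "type": ("rdf", "type"),
    "subClassOf": ("rdfs", "subClassOf"),
    "subPropertyOf": ("rdfs", "subPropertyOf"),
    "domain": ("rdfs", "domain"),
    "range": ("rdfs", "range"),
    "label": ("rdfs", "label"),
    "Class": ("rdfs", "Class"),
    "Property": ("rdf", "Property"),
}

#: mnemonic instance-name prefixes mirroring the figures
KIND_PREFIXES: dict[str, str] = {
    "resource-annotation": "ra",
    "graph-annotation": "ga",
    "statement": "s",
    "statement-element": "se",
    "graph": "g",
}


class VocabError(ValueError):
    """Raised for namespace/term misconfiguration or IRI collisions."""


@dataclass
class Vocab:
    """Namespace policy and model term table.

    Parameters override individual base IRIs; prefixes are fixed to the
    model's seven (kiao, kro, iao, obo, rdf, rdfs, ex).
    """

    namespaces: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_NAMESPACES))

    def __post_init__(self) -> None:
        missing = set(DEFAULT_NAMESPACES) - set(self.namespaces)
        if missing:
            raise VocabError(f"missing namespace prefixes: {sorted(missing)}")
        self._iris: dict[str, str] = {
            term: self.namespaces[prefix] + local for term, (prefix, local) in _TERMS.items()
        }
        seen: dict[str, str] = {}
        for term, iri in self._iris.items():
            if iri in seen:
                raise VocabError(f"terms {seen[iri]!r} and {term!r} share IRI {iri}")
            seen[iri] = term

    def term(self, name: str) -> str:
        """Full IRI of a model term, e.g. ``term('basedOn')``."""
        try:
            return self._iris[name]
        except KeyError:
            raise VocabError(f"unknown model term {name!r}") from None

    def __getitem__(self, name: str) -> str:
        return self.term(name)

    def expand(self, curie: str) -> str:
        """Expand ``prefix:local`` against the namespace map."""
        prefix, _, local = curie.partition(":")
        if prefix not in self.namespaces:
            raise VocabError(f"unknown prefix {prefix!r}")
        return self.namespaces[prefix] + local

    def compact(self, iri: str) -> str:
        """Best-effort CURIE for an IRI; returns the IRI if no prefix fits."""
        best = ""
        out = iri
        for prefix, base in self.namespaces.items():
            if iri.startswith(base) and len(base) > len(best):
                best, out = base, f"{prefix}:{iri[len(base):]}"
        return out

    def mint_iri(self, kind: str, label_hint: str = "", counter: int = 0,
                 existing: set[str] | frozenset[str] = frozenset()) -> str:
        """Deterministic mnemonic instance IRI in the ``ex:`` namespace.

        ``kind`` selects the figure-style prefix (``ra``/``ga``/``s``/
        ``se``/``g``); ``label_hint`` is inserted between prefix and
        counter when given.  Collisions with ``existing`` raise.
        """
        if counter < 0:
            raise VocabError("counter must be >= 0")
        try:
            mnemonic = KIND_PREFIXES[kind]
        except KeyError:
            raise VocabError(f"unknown term kind {kind!r}") from None
        local = f"{mnemonic}{label_hint}{counter}"
        iri = self.namespaces["ex"] + local
        if iri in existing:
            raise VocabError(f"minted IRI collides with existing {iri}")
        return iri

    # -- link-property helpers -------------------------------------------

    def element_link_properties(self) -> tuple[str, str, str]:
        """(subjectElement, propertyElement, objectElement) IRIs."""
        return (self["subjectElement"], self["propertyElement"], self["objectElement"])

    def position_property(self, position: str) -> str:
        """Link property for a statement position (subject/property/object)."""
        props = {"subject": "subjectElement", "property": "propertyElement",
                 "object": "objectElement"}
        if position not in props:
            raise VocabError(f"unknown statement position {position!r}")
        return self[props[position]]

    # -- TBox -------------------------------------------------------------

    def emit_tbox(self) -> set[tuple[str, str, str]]:
        """The model's class/property declarations and axioms as triples.

        Declares the Annotation hierarchy under the IAO information
        content entity, the reification classes, the three element-link
        subproperties of ``obo:has_part`` with their domains and ranges,
        and ``kiao:basedOn`` as a transitive relation between ICEs.
        Transitive entailment itself is computed at query time, never
        materialized.
        """
        t, sub, dom, rng, subp = (self["type"], self["subClassOf"], self["domain"],
                                  self["range"], self["subPropertyOf"])
        ice = self["informationContentEntity"]
        triples: set[tuple[str, str, str]] = set()
        for cls in ("Annotation", "RdfResourceAnnotation", "RdfGraphAnnotation",
                    "RdfStatement", "RdfStatementElement", "informationContentEntity"):
            triples.add((self[cls], t, self["Class"]))
        triples.add((self["Annotation"], sub, ice))
        triples.add((self["RdfResourceAnnotation"], sub, self["Annotation"]))
        triples.add((self["RdfGraphAnnotation"], sub, self["Annotation"]))
        triples.add((self["RdfStatement"], sub, ice))
        triples.add((self["RdfStatementElement"], sub, ice))
        for prop in ("basedOn", "subjectElement", "propertyElement", "objectElement",
                     "denotes", "has_part"):
            triples.add((self[prop], t, self["Property"]))
        for link in self.element_link_properties():
            triples.add((link, subp, self["has_part"]))
            triples.add((link, dom, self["RdfStatement"]))
            triples.add((link, rng, self["RdfStatementElement"]))
        triples.add((self["basedOn"], dom, ice))
        triples.add((self["basedOn"], rng, ice))
        triples.add((self["basedOn"], t, OWL_TRANSITIVE_PROPERTY))
        return triples

    def iter_terms(self) -> Iterator[tuple[str, str]]:
        yield from self._iris.items()


DEFAULT_VOCAB = Vocab()
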