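"""Persistent ontology store: terms, characters, hierarchy and equivalence.

The store mimics a small OBO-style phenotype ontology.  Three root classes
are seeded on creation — an anatomic-structure root (annotated as
equivalent to UBERON's anatomical entity), a perceived-quality root
(annotated as a subclass of PATO's quality) and a *new additions* holding
class under which author-contributed structure terms receive their
permanent identifiers immediately, before an ontology engineer re-files
them.  The holding class is itself a subclass of the anatomic-structure
root, so freshly added landmark terms are both "under new additions" and
anatomic structures.

Identifiers are never reassigned: deprecation flips a status flag and
keeps every axiom for history.  Equivalence axioms are unordered pairs
whose transitive closure (connected components of the axiom graph) gives
the equivalence class of an entity.

Persistence is a single JSON document; OBO 1.4 and Turtle exports are
one-way.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from measurement_recorder import config
from measurement_recorder.errors import (
    CycleError,
    DuplicateLabelError,
    StoreIOError,
    ValidationError,
)

# Logical-clock epoch: timestamps are epoch + tick seconds, which keeps
# stores built from the same seed byte-identical.
_EPOCH = datetime.datetime(2018, 9, 1, 0, 0, 0, tzinfo=datetime.timezone.utc)

ACTIVE = "active"
DEPRECATED = "deprecated"


@dataclass
class Term:
    """One ontology entry: an anatomic structure or a perceived quality.

    A term carries the four author-provided pieces of a definition — the
    label, a verbal definition, a sample sentence and a taxon example —
    plus provenance (creator, creation timestamp) and its place in the
    subclass hierarchy (``parent_id``; ``None`` only for roots).
    """

    id: str
    label: str
    verbal_definition: str = ""
    sample_sentence: str = ""
    taxon_example: str = ""
    parent_id: Optional[str] = None
    status: str = ACTIVE
    creator: str = ""
    created_at: str = ""

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "label": self.label,
            "verbal_definition": self.verbal_definition,
            "sample_sentence": self.sample_sentence,
            "taxon_example": self.taxon_example,
            "parent_id": self.parent_id,
            "status": self.status,
            "creator": self.creator,
            "created_at": self.created_at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Term":
        # Optional definition fields default to empty strings (older minor
        # schema versions omitted them).
        return cls(
            id=d["id"],
            label=d["label"],
            verbal_definition=d.get("verbal_definition", ""),
            sample_sentence=d.get("sample_sentence", ""),
            taxon_example=d.get("taxon_example", ""),
            parent_id=d.get("parent_id"),
            status=d.get("status", ACTIVE),
            creator=d.get("creator", ""),
            created_at=d.get("created_at", ""),
        )


@dataclass
class OntologyStore:
    """Terms plus characters, subclass links, equivalence axioms, counter."""

    terms: dict = field(default_factory=dict)  # id -> Term
    characters: dict = field(default_factory=dict)  # id -> Character
    equivalence_axioms: list = field(default_factory=list)  # sorted (a, b) pairs
    next_numeric_id: int = config.FIRST_FREE_NUMERIC_ID
    annotations: dict = field(default_factory=dict)  # external anchors
    log: list = field(default_factory=list)  # provenance events
    tick: int = 0  # logical clock

    # -- clock ---------------------------------------------------------

    def next_timestamp(self) -> str:
        """Advance the logical clock and return an ISO-8601 timestamp."""
        self.tick += 1
        t = _EPOCH + datetime.timedelta(seconds=self.tick)
        return t.strftime("%Y-%m-%dT%H:%M:%SZ")

    # -- identifiers ---------------------------------------------------

    def fresh_id(self) -> str:
        """Allocate the next permanent identifier (strictly increasing)."""
        identifier = config.format_id(self.next_numeric_id)
        self.next_numeric_id += 1
        return identifier

    # -- lookups -------------------------------------------------------

    def get_term(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise ValidationError(f"unknown term id: {term_id}") from None

    def get_character(self, character_id: str):
        try:
            return self.characters[character_id]
        except KeyError:
            raise ValidationError(f"unknown character id: {character_id}") from None

    def active_labels(self) -> set:
        """Case-folded labels of all active terms."""
        return {t.label.casefold() for t in self.terms.values() if t.status == ACTIVE}

    def subclass_axioms(self) -> list:
        """(child, parent) pairs derived from term parent links."""
        return sorted(
            (t.id, t.parent_id) for t in self.terms.values() if t.parent_id is not None
        )

    def parent_chain(self, term_id: str) -> list:
        """Ids from ``term_id`` up to (and including) its root."""
        chain = [term_id]
        seen = {term_id}
        current = self.get_term(term_id)
        while current.parent_id is not None:
            if current.parent_id in seen:
                raise CycleError(f"cycle in subclass graph at {current.parent_id}")
            chain.append(current.parent_id)
            seen.add(current.parent_id)
            current = self.get_term(current.parent_id)
        return chain

    def log_event(self, kind: str, **payload) -> None:
        self.log.append({"timestamp": self.next_timestamp(), "kind": kind, **payload})


def new_store() -> OntologyStore:
    """Create a store seeded with the three root classes and their anchors."""
    store = OntologyStore()
    roots = [
        (config.ROOT_ANATOMIC_STRUCTURE, "anatomic structure", None),
        (config.ROOT_PERCEIVED_QUALITY, "perceived quality", None),
        (config.ROOT_NEW_ADDITIONS, "new additions", config.ROOT_ANATOMIC_STRUCTURE),
    ]
    for term_id, label, parent in roots:
        store.terms[term_id] = Term(
            id=term_id,
            label=label,
            verbal_definition=f"root class: {label}",
            parent_id=parent,
            creator="system",
            created_at=store.next_timestamp(),
        )
    store.annotations = {
        config.ROOT_ANATOMIC_STRUCTURE: {
            "equivalent_to": config.ANCHOR_ANATOMIC_EQUIVALENT
        },
        config.ROOT_PERCEIVED_QUALITY: {"subclass_of": config.ANCHOR_QUALITY_PARENT},
    }
    return store


# ---------------------------------------------------------------------------
# Term operations
# ---------------------------------------------------------------------------


def add_term(
    label: str,
    verbal_definition: str,
    sample_sentence: str,
    taxon_example: str,
    creator: str,
    store: OntologyStore,
    parent_id: Optional[str] = None,
) -> Term:
    """Register a new term under the *new additions* holding class.

    The term receives its permanent identifier right away.  Raises
    :class:`DuplicateLabelError` (naming the existing id) when an active
    term already carries the same case-folded label — callers should reuse
    that term instead.
    """
    if not label or not label.strip():
        raise ValidationError("term label must be non-empty")
    label = " ".join(label.split())
    folded = label.casefold()
    for term in store.terms.values():
        if term.status == ACTIVE and term.label.casefold() == folded:
            raise DuplicateLabelError(label, term.id)
    if parent_id is None:
        parent_id = config.ROOT_NEW_ADDITIONS
    elif parent_id not in store.terms:
        raise ValidationError(f"unknown parent id: {parent_id}")
    term = Term(
        id=store.fresh_id(),
        label=label,
        verbal_definition=verbal_definition,
        sample_sentence=sample_sentence,
        taxon_example=taxon_example,
        parent_id=parent_id,
        creator=creator,
        created_at=store.next_timestamp(),
    )
    store.terms[term.id] = term
    return term


def find_terms(label_query: str, store: OntologyStore) -> list:
    """Case-insensitive exact-label matches among active terms, by id."""
    folded = label_query.casefold().strip()
    hits = [
        t
        for t in store.terms.values()
        if t.status == ACTIVE and t.label.casefold() == folded
    ]
    return sorted(hits, key=lambda t: t.id)


def deprecate_term(term_id: str, store: OntologyStore) -> Term:
    """Mark a term deprecated; its id and axioms are retained for history."""
    term = store.get_term(term_id)
    if term.status == DEPRECATED:
        raise ValidationError(f"term {term_id} is already deprecated")
    term.status = DEPRECATED
    store.log_event("deprecated", entity=term_id)
    return term


def reparent_term(term_id: str, new_parent_id: str, store: OntologyStore) -> OntologyStore:
    """Move a term under a new parent (ontology-engineer curation hook).

    Roots cannot be moved and the move must not create a cycle in the
    subclass graph.  The move is recorded in the store's provenance log.
    """
    term = store.get_term(term_id)
    store.get_term(new_parent_id)
    if term.parent_id is None:
        raise ValidationError(f"{term_id} is a root and cannot be reparented")
    if term_id == new_parent_id or term_id in store.parent_chain(new_parent_id):
        raise CycleError(
            f"moving {term_id} under {new_parent_id} would create a cycle"
        )
    old = term.parent_id
    term.parent_id = new_parent_id
    store.log_event("reparented", entity=term_id, old_parent=old, new_parent=new_parent_id)
    return store


# ---------------------------------------------------------------------------
# Equivalence axioms
# ---------------------------------------------------------------------------


def _known_entity(entity_id: str, store: OntologyStore) -> None:
    if entity_id not in store.terms and entity_id not in store.characters:
        raise ValidationError(f"unknown id: {entity_id}")


def add_equivalence(id_a: str, id_b: str, store: OntologyStore) -> OntologyStore:
    """Record an unordered equivalence axiom between two entities.

    Equivalence is the OWL ``equivalentClass`` relation between characters
    (or terms) that denote the same measurement; a self-equivalence is
    rejected, and a pair is stored at most once.
    """
    if id_a == id_b:
        raise ValidationError(f"cannot declare {id_a} equivalent to itself")
    _known_entity(id_a, store)
    _known_entity(id_b, store)
    pair = tuple(sorted((id_a, id_b)))
    if pair not in {tuple(p) for p in store.equivalence_axioms}:
        store.equivalence_axioms.append(list(pair))
        store.equivalence_axioms.sort()  # canonical order, stable on reload
    return store


def equivalence_class(entity_id: str, store: OntologyStore) -> set:
    """Members of the transitive closure containing ``entity_id``.

    Computed as the connected component of the axiom graph; a node with no
    axioms forms a singleton class.
    """
    _known_entity(entity_id, store)
    graph = nx.Graph()
    graph.add_node(entity_id)
    graph.add_edges_from(tuple(p) for p in store.equivalence_axioms)
    return set(nx.node_connected_component(graph, entity_id))


# ---------------------------------------------------------------------------
# Persistence: canonical JSON, one-way OBO 1.4 and Turtle exports
# ---------------------------------------------------------------------------


def store_to_dict(store: OntologyStore) -> dict:
    return {
        "schema_version": config.SCHEMA_VERSION,
        "next_numeric_id": store.next_numeric_id,
        "tick": store.tick,
        "annotations": store.annotations,
        "terms": [t.to_dict() for t in sorted(store.terms.values(), key=lambda t: t.id)],
        "characters": [
            c.to_dict()
            for c in sorted(store.characters.values(), key=lambda c: c.id)
        ],
        "equivalence_axioms": sorted(map(list, store.equivalence_axioms)),
        "log": store.log,
    }


def store_from_dict(doc: dict) -> OntologyStore:
    from measurement_recorder.character_model import Character

    if not isinstance(doc, dict) or "terms" not in doc:
        raise StoreIOError("not a store document: missing 'terms'")
    version = doc.get("schema_version", 1)
    if version > config.SCHEMA_VERSION:
        raise StoreIOError(
            f"store schema version {version} is newer than supported "
            f"({config.SCHEMA_VERSION})"
        )
    store = OntologyStore(
        next_numeric_id=doc.get("next_numeric_id", config.FIRST_FREE_NUMERIC_ID),
        annotations=doc.get("annotations", {}),
        log=doc.get("log", []),
        tick=doc.get("tick", 0),
    )
    for i, raw in enumerate(doc["terms"]):
        try:
            term = Term.from_dict(raw)
        except KeyError as exc:
            raise StoreIOError(f"terms[{i}]: missing field {exc}") from None
        if term.id in store.terms:
            raise StoreIOError(f"terms[{i}]: duplicate id {term.id}")
        store.terms[term.id] = term
    for i, raw in enumerate(doc.get("characters", [])):
        try:
            char = Character.from_dict(raw)
        except KeyError as exc:
            raise StoreIOError(f"characters[{i}]: missing field {exc}") from None
        if char.id in store.characters or char.id in store.terms:
            raise StoreIOError(f"characters[{i}]: duplicate id {char.id}")
        store.characters[char.id] = char
    store.equivalence_axioms = sorted(
        map(list, {tuple(p) for p in doc.get("equivalence_axioms", [])})
    )
    return store


def save_store(store: OntologyStore, path) -> None:
    """Write the canonical JSON document (UTF-8, sorted, deterministic)."""
    Path(path).write_text(
        json.dumps(store_to_dict(store), indent=1, ensure_ascii=False, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )


def load_store(path) -> OntologyStore:
    """Read a canonical JSON store; ``load(save(s)) == s`` (deep equality)."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise StoreIOError(f"cannot read store file {path}: {exc}") from None
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StoreIOError(
            f"malformed store file {path}: line {exc.lineno} column {exc.colno}: "
            f"{exc.msg}"
        ) from None
    return store_from_dict(doc)


def _obo_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export_obo(store: OntologyStore, path) -> None:
    """One-way OBO 1.4 flat-file export (``[Term]`` stanzas; no import)."""
    lines = [
        "format-version: 1.4",
        f"ontology: {config.ID_PREFIX.lower()}",
        "",
    ]
    equiv: dict = {}
    for a, b in store.equivalence_axioms:
        equiv.setdefault(a, []).append(b)
        equiv.setdefault(b, []).append(a)

    def stanza(entity_id, label, definition, parent, deprecated):
        out = ["[Term]", f"id: {entity_id}", f"name: {label}"]
        if definition:
            out.append(f'def: "{_obo_escape(definition)}" []')
        if parent:
            out.append(f"is_a: {parent}")
        for other in sorted(equiv.get(entity_id, [])):
            out.append(f"equivalent_to: {other}")
        if deprecated:
            out.append("is_obsolete: true")
        out.append("")
        return out

    for term in sorted(store.terms.values(), key=lambda t: t.id):
        lines += stanza(
            term.id,
            term.label,
            term.verbal_definition,
            term.parent_id,
            term.status == DEPRECATED,
        )
    for char in sorted(store.characters.values(), key=lambda c: c.id):
        lines += stanza(
            char.id,
            char.name.text(),
            char.method.display_text(),
            config.ROOT_PERCEIVED_QUALITY,
            char.status == DEPRECATED,
        )
    anchors = store.annotations.get(config.ROOT_ANATOMIC_STRUCTURE, {})
    if "equivalent_to" in anchors:
        lines.append(f"! {config.ROOT_ANATOMIC_STRUCTURE} equivalent_to "
                     f"{anchors['equivalent_to']} (external anchor)")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_turtle(store: OntologyStore, path) -> None:
    """One-way RDF/Turtle export via rdflib (subclass + equivalence)."""
    from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

    ns = Namespace("http://example.org/carex/")

    def uri(entity_id: str) -> URIRef:
        return ns[entity_id.replace(":", "_")]

    g = Graph()
    g.bind("carex", ns)
    g.bind("owl", OWL)
    for term in store.terms.values():
        node = uri(term.id)
        g.add((node, RDF.type, OWL.Class))
        g.add((node, RDFS.label, Literal(term.label)))
        if term.parent_id:
            g.add((node, RDFS.subClassOf, uri(term.parent_id)))
        if term.verbal_definition:
            g.add((node, RDFS.comment, Literal(term.verbal_definition)))
    for char in store.characters.values():
        node = uri(char.id)
        g.add((node, RDF.type, OWL.Class))
        g.add((node, RDFS.label, Literal(char.name.text())))
        g.add((node, RDFS.subClassOf, uri(config.ROOT_PERCEIVED_QUALITY)))
    for a, b in store.equivalence_axioms:
        g.add((uri(a), OWL.equivalentClass, uri(b)))
    g.serialize(destination=str(path), format="turtle")


def validate_store(store: OntologyStore) -> None:
    """Check structural invariants; raises ``ValidationError`` on breach.

    Verifies id uniqueness across terms and characters, that every active
    term reaches a root through active-or-deprecated parents, that the
    subclass graph is acyclic and that equivalence axioms reference known
    entities.
    """
    overlap = set(store.terms) & set(store.characters)
    if overlap:
        raise ValidationError(f"ids shared between terms and characters: {overlap}")
    for term in store.terms.values():
        if not term.label:
            raise ValidationError(f"term {term.id} has an empty label")
        store.parent_chain(term.id)  # raises CycleError on a cycle
    for a, b in store.equivalence_axioms:
        _known_entity(a, store)
        _known_entity(b, store)
    numeric = [config.numeric_suffix(i) for i in (*store.terms, *store.characters)]
    if numeric and max(numeric) >= store.next_numeric_id:
        raise ValidationError("id counter is behind existing identifiers")
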