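"""Character lifecycle: naming grammar, landmark methods, reuse semantics.

A *continuous character* is a named numeric measurement such as
``length of perigynium beak``.  Its name follows a controlled grammar
(``<quality> of <structure>`` or ``<quality> between <structures>``), its
measurement method is a five-field landmark schema (from / to / include /
exclude / at), and it must carry a unit and a creator before it can be
saved into the ontology.  Every word used in a method definition is
checked against the ontology; unknown words must be registered as terms
(with a verbal definition, sample sentence and taxon example) before the
character can be saved.

Reuse comes in two flavours: *use this* adopts an existing character
verbatim and increments its usage count; *clone and enhance* creates a new
character from an existing one, shares creatorship with the original
creator and records an OWL-style equivalence axiom between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from measurement_recorder import config, ontology_store
from measurement_recorder.errors import (
    DuplicateNameError,
    GrammarError,
    UnknownTermsError,
    ValidationError,
)
from measurement_recorder.ontology_store import ACTIVE, DEPRECATED, OntologyStore

_NUMBER_RE = re.compile(r"^\d+(?:[.,]\d+)?$")
_EDGE_PUNCT = "".join(c for c in "!\"#$%&'()*+,./:;<=>?@[\\]^`{|}~")

METHOD_FIELDS = ("from_landmark", "to_landmark", "include", "exclude", "at")
_FIELD_LABELS = {
    "from_landmark": "From",
    "to_landmark": "To",
    "include": "Include",
    "exclude": "Exclude",
    "at": "At",
}


def _normalize_phrase(text: str) -> str:
    return " ".join(text.split()).lower()


@dataclass(frozen=True)
class CharacterName:
    """Parsed character name: quality + preposition + structure phrase(s).

    The grammar is quality-first: ``length of leaf`` is accepted,
    ``leaf length`` is not.  ``between`` takes either a single plural
    structure phrase (``distance between pupils``) or two phrases joined
    by ``and`` (``distance between apex and base``).
    """

    quality: str
    preposition: str  # "of" | "between"
    structures: tuple

    def text(self) -> str:
        """Canonical rendering (lowercase, single spaces)."""
        joined = " and ".join(self.structures)
        return f"{self.quality} {self.preposition} {joined}"

    def tokens(self) -> list:
        return self.text().split()


def parse_character_name(text: str) -> CharacterName:
    """Parse a character name against the quality-first grammar.

    Raises :class:`GrammarError` for noun-phrase-first forms and anything
    else that does not match ``<quality> of <structure>`` or
    ``<quality> between <structure(s)>``.
    """
    normalized = _normalize_phrase(text)
    if not normalized:
        raise GrammarError(
            "empty character name; expected '<quality> of <structure>' or "
            "'<quality> between <structures>'"
        )
    words = normalized.split()
    preposition = None
    for candidate in ("of", "between"):
        if candidate in words:
            preposition = candidate
            split_at = words.index(candidate)
            break
    if preposition is None or split_at == 0 or split_at == len(words) - 1:
        raise GrammarError(
            f"character name {normalized!r} does not match the pattern "
            "'<quality> of <structure>' or '<quality> between <structures>' "
            "(e.g. 'length of leaf' is accepted, 'leaf length' is not)"
        )
    quality = " ".join(words[:split_at])
    rest = words[split_at + 1 :]
    if preposition == "of":
        structures = (" ".join(rest),)
    else:
        if "and" in rest:
            i = rest.index("and")
            left, right = " ".join(rest[:i]), " ".join(rest[i + 1 :])
            if not left or not right:
                raise GrammarError(
                    f"'between' in {normalized!r} needs two structures joined "
                    "by 'and', or one plural structure"
                )
            structures = (left, right)
        else:
            phrase = " ".join(rest)
            if not phrase.split()[-1].endswith("s"):
                raise GrammarError(
                    f"'between' in {normalized!r} needs a plural structure "
                    "(e.g. 'distance between pupils') or two structures "
                    "joined by 'and'"
                )
            structures = (phrase,)
    return CharacterName(quality=quality, preposition=preposition, structures=structures)


@dataclass
class MethodDefinition:
    """Five-field landmark schema describing how a measurement is taken.

    ``from_landmark`` and ``to_landmark`` name the start and end landmarks,
    ``include``/``exclude`` list structures counted in or out of the
    measurement, and ``at`` gives the position for measurements taken at a
    point (e.g. a width at the widest part).
    """

    from_landmark: str = ""
    to_landmark: str = ""
    include: list = field(default_factory=list)
    exclude: list = field(default_factory=list)
    at: str = ""

    def field_texts(self) -> dict:
        """Field name → displayable text (lists joined with commas)."""
        return {
            "from_landmark": self.from_landmark,
            "to_landmark": self.to_landmark,
            "include": ", ".join(self.include),
            "exclude": ", ".join(self.exclude),
            "at": self.at,
        }

    def is_empty(self) -> bool:
        return not any(self.field_texts().values())

    def has_landmarks(self) -> bool:
        """A usable text method names at least one of from/to/at."""
        return bool(self.from_landmark or self.to_landmark or self.at)

    def display_text(self) -> str:
        """Human-readable one-line rendering of the non-empty fields."""
        parts = []
        for name, text in self.field_texts().items():
            if text:
                parts.append(f"{_FIELD_LABELS[name]}: {text}")
        return " ".join(parts)

    def to_dict(self) -> dict:
        return {
            "from": self.from_landmark,
            "to": self.to_landmark,
            "include": list(self.include),
            "exclude": list(self.exclude),
            "at": self.at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MethodDefinition":
        return cls(
            from_landmark=d.get("from", ""),
            to_landmark=d.get("to", ""),
            include=list(d.get("include", [])),
            exclude=list(d.get("exclude", [])),
            at=d.get("at", ""),
        )


@dataclass
class CheckReport:
    """Outcome of checking a method's words against the ontology.

    ``fields`` maps each method field to an ordered list of
    ``(word, status)`` pairs with status one of ``known`` (an active term
    label), ``new`` (needs registering) or ``stopword`` (function words and
    bare numbers, ignored).
    """

    fields: dict = field(default_factory=dict)

    @property
    def all_known(self) -> bool:
        return not self.new_words()

    def new_words(self) -> set:
        return {
            w
            for entries in self.fields.values()
            for (w, status) in entries
            if status == "new"
        }


def _tokenize(text: str) -> list:
    """Lowercased tokens with surrounding punctuation stripped; hyphens
    and digits inside a token are kept (e.g. 'struct001', 'mid-vein')."""
    tokens = []
    for raw in text.replace(",", " ").split():
        word = raw.strip(_EDGE_PUNCT).lower()
        if word:
            tokens.append(word)
    return tokens


def semantic_check(
    method: MethodDefinition,
    store: OntologyStore,
    stopwords: Iterable[str] = config.STOPWORDS,
) -> CheckReport:
    """Classify every word of a method as known / new / stopword.

    A word is *known* when it matches an active term label (case-folded);
    multi-word labels do not make their constituent words known.  Numbers
    and stopwords are ignorable.  ``all_known`` is true iff nothing needs
    registering.
    """
    stopset = {w.casefold() for w in stopwords}
    labels = store.active_labels()
    report = CheckReport()
    for name, text in method.field_texts().items():
        entries = []
        for word in _tokenize(text):
            if _NUMBER_RE.match(word) or word in stopset:
                entries.append((word, "stopword"))
            elif word in labels:
                entries.append((word, "known"))
            else:
                entries.append((word, "new"))
        report.fields[name] = entries
    return report


def register_new_terms(
    report: CheckReport,
    definitions: dict,
    creator: str,
    store: OntologyStore,
) -> list:
    """Add every *new* word of a check report to the ontology.

    ``definitions`` maps each new word to a ``(verbal_definition,
    sample_sentence, taxon_example)`` triple and must cover exactly the
    report's new-word set.  After registration, re-checking the same
    method is ``all_known``.
    """
    new = report.new_words()
    given = set(definitions)
    if given != new:
        missing = sorted(new - given)
        extra = sorted(given - new)
        parts = []
        if missing:
            parts.append(f"missing definitions for: {', '.join(missing)}")
        if extra:
            parts.append(f"definitions for words not in the report: {', '.join(extra)}")
        raise ValidationError("; ".join(parts))
    created = []
    for word in sorted(new):
        verbal, sample, taxon = definitions[word]
        created.append(
            ontology_store.add_term(word, verbal, sample, taxon, creator, store)
        )
    return created


@dataclass
class HistoryEvent:
    """Append-only provenance record on a character."""

    timestamp: str
    actor: str
    kind: str  # created | used | cloned_from | enhanced | unit_changed | method_changed
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "actor": self.actor,
            "kind": self.kind,
            "payload": self.payload,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HistoryEvent":
        return cls(
            timestamp=d["timestamp"],
            actor=d["actor"],
            kind=d["kind"],
            payload=d.get("payload", {}),
        )


@dataclass
class Character:
    """A saved continuous character living in the ontology store."""

    id: str
    name: CharacterName
    method: MethodDefinition
    unit: str
    creators: list
    usage_count: int = 1
    history: list = field(default_factory=list)
    illustrations: list = field(default_factory=list)
    structure_terms: list = field(default_factory=list)
    status: str = ACTIVE

    def used_events(self) -> int:
        return sum(1 for e in self.history if e.kind == "used")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name.text(),
            "method": self.method.to_dict(),
            "unit": self.unit,
            "creators": list(self.creators),
            "usage_count": self.usage_count,
            "history": [e.to_dict() for e in self.history],
            "illustrations": list(self.illustrations),
            "structure_terms": list(self.structure_terms),
            "status": self.status,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Character":
        return cls(
            id=d["id"],
            name=parse_character_name(d["name"]),
            method=MethodDefinition.from_dict(d["method"]),
            unit=d["unit"],
            creators=list(d["creators"]),
            usage_count=d.get("usage_count", 1),
            history=[HistoryEvent.from_dict(e) for e in d.get("history", [])],
            illustrations=list(d.get("illustrations", [])),
            structure_terms=list(d.get("structure_terms", [])),
            status=d.get("status", ACTIVE),
        )


def _link_structure_terms(name: CharacterName, store: OntologyStore) -> list:
    """Active term ids for the name's structure phrases.

    Prefers an exact-label match on the whole phrase, falling back to the
    phrase's individual content words.
    """
    linked = []
    for phrase in name.structures:
        hits = ontology_store.find_terms(phrase, store)
        if not hits:
            for word in phrase.split():
                if word not in config.STOPWORDS:
                    hits.extend(ontology_store.find_terms(word, store))
        linked.extend(t.id for t in hits if t.id not in linked)
    return linked


def create_character(
    name_text: str,
    method: MethodDefinition,
    unit: str,
    creator: str,
    store: OntologyStore,
    force: bool = False,
    illustrations: Optional[list] = None,
    units: Iterable[str] = config.UNITS,
) -> Character:
    """Define and save a new character into the ontology.

    The save is refused when the name violates the grammar, when the unit
    is missing or unknown, when the method still contains unregistered
    words (register them first via :func:`register_new_terms`), or when an
    active character with the same canonical name exists — unless
    ``force`` overrides the duplicate check.  A saved character needs a
    text method with at least one landmark, or at least one illustration.
    On success the character is a subclass of the perceived-quality root,
    linked to its structure term(s), with ``usage_count`` 1.
    """
    name = parse_character_name(name_text)
    if not unit or not unit.strip():
        raise ValidationError(
            "a unit is required before the character can be saved"
        )
    unit = unit.strip()
    if unit not in set(units):
        raise ValidationError(
            f"unknown unit {unit!r}; expected one of {sorted(set(units))}"
        )
    if not creator or not creator.strip():
        raise ValidationError("a creator name is required")
    report = semantic_check(method, store)
    if not report.all_known:
        raise UnknownTermsError(report)
    illustrations = list(illustrations or [])
    if not method.has_landmarks() and not illustrations:
        raise ValidationError(
            "a saved character needs a method naming at least one landmark "
            "(from/to/at) or at least one illustration"
        )
    if not force:
        from measurement_recorder.character_search import search_characters

        same = [
            hit
            for hit in search_characters(name.text(), store)
            if store.characters[hit.character_id].name.text() == name.text()
        ]
        if same:
            raise DuplicateNameError(name.text(), same)
    character = Character(
        id=store.fresh_id(),
        name=name,
        method=method,
        unit=unit,
        creators=[creator],
        usage_count=1,
        illustrations=illustrations,
        structure_terms=_link_structure_terms(name, store),
    )
    character.history.append(
        HistoryEvent(store.next_timestamp(), creator, "created", {"unit": unit})
    )
    store.characters[character.id] = character
    return character


def use_this(character_id: str, actor: str, store: OntologyStore) -> Character:
    """Adopt an existing character verbatim.

    Increments its usage count by exactly one and appends a ``used``
    history event; definition, unit and creators are untouched.
    Deprecated characters are refused.
    """
    character = store.get_character(character_id)
    if character.status == DEPRECATED:
        raise ValidationError(f"character {character_id} is deprecated")
    character.usage_count += 1
    character.history.append(
        HistoryEvent(store.next_timestamp(), actor, "used", {})
    )
    return character


def clone_and_enhance(
    source_id: str,
    enhanced_method: MethodDefinition,
    actor: str,
    store: OntologyStore,
    unit: Optional[str] = None,
    units: Iterable[str] = config.UNITS,
) -> Character:
    """Create an enhanced copy of a character, equivalent to its source.

    The clone is a new character (fresh id, usage count 1) whose creators
    are the source's creators plus the enhancing actor, order preserved.
    An equivalence axiom links clone and source — enhanced characters are
    meant to denote the same measurement.  The unit is inherited unless
    explicitly changed.  The source is unchanged except for a
    ``cloned_from`` cross-reference event in its history.
    """
    source = store.get_character(source_id)
    report = semantic_check(enhanced_method, store)
    if not report.all_known:
        raise UnknownTermsError(report)
    clone_unit = (unit or source.unit).strip()
    if clone_unit not in set(units):
        raise ValidationError(
            f"unknown unit {clone_unit!r}; expected one of {sorted(set(units))}"
        )
    illustrations = []
    if not enhanced_method.has_landmarks():
        # An illustration-only source may be cloned without a text method;
        # the clone then carries the source's illustrations.
        illustrations = list(source.illustrations)
        if not illustrations:
            raise ValidationError(
                "enhanced method must name at least one landmark (from/to/at)"
            )
    creators = list(source.creators)
    if actor not in creators:
        creators.append(actor)
    clone = Character(
        id=store.fresh_id(),
        name=source.name,
        method=enhanced_method,
        unit=clone_unit,
        creators=creators,
        usage_count=1,
        illustrations=illustrations,
        structure_terms=list(source.structure_terms),
    )
    clone.history.append(
        HistoryEvent(
            store.next_timestamp(), actor, "created", {"cloned_from": source_id}
        )
    )
    if enhanced_method.to_dict() != source.method.to_dict():
        clone.history.append(
            HistoryEvent(store.next_timestamp(), actor, "enhanced", {})
        )
    if clone_unit != source.unit:
        clone.history.append(
            HistoryEvent(
                store.next_timestamp(),
                actor,
                "unit_changed",
                {"from": source.unit, "to": clone_unit},
            )
        )
    store.characters[clone.id] = clone
    source.history.append(
        HistoryEvent(
            store.next_timestamp(), actor, "cloned_from", {"clone": clone.id}
        )
    )
    ontology_store.add_equivalence(source_id, clone.id, store)
    return clone


def render_character(character_id: str, store: OntologyStore) -> dict:
    """Full display record for a character: name, marked-up method, unit,
    creators, usage, history and illustration references."""
    character = store.get_character(character_id)
    report = semantic_check(character.method, store)
    return {
        "id": character.id,
        "name": character.name.text(),
        "method": {
            name: {"text": text, "words": report.fields[name]}
            for name, text in character.method.field_texts().items()
        },
        "method_text": character.method.display_text(),
        "unit": character.unit,
        "creators": list(character.creators),
        "usage_count": character.usage_count,
        "status": character.status,
        "history": [e.to_dict() for e in character.history],
        "illustrations": list(character.illustrations),
        "equivalent_to": sorted(
            ontology_store.equivalence_class(character.id, store) - {character.id}
        ),
    }


def deprecate_character(character_id: str, store: OntologyStore) -> Character:
    """Mark a character deprecated; it keeps its id, axioms and history."""
    character = store.get_character(character_id)
    if character.status == DEPRECATED:
        raise ValidationError(f"character {character_id} is already deprecated")
    character.status = DEPRECATED
    store.log_event("deprecated", entity=character_id)
    return character
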