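"""Search saved characters by name phrase, ranked for reuse.

Matching is token containment: a character matches when every content
token of the query (case-folded, stopwords dropped) occurs among the
tokens of its name.  Hits are ordered by usage count descending — the
most-reused definition first — then name, then id, so identical
(query, store) pairs always give identical results.  Deprecated
characters never appear in results but stay retrievable by id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from measurement_recorder import config
from measurement_recorder.ontology_store import ACTIVE, OntologyStore

NO_DEFINITION = "(no definition)"
_PREVIEW_LIMIT = 80


@dataclass(frozen=True)
class SearchHit:
    """One search result row: enough to decide whether to reuse."""

    character_id: str
    name: str
    creators: tuple
    usage_count: int
    preview: str


def _content_tokens(text: str, stopwords) -> set:
    stopset = {w.casefold() for w in stopwords}
    return {t for t in text.casefold().split() if t and t not in stopset}


def search_characters(
    query: str,
    store: OntologyStore,
    stopwords: Iterable[str] = config.STOPWORDS,
) -> list:
    """Ranked reuse candidates for a name query.

    An empty result signals the caller to offer creating a new character.
    """
    wanted = _content_tokens(query, stopwords)
    hits = []
    for character in store.characters.values():
        if character.status != ACTIVE:
            continue
        name_tokens = set(character.name.tokens())
        if wanted <= name_tokens:
            hits.append(
                SearchHit(
                    character_id=character.id,
                    name=character.name.text(),
                    creators=tuple(character.creators),
                    usage_count=character.usage_count,
                    preview=preview(character.id, store),
                )
            )
    hits.sort(key=lambda h: (-h.usage_count, h.name, h.character_id))
    return hits


def preview(character_id: str, store: OntologyStore) -> str:
    """Tooltip-style preview: verbal method text, else the first
    illustration reference, else an explicit no-definition marker."""
    character = store.get_character(character_id)
    text = character.method.display_text()
    if text:
        if len(text) > _PREVIEW_LIMIT:
            text = text[: _PREVIEW_LIMIT - 1] + "…"
        return text
    if character.illustrations:
        return f"[illustration] {character.illustrations[0]}"
    return NO_DEFINITION
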