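"""Shared fixtures: small hand-built stores and seeded random stores."""

from __future__ import annotations

import random

import pytest

from measurement_recorder import config
from measurement_recorder.character_model import (
    MethodDefinition,
    clone_and_enhance,
    create_character,
    use_this,
)
from measurement_recorder.fixtures import FixtureSpec, make_fixture
from measurement_recorder.ontology_store import (
    ACTIVE,
    OntologyStore,
    add_equivalence,
    add_term,
    deprecate_term,
    new_store,
)


@pytest.fixture
def store() -> OntologyStore:
    """Minimal store with a handful of sedge structure terms."""
    s = new_store()
    for label in ["perigynium", "beak", "leaf", "inflorescence", "scale",
                  "apex", "insertion", "lowest", "tip", "base"]:
        add_term(label, f"def of {label}", f"sentence with {label}",
                 "Carex synthetica", "tester", s)
    return s


@pytest.fixture
def shared_store() -> OntologyStore:
    """The shared-profile study fixture (seed 7)."""
    return make_fixture(FixtureSpec(seed=7, profile="shared"))[0]


def brute_force_component(entity_id, pairs):
    """Independent BFS over the axiom pairs (no graph library)."""
    seen = {entity_id}
    frontier = {entity_id}
    while frontier:
        grown = set()
        for a, b in pairs:
            for x, y in ((a, b), (b, a)):
                if x in frontier and y not in seen:
                    grown.add(y)
        seen |= grown
        frontier = grown
    return seen


def build_random_store(seed: int, n_ops: int = 30) -> OntologyStore:
    """Grow a store through a seeded random operation sequence.

    Mixes term additions, deprecations, character creation, verbatim
    reuse, clone-and-enhance and explicit equivalence axioms, so that
    structural invariants are exercised on non-trivial shapes.
    """
    rng = random.Random(seed)
    s = new_store()
    label_counter = 0
    for _ in range(n_ops):
        op = rng.randrange(6)
        active_terms = [
            t for t in s.terms.values()
            if t.status == ACTIVE
            and config.numeric_suffix(t.id) >= config.FIRST_FREE_NUMERIC_ID
        ]
        active_chars = [c for c in s.characters.values() if c.status == ACTIVE]
        if op == 0 or not active_terms:
            label_counter += 1
            add_term(f"struct{label_counter:03d}", "synthetic", "", "",
                     f"user{rng.randrange(5)}", s)
        elif op == 1 and len(active_terms) > 3:
            deprecate_term(rng.choice(active_terms).id, s)
        elif op == 2:
            term = rng.choice(active_terms)
            quality = rng.choice(["length", "width", "depth"])
            create_character(
                f"{quality} of {term.label}",
                MethodDefinition(at=term.label),
                rng.choice(["mm", "cm"]),
                f"user{rng.randrange(5)}",
                s,
                force=True,
            )
        elif op == 3 and active_chars:
            use_this(rng.choice(active_chars).id, f"user{rng.randrange(5)}", s)
        elif op == 4 and active_chars:
            source = rng.choice(active_chars)
            if source.method.has_landmarks():
                try:
                    clone_and_enhance(
                        source.id, source.method, f"user{rng.randrange(5)}", s
                    )
                except Exception:
                    pass  # method words may have been deprecated since
        elif op == 5:
            entities = list(s.terms) + list(s.characters)
            a, b = rng.choice(entities), rng.choice(entities)
            if a != b:
                add_equivalence(a, b, s)
    return s
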