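"""Shared configuration: stopwords, unit vocabulary, ID scheme.

Everything here is a plain module-level constant so downstream code can
import and, where documented, override per call.  The stopword list is
versioned: analysis outputs record which list produced them.
"""

from __future__ import annotations

# Function words ignored when classifying method-definition words against
# the ontology and when tokenising character names for search.
STOPWORDS: frozenset[str] = frozenset(
    {"of", "a", "an", "the", "to", "from", "at", "and", "or", "between"}
)
STOPWORDS_VERSION = "1"

# Seeded measurement-unit vocabulary; extend by passing extra units to the
# validators that take a `units` argument.
UNITS: frozenset[str] = frozenset({"mm", "cm", "m", "µm", "count", "ratio", "degree"})

# Units whose measured values cannot be negative (lengths and counts).
NONNEGATIVE_UNITS: frozenset[str] = frozenset({"mm", "cm", "m", "µm", "count"})

# Permanent-identifier scheme: OBO-style prefix + zero-padded counter.
ID_PREFIX = "CAREX"
ID_PAD = 7

# Reserved low identifiers for the three seeded root classes.
ROOT_ANATOMIC_STRUCTURE = f"{ID_PREFIX}:{1:0{ID_PAD}d}"
ROOT_PERCEIVED_QUALITY = f"{ID_PREFIX}:{2:0{ID_PAD}d}"
ROOT_NEW_ADDITIONS = f"{ID_PREFIX}:{3:0{ID_PAD}d}"
FIRST_FREE_NUMERIC_ID = 10

# External semantic anchors, stored as annotation strings only (never
# resolved remotely): the anatomic-structure root is declared equivalent to
# the UBERON anatomical entity, the perceived-quality root a subclass of
# the PATO quality.
ANCHOR_ANATOMIC_EQUIVALENT = "UBERON:0001062"  # anatomical entity
ANCHOR_QUALITY_PARENT = "PATO:0000001"  # quality

SCHEMA_VERSION = 2


def format_id(numeric: int) -> str:
    """Render a numeric suffix as a permanent identifier string."""
    return f"{ID_PREFIX}:{numeric:0{ID_PAD}d}"


def numeric_suffix(identifier: str) -> int:
    """Inverse of :func:`format_id`; raises ``ValueError`` on foreign ids."""
    prefix, _, suffix = identifier.partition(":")
    if prefix != ID_PREFIX or not suffix.isdigit():
        raise ValueError(f"not a {ID_PREFIX} identifier: {identifier!r}")
    return int(suffix)
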