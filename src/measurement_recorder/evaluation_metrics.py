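"""Evaluation statistics for measurement-definition usability studies.

Covers four families of computations used to score such studies:

* **definition convergence** — normalise the words participants wrote in
  the five method fields (lowercase, strip punctuation and numbers, drop
  stopwords), then count unique words and unique definitions per session
  and the percentage reduction between sessions;
* **Likert scoring** — mean, sample standard deviation and the share of
  respondents who agree (score 4) or strongly agree (score 5);
* **weighted influence strength** — a 3/2/1/0-weighted sum over counts of
  strong / some / weak / no influence responses;
* **error accounting** — error rates over reviewed characters, with
  errors categorised as wrong definition and/or wrong unit so that
  unit-only errors (a fixable interface issue) can be discounted.

All printed percentages round half away from zero (87.5 → 88).
"""

from __future__ import annotations

import math
import re
import statistics
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from measurement_recorder import config
from measurement_recorder.errors import ValidationError

FIELD_NAMES = ("from", "to", "include", "exclude", "at")

_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_NUMBER_RE = re.compile(r"^\d+$")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (87.5 → 88)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DefinitionRecord:
    """One participant's definition of one task character in one session
    (``paper`` = written on paper beforehand, ``machine`` = recorded in
    the tool), as the five field texts."""

    participant: str
    task: str
    session: str  # "paper" | "machine"
    from_text: str = ""
    to_text: str = ""
    include_text: str = ""
    exclude_text: str = ""
    at_text: str = ""

    def field_texts(self) -> tuple:
        return (
            self.from_text,
            self.to_text,
            self.include_text,
            self.exclude_text,
            self.at_text,
        )


@dataclass(frozen=True)
class LikertResponse:
    """One five-point answer: 5 = strongly agree … 1 = strongly disagree."""

    question: str
    value: int

    def __post_init__(self):
        if not 1 <= self.value <= 5:
            raise ValidationError(f"Likert value must be 1..5, got {self.value}")


@dataclass(frozen=True)
class InfluenceCounts:
    """Respondent counts per influence level for one reuse-decision factor."""

    strong: int
    some: int
    weak: int
    none: int

    WEIGHTS = (3, 2, 1, 0)

    def __post_init__(self):
        if min(self.strong, self.some, self.weak, self.none) < 0:
            raise ValidationError("influence counts must be non-negative")


@dataclass(frozen=True)
class ErrorRecord:
    """Review outcome for one character created by one participant.

    ``method`` is how the character came about (reuse verbatim, clone and
    enhance, or create new); an ``error`` outcome carries one or both of
    the categories ``wrong_definition`` / ``wrong_unit``.
    """

    participant: str
    task: str
    method: str  # use_this | clone_enhance | create_new
    outcome: str  # correct | error
    categories: frozenset = frozenset()

    def __post_init__(self):
        bad = set(self.categories) - {"wrong_definition", "wrong_unit"}
        if bad:
            raise ValidationError(f"unknown error categories: {sorted(bad)}")
        if (self.outcome == "error") != bool(self.categories):
            raise ValidationError(
                "outcome must be 'error' exactly when categories are non-empty"
            )


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------


def normalize_words(text: str, stopwords: Iterable[str] = config.STOPWORDS) -> list:
    """Normalise free text to an ordered list of content words.

    Lowercases, strips punctuation, splits on whitespace, removes
    pure-number tokens and stopwords.  Idempotent and order-preserving.
    """
    stopset = {w.casefold() for w in stopwords}
    cleaned = _PUNCT_RE.sub(" ", text.lower())
    return [
        token
        for token in cleaned.split()
        if token not in stopset and not _NUMBER_RE.match(token)
    ]


def _session_records(records, session):
    return [r for r in records if r.session == session]


def unique_word_count(
    records: Iterable[DefinitionRecord],
    session: str,
    stopwords: Iterable[str] = config.STOPWORDS,
) -> int:
    """Distinct normalised words across all five fields of a session."""
    words = set()
    for record in _session_records(records, session):
        for text in record.field_texts():
            words.update(normalize_words(text, stopwords))
    return len(words)


def definition_key(
    record: DefinitionRecord, stopwords: Iterable[str] = config.STOPWORDS
) -> tuple:
    """Normalised identity of a definition: the 5-tuple of space-joined
    normalised field word lists."""
    return tuple(
        " ".join(normalize_words(text, stopwords)) for text in record.field_texts()
    )


def unique_definition_count(
    records: Iterable[DefinitionRecord],
    session: str,
    stopwords: Iterable[str] = config.STOPWORDS,
    per_field: bool = False,
) -> int:
    """Distinct definitions in a session after normalisation.

    By default a definition is the whole 5-field tuple; ``per_field``
    instead counts distinct non-empty single-field word sequences.
    """
    selected = _session_records(records, session)
    if per_field:
        keys = {
            (name, joined)
            for record in selected
            for name, joined in zip(FIELD_NAMES, definition_key(record, stopwords))
            if joined
        }
    else:
        keys = {definition_key(record, stopwords) for record in selected}
    return len(keys)


def reduction_percent(before: int, after: int) -> int:
    """Percentage reduction from ``before`` to ``after``, as the studies
    print it: ``round_half_away((before - after) / before * 100)``."""
    if before <= 0:
        raise ValidationError("reduction_percent needs before > 0")
    return round_half_away((before - after) / before * 100)


# ---------------------------------------------------------------------------
# Survey scoring
# ---------------------------------------------------------------------------


def likert_stats(responses: Iterable[LikertResponse]) -> tuple:
    """(mean, sample sd, agree %) of a set of five-point responses.

    Agreement is the share of responses scoring 4 or 5, as an integer
    percent (half away from zero).  The sd uses the n−1 denominator and
    is ``nan`` for a single response.
    """
    values = [r.value for r in responses]
    if not values:
        raise ValidationError("likert_stats needs at least one response")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else float("nan")
    agree = round_half_away(
        sum(1 for v in values if v >= 4) / len(values) * 100
    )
    return mean, sd, agree


def influence_strength(counts: InfluenceCounts) -> float:
    """Weighted sum 3·strong + 2·some + 1·weak + 0·none."""
    levels = (counts.strong, counts.some, counts.weak, counts.none)
    return float(sum(w * n for w, n in zip(InfluenceCounts.WEIGHTS, levels)))


# ---------------------------------------------------------------------------
# Error accounting
# ---------------------------------------------------------------------------


def error_rate(wrong: int, total: int) -> int:
    """Integer error percentage, half away from zero."""
    if total <= 0:
        raise ValidationError("error_rate needs total > 0")
    return round_half_away(wrong / total * 100)


def aggregate_errors(
    records: Iterable[ErrorRecord],
    where: Optional[Callable[[ErrorRecord], bool]] = None,
    exclude_unit_only: bool = False,
) -> int:
    """Count error records within an optional filter.

    With ``exclude_unit_only``, records whose only category is
    ``wrong_unit`` are discounted — the wrong-unit slip was a fixable
    interface issue rather than a knowledge error.
    """
    count = 0
    for record in records:
        if record.outcome != "error":
            continue
        if where is not None and not where(record):
            continue
        if exclude_unit_only and set(record.categories) == {"wrong_unit"}:
            continue
        count += 1
    return count


# ---------------------------------------------------------------------------
# CSV I/O for the evaluation inputs
# ---------------------------------------------------------------------------


def read_definitions_csv(path) -> list:
    """definitions CSV: participant, task, session, from, to, include,
    exclude, at."""
    import pandas as pd

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    required = ["participant", "task", "session", *FIELD_NAMES]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"definitions CSV missing columns: {missing}")
    return [
        DefinitionRecord(
            participant=row["participant"],
            task=row["task"],
            session=row["session"],
            from_text=row["from"],
            to_text=row["to"],
            include_text=row["include"],
            exclude_text=row["exclude"],
            at_text=row["at"],
        )
        for _, row in frame.iterrows()
    ]


def read_responses_csv(path) -> list:
    """responses CSV: participant, question, value (1..5)."""
    import pandas as pd

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in ("participant", "question", "value") if c not in frame.columns]
    if missing:
        raise ValidationError(f"responses CSV missing columns: {missing}")
    return [
        LikertResponse(question=row["question"], value=int(row["value"]))
        for _, row in frame.iterrows()
    ]


_CATEGORY_CODES = {
    "": frozenset(),
    "d": frozenset({"wrong_definition"}),
    "u": frozenset({"wrong_unit"}),
    "du": frozenset({"wrong_definition", "wrong_unit"}),
    "ud": frozenset({"wrong_definition", "wrong_unit"}),
}


def read_errors_csv(path) -> list:
    """errors CSV: participant, task, method, outcome, categories.

    Categories use the compact codes ``d`` (wrong definition), ``u``
    (wrong unit) and ``du`` (both); empty for correct outcomes.
    """
    import pandas as pd

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    required = ("participant", "task", "method", "outcome", "categories")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"errors CSV missing columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        code = row["categories"].strip().lower()
        if code not in _CATEGORY_CODES:
            raise ValidationError(
                f"errors CSV row {i}: unknown category code {code!r}"
            )
        records.append(
            ErrorRecord(
                participant=row["participant"],
                task=row["task"],
                method=row["method"],
                outcome=row["outcome"],
                categories=_CATEGORY_CODES[code],
            )
        )
    return records


def convergence_report(
    records: Iterable[DefinitionRecord],
    stopwords: Iterable[str] = config.STOPWORDS,
) -> dict:
    """Unique-word and unique-definition counts per session plus the
    paper→machine reduction percentages.  Records the stopword-list
    version that produced it."""
    records = list(records)
    words = {
        session: unique_word_count(records, session, stopwords)
        for session in ("paper", "machine")
    }
    defs = {
        session: unique_definition_count(records, session, stopwords)
        for session in ("paper", "machine")
    }
    return {
        "unique_words": words,
        "unique_definitions": defs,
        "word_reduction_percent": reduction_percent(words["paper"], words["machine"]),
        "definition_reduction_percent": reduction_percent(
            defs["paper"], defs["machine"]
        ),
        "stopwords_version": config.STOPWORDS_VERSION,
    }
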