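"""Exception hierarchy.

``ValidationError`` covers precondition failures a user can fix (exit code
2 in the CLI); ``StoreIOError`` covers unreadable or malformed files (exit
code 3).  Subclasses carry structured context so callers can steer users
toward reuse instead of duplication.
"""

from __future__ import annotations


class MeasurementRecorderError(Exception):
    """Base class for all package errors."""


class ValidationError(MeasurementRecorderError):
    """A precondition on user input failed."""


class DuplicateLabelError(ValidationError):
    """An active entity with the same (case-folded) label already exists.

    Signals that the caller should reuse the existing entity rather than
    create a duplicate; ``existing_id`` points at it.
    """

    def __init__(self, label: str, existing_id: str):
        self.label = label
        self.existing_id = existing_id
        super().__init__(
            f"an active entry labelled {label!r} already exists as {existing_id}; "
            f"reuse it instead of creating a duplicate"
        )


class DuplicateNameError(ValidationError):
    """An active character with the same name exists; suggests reuse."""

    def __init__(self, name_text: str, suggestions):
        self.name_text = name_text
        self.suggestions = list(suggestions)
        detail = "; ".join(
            f"{s.character_id} by {', '.join(s.creators)} (used {s.usage_count}x)"
            for s in self.suggestions
        )
        super().__init__(
            f"an active character named {name_text!r} already exists — "
            f"consider reusing: {detail}"
        )


class GrammarError(ValidationError):
    """A character name does not follow '<quality> of/between <structure>'."""


class UnknownTermsError(ValidationError):
    """A method definition contains words not yet in the ontology."""

    def __init__(self, report):
        self.report = report
        words = sorted(report.new_words())
        super().__init__(
            "method uses terms not in the ontology; define them first: "
            + ", ".join(words)
        )


class CycleError(ValidationError):
    """A reparenting would make the subclass graph cyclic."""


class StoreIOError(MeasurementRecorderError):
    """A store or table file could not be read or parsed."""
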