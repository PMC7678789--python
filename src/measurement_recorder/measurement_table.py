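"""The spreadsheet surface: specimens × characters measurement grid.

The defining contract of this module is that a value can only be recorded
against a character that has been defined and saved in the ontology —
there is no such thing as an ad-hoc column.  Each column carries the unit
of its character; cells are single finite numbers (ranges and qualifiers
are out of scope).  Cell overwrites are allowed and keep per-cell history.

Export is CSV in two shapes: *wide* (row = specimen, column = character
id) for spreadsheet interoperability, and *long* (specimen, character_id,
value, unit, actor, timestamp) for analysis.  Missing values export as
empty fields, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from measurement_recorder import config
from measurement_recorder.errors import StoreIOError, ValidationError
from measurement_recorder.ontology_store import ACTIVE, OntologyStore


@dataclass
class MeasurementTable:
    """Ordered specimens × ordered character columns, with provenance."""

    specimens: list = field(default_factory=list)
    columns: list = field(default_factory=list)  # character ids
    units: dict = field(default_factory=dict)  # character id -> unit
    cells: dict = field(default_factory=dict)  # (specimen, character id) -> float
    provenance: dict = field(default_factory=dict)  # cell -> list of entries

    def value(self, specimen: str, character_id: str) -> Optional[float]:
        return self.cells.get((specimen, character_id))


def add_column(
    table: MeasurementTable, character_id: str, store: OntologyStore
) -> MeasurementTable:
    """Append a column for a saved, active character; duplicates refused."""
    character = store.get_character(character_id)  # raises on unsaved ids
    if character.status != ACTIVE:
        raise ValidationError(
            f"character {character_id} is deprecated and cannot take new columns"
        )
    if character_id in table.columns:
        raise ValidationError(f"column {character_id} is already in the table")
    table.columns.append(character_id)
    table.units[character_id] = character.unit
    return table


def record_value(
    table: MeasurementTable,
    specimen: str,
    character_id: str,
    value,
    actor: str = "",
    timestamp: str = "",
) -> MeasurementTable:
    """Set one cell; the value must be a finite number, non-negative for
    length-like units.  Overwriting keeps the previous entries in the
    cell's provenance history."""
    if character_id not in table.columns:
        raise ValidationError(
            f"no column for {character_id}; add the (saved) character first"
        )
    try:
        number = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"measurement value {value!r} is not numeric") from None
    if not math.isfinite(number):
        raise ValidationError(f"measurement value {value!r} is not finite")
    unit = table.units[character_id]
    if number < 0 and unit in config.NONNEGATIVE_UNITS:
        raise ValidationError(
            f"negative value {number} is invalid for unit {unit!r}"
        )
    if specimen not in table.specimens:
        table.specimens.append(specimen)
    key = (specimen, character_id)
    table.cells[key] = number
    table.provenance.setdefault(key, []).append(
        {"actor": actor, "timestamp": timestamp, "value": number}
    )
    return table


def _wide_frame(table: MeasurementTable) -> pd.DataFrame:
    data = {
        col: [table.value(s, col) for s in table.specimens] for col in table.columns
    }
    frame = pd.DataFrame(data, index=pd.Index(table.specimens, name="specimen"))
    return frame


def export_csv(table: MeasurementTable, path, fmt: str = "wide") -> None:
    """Write the table as CSV (UTF-8, comma, ``.`` decimal, header row)."""
    path = Path(path)
    if fmt == "wide":
        _wide_frame(table).to_csv(path, encoding="utf-8")
    elif fmt == "long":
        rows = []
        for specimen in table.specimens:
            for col in table.columns:
                value = table.value(specimen, col)
                if value is None:
                    continue
                latest = table.provenance.get((specimen, col), [{}])[-1]
                rows.append(
                    {
                        "specimen": specimen,
                        "character_id": col,
                        "value": value,
                        "unit": table.units[col],
                        "actor": latest.get("actor", ""),
                        "timestamp": latest.get("timestamp", ""),
                    }
                )
        pd.DataFrame(
            rows,
            columns=["specimen", "character_id", "value", "unit", "actor", "timestamp"],
        ).to_csv(path, index=False, encoding="utf-8")
    else:
        raise ValidationError(f"unknown export format {fmt!r}; use 'wide' or 'long'")


def import_csv(path, store: OntologyStore) -> MeasurementTable:
    """Read a wide CSV back into a table.

    Every column header must resolve to a saved character in the store —
    unresolvable headers are reported together.  Round-trips values:
    ``import(export(t))`` equals ``t`` on (specimen, character, value).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except OSError as exc:
        raise StoreIOError(f"cannot read table file {path}: {exc}") from None
    except pd.errors.ParserError as exc:
        raise StoreIOError(f"malformed table file {path}: {exc}") from None
    if frame.empty and len(frame.columns) == 0:
        raise StoreIOError(f"table file {path} has no header row")
    if frame.columns[0] != "specimen":
        raise StoreIOError(
            f"table file {path}: first column must be 'specimen', "
            f"got {frame.columns[0]!r}"
        )
    headers = list(frame.columns[1:])
    bad = [h for h in headers if h not in store.characters]
    if bad:
        raise ValidationError(
            "column headers do not resolve to saved characters: " + ", ".join(bad)
        )
    table = MeasurementTable()
    for header in headers:
        add_column(table, header, store)
    for _, row in frame.iterrows():
        specimen = row["specimen"]
        if specimen not in table.specimens:
            table.specimens.append(specimen)
        for header in headers:
            raw = row[header].strip()
            if raw == "":
                continue
            record_value(table, specimen, header, raw)
    return table


def as_multiset(table: MeasurementTable) -> list:
    """Sorted (specimen, character, value) triples — the table's content
    irrespective of layout; wide and long exports agree on it."""
    return sorted((s, c, v) for (s, c), v in table.cells.items())
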