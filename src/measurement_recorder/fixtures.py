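"""Seeded fixture generation emulating the usability-study setup.

Two profiles mirror the two study configurations:

* ``individual`` — everyday measuring tasks (leaf, pupils, screen); the
  ontology carries terms and illustrations of varying usefulness per task
  and a single preloaded character.
* ``shared`` — technical *Carex* measuring tasks; the ontology carries a
  home-grown set of sedge structure terms and six preloaded characters
  created by two botanist personas ("Bruce Ford" and the made-up
  "Yin Ming"), differing in usage count (one used 20 times vs. a few),
  illustrations (0–2, some deliberate distractors) and task match.  The
  distractor trio for the fourth task includes two illustration-only
  definitions and one text definition measured from the end of the
  perigynium wings.

`make_experiment_tables` regenerates evaluation inputs in the shape of
the study's review tables: per-character error records whose marginal
counts equal the published per-task/method/group cells, paper-session
review outcomes, synthetic definition records exhibiting paper→machine
convergence, and a small Likert response file.  Everything is a pure
function of ``(seed, profile)``: the same spec yields byte-identical
files.

All taxon names and participant identities are synthetic placeholders;
no real nomenclatural claims are made.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from measurement_recorder.character_model import (
    MethodDefinition,
    create_character,
    use_this,
)
from measurement_recorder.errors import ValidationError
from measurement_recorder.measurement_table import MeasurementTable, add_column
from measurement_recorder.ontology_store import OntologyStore, add_term, new_store


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated fixture; same spec → identical bytes."""

    seed: int
    profile: str = "shared"  # "individual" | "shared"
    n_structure_terms: int = 0  # extra synthetic structure terms
    n_characters: int = 0  # extra synthetic filler characters


# Core sedge-structure vocabulary used by the shared-profile method
# definitions (word forms as typed, since the semantic check does not stem).
_SHARED_TERMS = [
    "perigynium", "beak", "wing", "wings", "inflorescence", "scale", "leaf",
    "culm", "spike", "achene", "apex", "summit", "base", "tip", "insertion",
    "teeth", "lowest", "widest", "point", "end", "style", "stigma", "margin",
]

_INDIVIDUAL_TERMS = [
    "leaf", "blade", "base", "tip", "petiole", "margin", "pupil", "pupils",
    "eye", "eyes", "center", "inner", "outer", "corner", "widest", "point",
]

_SYLLABLES = ["lam", "stip", "glum", "ceph", "rhiz", "phyl", "troch", "carp"]
_SUFFIXES = ["ule", "ella", "idium", "ina", "oid", "arium"]


def _bump_usage(store, character, target, actors, rng):
    """Raise a preloaded character's usage count via recorded uses."""
    for _ in range(target - 1):
        use_this(character.id, rng.choice(actors), store)


def _shared_store(spec: FixtureSpec, rng: random.Random) -> OntologyStore:
    store = new_store()
    for label in _SHARED_TERMS:
        add_term(label, f"{label} of a sedge (synthetic definition)",
                 f"the {label} is distinct in this taxon",
                 "Carex synthetica", "Bruce Ford", store)
    actors = [f"setup{j:02d}" for j in range(1, 6)]

    # Task 1 preload: illustration-only, does not match the task.
    c1 = create_character(
        "length of culm", MethodDefinition(), "cm", "Yin Ming", store,
        illustrations=["culm_full_length.png"],
    )
    _bump_usage(store, c1, 3, actors, rng)

    # Task 2 preload: text definition matching the task, heavily used.
    c2 = create_character(
        "length of inflorescence",
        MethodDefinition(
            from_landmark="insertion of lowest scale",
            to_landmark="apex of inflorescence",
        ),
        "mm", "Bruce Ford", store,
        illustrations=["inflorescence_length.png"],
    )
    _bump_usage(store, c2, 20, actors, rng)

    # Task 3 preload: same definition style but the wrong unit (cm, where
    # the task sheet asks for mm).
    c3 = create_character(
        "length of inflorescence",
        MethodDefinition(
            from_landmark="insertion of lowest scale",
            to_landmark="apex of inflorescence",
        ),
        "cm", "Yin Ming", store, force=True,
    )
    _bump_usage(store, c3, 2, actors, rng)

    # Task 4 distractors: (a) and (b) illustration-only, (c) text-defined.
    c4a = create_character(
        "length of perigynium beak", MethodDefinition(), "mm", "Yin Ming",
        store, illustrations=["perigynium_beak_bend.png"],
    )
    _bump_usage(store, c4a, 2, actors, rng)
    c4b = create_character(
        "length of perigynium beak", MethodDefinition(), "mm", "Bruce Ford",
        store, force=True,
        illustrations=["perigynium_beak_style.png", "perigynium_whole.png"],
    )
    _bump_usage(store, c4b, 4, actors, rng)
    c4c = create_character(
        "length of winged perigynium beak",
        MethodDefinition(
            from_landmark="end of perigynium wings",
            to_landmark="summit of perigynium",
            include=["perigynium beak teeth"],
        ),
        "mm", "Bruce Ford", store,
    )
    _bump_usage(store, c4c, 5, actors, rng)
    return store


def _individual_store(spec: FixtureSpec, rng: random.Random) -> OntologyStore:
    store = new_store()
    for label in _INDIVIDUAL_TERMS:
        add_term(label, f"{label} (synthetic definition)",
                 f"measure to the {label}", "everyday object", "Yin Ming", store)
    # One preloaded character: a matching illustration plus two distractors.
    create_character(
        "length of leaf",
        MethodDefinition(from_landmark="base of leaf blade",
                         to_landmark="tip of leaf blade"),
        "mm", "Bruce Ford", store,
        illustrations=["leaf_length_match.png", "leaf_width_distractor.png"],
    )
    return store


def _synthetic_label(i: int, rng: random.Random) -> str:
    return rng.choice(_SYLLABLES) + rng.choice(_SUFFIXES) + f"{i:02d}"


def make_fixture(spec: FixtureSpec):
    """Build the seeded ontology store and an empty measurement-table
    skeleton whose columns are the preloaded characters."""
    if spec.profile not in ("individual", "shared"):
        raise ValidationError(f"unknown fixture profile {spec.profile!r}")
    rng = random.Random(spec.seed)
    store = (
        _shared_store(spec, rng)
        if spec.profile == "shared"
        else _individual_store(spec, rng)
    )
    preloaded = list(store.characters)

    extra_labels = []
    for i in range(spec.n_structure_terms):
        label = _synthetic_label(i, rng)
        add_term(label, "synthetic filler structure", "", "Carex synthetica",
                 "Yin Ming", store)
        extra_labels.append(label)
    qualities = ["width", "length", "diameter"]
    for i in range(spec.n_characters):
        label = extra_labels[i % len(extra_labels)] if extra_labels else "leaf"
        quality = qualities[i % len(qualities)]
        name = f"{quality} of {label}"
        create_character(
            name,
            MethodDefinition(at=f"widest point {label}"),
            rng.choice(["mm", "cm"]),
            rng.choice(["Bruce Ford", "Yin Ming"]),
            store,
            force=True,
        )

    table = MeasurementTable()
    for character_id in preloaded:
        add_column(table, character_id, store)
    return store, table


# ---------------------------------------------------------------------------
# Evaluation-input tables
# ---------------------------------------------------------------------------

# Machine-session review cells: (task, method) -> per-group lists of
# (n_correct, {category code: n_errors}).  Category codes: d = wrong
# definition, u = wrong unit, du = both.
_MACHINE_CELLS = {
    "ns": {
        ("task1", "use_this"): (0, {}),
        ("task1", "clone_enhance"): (7, {}),
        ("task1", "create_new"): (6, {}),
        ("task2", "use_this"): (7, {}),
        ("task2", "clone_enhance"): (2, {"d": 1}),
        ("task2", "create_new"): (1, {"d": 2}),
        ("task3", "use_this"): (0, {"u": 3}),
        ("task3", "clone_enhance"): (3, {"d": 3, "u": 1, "du": 2}),
        ("task3", "create_new"): (0, {"d": 1}),
        ("task4", "use_this"): (0, {"d": 5}),
        ("task4", "clone_enhance"): (0, {"d": 2}),
        ("task4", "create_new"): (3, {"d": 2}),
    },
    "es": {
        ("task1", "use_this"): (0, {"d": 2}),
        ("task1", "clone_enhance"): (11, {}),
        ("task1", "create_new"): (6, {}),
        ("task2", "use_this"): (13, {}),
        ("task2", "clone_enhance"): (4, {"d": 1}),
        ("task2", "create_new"): (1, {}),
        ("task3", "use_this"): (0, {"u": 7}),
        ("task3", "clone_enhance"): (6, {"u": 2}),
        ("task3", "create_new"): (4, {}),
        ("task4", "use_this"): (0, {"d": 9}),
        ("task4", "clone_enhance"): (2, {"d": 4}),
        ("task4", "create_new"): (3, {"d": 1}),
    },
}

# Paper-session review: per-task wrong-character counts per group
# (group size, total reviewed characters, wrong count per task).
_PAPER_CELLS = {
    "ns": {"n": 13, "wrong": {"task1": 5, "task2": 7, "task3": 7, "task4": 10}},
    "es": {"n": 19, "wrong": {"task1": 4, "task2": 5, "task3": 8, "task4": 8}},
}

_GROUP_SIZES = {"ns": 13, "es": 19}

# Definition-convergence vocabulary: canonical machine-session wordings
# (participants converge on the preloaded/shared definitions) and wider
# paper-session variant pools per task.
_TASK_CANON = {
    "task1": ("base of culm", "apex of culm", "", "", ""),
    "task2": ("insertion of lowest scale", "apex of inflorescence", "", "", ""),
    "task3": ("insertion of lowest scale", "apex of inflorescence", "", "", ""),
    "task4": ("end of perigynium wings", "summit of perigynium",
              "perigynium beak teeth", "", ""),
}

_PAPER_VARIANTS = {
    "task1": ["bottom of the stem", "where the stalk meets the root",
              "ground level of the culm", "start of the flowering stem"],
    "task2": ["lowest bract on the cluster", "first scale near the stalk",
              "beginning of the flower head", "where the lowest spike starts"],
    "task3": ["bottom scale insertion area", "under the lowest flower scale",
              "start of the seed head", "lowest point of the cluster"],
    "task4": ["bend of the beak body", "edge of the winged part",
              "where the teeth begin", "margin of the perigynium wing"],
}


def _participants(group: str) -> list:
    return [f"{group}{i:02d}" for i in range(1, _GROUP_SIZES[group] + 1)]


def _machine_error_rows(rng: random.Random) -> list:
    rows = []
    for group, cells in _MACHINE_CELLS.items():
        for task in ("task1", "task2", "task3", "task4"):
            entries = []
            for method in ("use_this", "clone_enhance", "create_new"):
                n_correct, errors = cells[(task, method)]
                entries += [(method, "correct", "")] * n_correct
                for code, n in errors.items():
                    entries += [(method, "error", code)] * n
            people = _participants(group)
            rng.shuffle(people)
            for participant, (method, outcome, code) in zip(people, entries):
                rows.append(
                    {
                        "participant": participant,
                        "task": task,
                        "method": method,
                        "outcome": outcome,
                        "categories": code,
                    }
                )
    rows.sort(key=lambda r: (r["participant"], r["task"], r["method"]))
    return rows


def _paper_error_rows(rng: random.Random) -> list:
    rows = []
    for group, info in _PAPER_CELLS.items():
        people = _participants(group)
        for task, wrong in info["wrong"].items():
            flagged = rng.sample(people, wrong)
            for participant in people:
                rows.append(
                    {
                        "participant": participant,
                        "task": task,
                        "method": "paper",
                        "outcome": "error" if participant in flagged else "correct",
                        "categories": "d" if participant in flagged else "",
                    }
                )
    rows.sort(key=lambda r: (r["participant"], r["task"]))
    return rows


def _definition_rows(rng: random.Random) -> list:
    rows = []
    people = _participants("ns") + _participants("es")
    for task in ("task1", "task2", "task3", "task4"):
        canon = _TASK_CANON[task]
        variants = _PAPER_VARIANTS[task]
        for participant in people:
            # Paper session: idiosyncratic wording drawn from a wide pool.
            variant = rng.choice(variants)
            extra = rng.choice(variants)
            rows.append(
                {
                    "participant": participant,
                    "task": task,
                    "session": "paper",
                    "from": variant,
                    "to": canon[1] if rng.random() < 0.4 else extra,
                    "include": canon[2],
                    "exclude": "",
                    "at": "",
                }
            )
            # Machine session: most participants converge on the shared
            # definition; a few keep a personal variant.
            if rng.random() < 0.8:
                from_text = canon[0]
            else:
                from_text = rng.choice(variants)
            rows.append(
                {
                    "participant": participant,
                    "task": task,
                    "session": "machine",
                    "from": from_text,
                    "to": canon[1],
                    "include": canon[2],
                    "exclude": "",
                    "at": "",
                }
            )
    rows.sort(key=lambda r: (r["session"], r["participant"], r["task"]))
    return rows


def _response_rows(rng: random.Random) -> list:
    rows = []
    for participant in _participants("ns") + _participants("es"):
        for question in ("q1", "q2", "q3", "q4", "q5"):
            value = rng.choices([1, 2, 3, 4, 5], weights=[1, 2, 4, 8, 6])[0]
            rows.append(
                {"participant": participant, "question": question, "value": value}
            )
    return rows


def make_experiment_tables(spec: FixtureSpec, out_dir) -> dict:
    """Write the evaluation-input CSVs for the shared profile.

    Emits ``machine_errors.csv`` and ``paper_errors.csv`` (per-character
    review outcomes whose per-(group, task, method, category) counts equal
    the published review cells), ``definitions.csv`` (paper vs. machine
    session definition records) and ``responses.csv`` (Likert responses).
    Returns a name → path mapping.  Deterministic per seed.
    """
    if spec.profile != "shared":
        raise ValidationError(
            "experiment tables are defined for the shared profile only"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    outputs = {
        "machine_errors": (_machine_error_rows(rng),
                           ["participant", "task", "method", "outcome", "categories"]),
        "paper_errors": (_paper_error_rows(rng),
                         ["participant", "task", "method", "outcome", "categories"]),
        "definitions": (_definition_rows(rng),
                        ["participant", "task", "session", "from", "to",
                         "include", "exclude", "at"]),
        "responses": (_response_rows(rng), ["participant", "question", "value"]),
    }
    paths = {}
    for name, (rows, columns) in outputs.items():
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows, columns=columns).to_csv(
            path, index=False, encoding="utf-8", lineterminator="\n"
        )
        paths[name] = path
    return paths
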