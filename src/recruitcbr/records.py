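"""Data model and I/O for coded EHR events in long entity-attribute-value (EAV) form.

Clinical facts are held as one row per coded event. Four entities are
recognised — diagnoses (ICD-10), procedures (OPCS-4), prescriptions (BNF
codes) and laboratory tests (read codes) — though codes are treated as
opaque strings throughout. Events may arrive in a wide layout (one row per
person with a variable number of codes); :func:`widen_to_long` converts
them to long form. Persons without sufficient coded data are removed with
:func:`apply_inclusion_filter`.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENTITIES: tuple[str, ...] = ("diagnosis", "procedure", "prescription", "lab_test")

EVENT_COLUMNS: tuple[str, ...] = (
    "person_id",
    "entity",
    "code",
    "event_date",
    "value",
    "quantity",
)

LABEL_COLUMNS: tuple[str, ...] = ("person_id", "project_id", "recruited", "db_identified")


@dataclass(frozen=True)
class CodedEvent:
    """One coded clinical fact for one person.

    ``value`` (a numeric lab result) is only meaningful for lab tests and
    ``quantity`` (a dispensed amount) only for prescriptions; both are
    carried through I/O but never enter the similarity computation.
    """

    person_id: str
    entity: str
    code: str
    event_date: str | None = None
    value: float | None = None
    quantity: float | None = None

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise ValueError(
                f"unknown entity {self.entity!r}; expected one of {ENTITIES}"
            )
        if not self.code:
            raise ValueError("code must be a non-empty string")
        if self.value is not None and self.entity != "lab_test":
            raise ValueError("value is only permitted for lab_test events")
        if self.quantity is not None and self.entity != "prescription":
            raise ValueError("quantity is only permitted for prescription events")


@dataclass
class PersonRecord:
    """All coded events for one person, grouped by entity on demand."""

    person_id: str
    events: tuple[CodedEvent, ...] = ()

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        for ev in self.events:
            if ev.person_id != self.person_id:
                raise ValueError(
                    f"event person_id {ev.person_id!r} does not match "
                    f"record person_id {self.person_id!r}"
                )

    def code_counts(self, entity: str) -> Counter:
        """Occurrence count of each code of ``entity`` for this person."""
        _check_entity(entity)
        return Counter(ev.code for ev in self.events if ev.entity == entity)

    def codes(self, entity: str) -> frozenset[str]:
        """Distinct codes of ``entity`` carried by this person."""
        return frozenset(self.code_counts(entity))

    def entities_present(self) -> frozenset[str]:
        return frozenset(ev.entity for ev in self.events)


@dataclass
class CountVector:
    """Occurrence counts of an ordered code list for one person."""

    codes: tuple[str, ...]
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.codes = tuple(self.codes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.codes) != len(self.counts):
            raise ValueError("codes and counts must have the same length")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


def _check_entity(entity: str) -> None:
    if entity not in ENTITIES:
        raise ValueError(f"unknown entity {entity!r}; expected one of {ENTITIES}")


def widen_to_long(wide_rows: Iterable[Mapping]) -> list[CodedEvent]:
    """Explode wide rows (one person, several codes) into long EAV events.

    Each wide row is a mapping with keys ``person_id``, ``entity`` and
    ``codes`` (an iterable of code strings, possibly containing empty
    cells). One event is produced per non-empty code cell; within-row code
    order is preserved.
    """
    events: list[CodedEvent] = []
    for row in wide_rows:
        entity = row["entity"]
        _check_entity(entity)
        person_id = str(row["person_id"])
        for code in row["codes"]:
            if code is None:
                continue
            code = str(code).strip()
            if not code:
                continue
            events.append(CodedEvent(person_id=person_id, entity=entity, code=code))
    return events


def group_by_person(events: Iterable[CodedEvent]) -> list[PersonRecord]:
    """Bundle a flat event collection into one :class:`PersonRecord` per person."""
    by_person: dict[str, list[CodedEvent]] = {}
    for ev in events:
        by_person.setdefault(ev.person_id, []).append(ev)
    return [PersonRecord(pid, tuple(evs)) for pid, evs in by_person.items()]


def apply_inclusion_filter(persons, mode: str = "all_four") -> list[str]:
    """Return ids of persons with enough coded data to be analysed.

    ``mode='all_four'`` retains a person only if they have at least one
    event in every entity (the criterion applied to both participants and
    the registrant pool). ``mode='any'`` requires at least one event in at
    least one entity. Lab-test events with a missing code (an incomplete
    test description) do not count toward coverage.

    ``persons`` may be a collection of :class:`PersonRecord` or a long-form
    events DataFrame; ids are returned in first-appearance order.
    """
    if mode not in ("all_four", "any"):
        raise ValueError(f"mode must be 'all_four' or 'any', got {mode!r}")

    if isinstance(persons, pd.DataFrame):
        df = persons
        ok = df["code"].notna() & (df["code"].astype(str).str.len() > 0)
        df = df.loc[ok]
        coverage = df.groupby("person_id", sort=False)["entity"].agg(
            lambda s: len(set(s))
        )
        need = len(ENTITIES) if mode == "all_four" else 1
        return [pid for pid, n in coverage.items() if n >= need]

    included: list[str] = []
    for person in persons:
        present = person.entities_present()
        if mode == "all_four":
            if present >= set(ENTITIES):
                included.append(person.person_id)
        else:
            if present:
                included.append(person.person_id)
    return included


def count_vector(
    person: PersonRecord,
    entity: str,
    codes: Sequence[str],
    binary: bool = False,
) -> CountVector:
    """Project a person's events of one entity onto an ordered code list.

    With ``binary=True`` each entry is 1 if the person carries the code at
    least once, otherwise the entry is the occurrence count. Codes the
    person does not carry give 0.
    """
    if not codes:
        raise ValueError("codes must be non-empty")
    tally = person.code_counts(entity)
    counts = np.array([tally.get(c, 0) for c in codes], dtype=np.int64)
    if binary:
        counts = (counts > 0).astype(np.int64)
    return CountVector(tuple(codes), counts)


# ---------------------------------------------------------------------------
# I/O: comma-delimited UTF-8 text, empty string = missing, ISO-8601 dates.


def events_to_frame(events: Iterable[CodedEvent]) -> pd.DataFrame:
    rows = [
        (ev.person_id, ev.entity, ev.code, ev.event_date, ev.value, ev.quantity)
        for ev in events
    ]
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def frame_to_events(df: pd.DataFrame) -> list[CodedEvent]:
    events = []
    for row in df.itertuples(index=False):
        events.append(
            CodedEvent(
                person_id=str(row.person_id),
                entity=row.entity,
                code=str(row.code),
                event_date=None if _is_missing(row.event_date) else str(row.event_date),
                value=None if _is_missing(row.value) else float(row.value),
                quantity=None if _is_missing(row.quantity) else float(row.quantity),
            )
        )
    return events


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return isinstance(x, str) and x == ""


def read_events(path) -> pd.DataFrame:
    """Read a long-form events CSV, validating structure row by row.

    Raises ``ValueError`` naming the offending line for malformed rows or
    unknown entity values.
    """
    import csv

    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {EVENT_COLUMNS}")
        if tuple(header) != EVENT_COLUMNS:
            raise ValueError(
                f"{path}: bad header {header}, expected {list(EVENT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(EVENT_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(EVENT_COLUMNS)} "
                    f"fields, got {len(row)}"
                )
            person_id, entity, code, event_date, value, quantity = row
            if entity not in ENTITIES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown entity {entity!r}; "
                    f"expected one of {ENTITIES}"
                )
            if not code:
                raise ValueError(f"{path}: line {lineno}: empty code")
            try:
                value_f = float(value) if value else np.nan
                quantity_f = float(quantity) if quantity else np.nan
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value/quantity"
                ) from None
            rows.append(
                (person_id, entity, code, event_date or None, value_f, quantity_f)
            )
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    if df.empty:
        df = pd.DataFrame(columns=list(EVENT_COLUMNS))
    return df


def write_events(events, path) -> None:
    """Write events (a collection of CodedEvent or a DataFrame) as CSV."""
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    out = df.copy()
    out["event_date"] = out["event_date"].fillna("") if len(out) else out["event_date"]
    out.to_csv(path, index=False, na_rep="")


def read_labels(path) -> pd.DataFrame:
    """Read per-project recruitment labels (person_id, project_id, recruited, db_identified)."""
    df = pd.read_csv(path, dtype={"person_id": str, "project_id": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing label columns {sorted(missing)}")
    for col in ("recruited", "db_identified"):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            raise ValueError(f"{path}: column {col} must be 0/1")
        df[col] = df[col].astype(np.int64)
    return df


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False, columns=list(LABEL_COLUMNS))
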