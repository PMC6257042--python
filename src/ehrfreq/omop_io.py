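"""Read OMOP CDM v5-shaped delimited extracts into the engine's domain types.

The engine consumes four OMOP tables — ``person``, ``condition_occurrence``,
``drug_exposure`` and ``procedure_occurrence`` — plus the ``concept``
dictionary, all as delimited text (tab by default, comma via ``dialect``).
Bulk data is carried in pandas DataFrames with a fixed, validated column
set; the dataclasses below define the per-record view of the same data.

Events with ``concept_id == 0`` (OMOP's "no matching concept" sentinel) are
dropped at read time and tallied, so unmapped source codes never pollute
prevalence estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from ehrfreq.errors import IntegrityError, RowError, SchemaError

logger = logging.getLogger(__name__)

MAX_CONCEPT_NAME_LEN = 255  # OMOP CDM limit on concept_name

CONCEPT_COLUMNS = [
    "concept_id",
    "concept_name",
    "domain_id",
    "vocabulary_id",
    "concept_class_id",
    "concept_code",
]

PERSON_COLUMNS = [
    "person_id",
    "gender_concept_id",
    "race_concept_id",
    "ethnicity_concept_id",
]

#: OMOP v5 concept-id and start-date column per event table.
EVENT_TABLE_COLUMNS: dict[str, tuple[str, str]] = {
    "condition": ("condition_concept_id", "condition_start_date"),
    "drug": ("drug_concept_id", "drug_exposure_start_date"),
    "procedure": ("procedure_concept_id", "procedure_date"),
}

EVENT_FRAME_COLUMNS = ["person_id", "concept_id", "event_date", "source_table"]

SourceTable = Literal["condition", "drug", "procedure"]


@dataclass(frozen=True)
class Concept:
    """One OMOP concept definition."""

    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str
    concept_code: str


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated clinical observation of a concept for a person."""

    person_id: int
    concept_id: int
    event_date: date
    source_table: SourceTable


@dataclass(frozen=True)
class PersonRecord:
    """Demographic concept ids for one person (0 = unmapped)."""

    person_id: int
    gender_concept_id: int = 0
    race_concept_id: int = 0
    ethnicity_concept_id: int = 0


@dataclass
class ReadReport:
    """Row-level accounting for one event-table read.

    ``rows_read`` = rows kept + ``dropped_zero_concept`` + ``dropped_bad_date``;
    the reconciliation is exact.
    """

    rows_read: int = 0
    dropped_zero_concept: int = 0
    dropped_bad_date: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def rows_kept(self) -> int:
        return self.rows_read - self.dropped_zero_concept - self.dropped_bad_date


def _read_table(path: str | Path, delimiter: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"{path.name}: missing required column {column!r}")
    return frame


def read_concepts(
    path: str | Path,
    delimiter: str = "\t",
    long_names: Literal["error", "truncate"] = "error",
) -> dict[int, Concept]:
    """Read a concept dictionary file into a ``{concept_id: Concept}`` map.

    Parameters
    ----------
    path
        Delimited file with a header row naming the six concept columns.
    delimiter
        Field delimiter; tab by default.
    long_names
        Policy for names longer than the 255-character OMOP limit:
        ``"error"`` raises, ``"truncate"`` keeps the first 255 characters.

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        On a duplicate ``concept_id`` or an over-long name under ``"error"``.
    """
    frame = _read_table(path, delimiter, CONCEPT_COLUMNS)
    concepts: dict[int, Concept] = {}
    for row in frame.itertuples(index=False):
        cid = int(row.concept_id)
        if cid in concepts:
            raise IntegrityError(f"duplicate concept_id {cid} in {Path(path).name}")
        name = str(row.concept_name)
        if len(name) > MAX_CONCEPT_NAME_LEN:
            if long_names == "error":
                raise IntegrityError(
                    f"concept_id {cid}: concept_name length {len(name)} exceeds "
                    f"{MAX_CONCEPT_NAME_LEN}"
                )
            name = name[:MAX_CONCEPT_NAME_LEN]
        concepts[cid] = Concept(
            concept_id=cid,
            concept_name=name,
            domain_id=str(row.domain_id),
            vocabulary_id=str(row.vocabulary_id),
            concept_class_id=str(row.concept_class_id),
            concept_code=str(row.concept_code),
        )
    return concepts


def write_concepts(
    concepts: dict[int, Concept], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a concept dictionary, sorted by id, in the six-column layout."""
    rows = [
        [c.concept_id, c.concept_name, c.domain_id, c.vocabulary_id,
         c.concept_class_id, c.concept_code]
        for c in sorted(concepts.values(), key=lambda c: c.concept_id)
    ]
    frame = pd.DataFrame(rows, columns=CONCEPT_COLUMNS)
    frame.to_csv(path, sep=delimiter, index=False)


def read_events(
    path: str | Path,
    source_table: SourceTable,
    delimiter: str = "\t",
    bad_dates: Literal["fail", "skip"] = "fail",
    id_column: str | None = None,
    date_column: str | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read one OMOP event table into the normalized event frame.

    Each kept row becomes one event with columns ``person_id``,
    ``concept_id``, ``event_date`` (``datetime.date``) and ``source_table``.
    Rows whose concept id is 0 are dropped and tallied; rows whose date
    does not parse either raise (``bad_dates="fail"``, naming the row) or
    are dropped and tallied (``"skip"``).  Datetime values are truncated
    to their date part.

    ``id_column`` / ``date_column`` override the standard OMOP v5 column
    names for the given ``source_table``.
    """
    if source_table not in EVENT_TABLE_COLUMNS:
        raise ValueError(
            f"source_table must be one of {sorted(EVENT_TABLE_COLUMNS)}, "
            f"got {source_table!r}"
        )
    default_id, default_date = EVENT_TABLE_COLUMNS[source_table]
    id_column = id_column or default_id
    date_column = date_column or default_date

    frame = _read_table(path, delimiter, ["person_id", id_column, date_column])
    report = ReadReport(rows_read=len(frame))

    concept_ids = pd.to_numeric(frame[id_column], errors="coerce").fillna(0).astype(int)
    nonzero = concept_ids != 0
    report.dropped_zero_concept = int((~nonzero).sum())
    if report.dropped_zero_concept:
        report.messages.append(
            f"{Path(path).name}: dropped {report.dropped_zero_concept} row(s) "
            "with concept_id 0 (unmapped)"
        )

    parsed = pd.to_datetime(frame[date_column], errors="coerce", format="mixed")
    bad = parsed.isna() & nonzero
    if bad.any():
        if bad_dates == "fail":
            row_no = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise RowError(
                f"{Path(path).name} line {row_no}: unparseable "
                f"{date_column} value {frame[date_column][bad.idxmax()]!r}"
            )
        report.dropped_bad_date = int(bad.sum())
        report.messages.append(
            f"{Path(path).name}: skipped {report.dropped_bad_date} row(s) "
            f"with unparseable {date_column}"
        )

    keep = nonzero & parsed.notna()
    events = pd.DataFrame(
        {
            "person_id": pd.to_numeric(frame["person_id"][keep]).astype(int),
            "concept_id": concept_ids[keep],
            "event_date": parsed[keep].dt.date,
            "source_table": source_table,
        }
    ).reset_index(drop=True)
    for message in report.messages:
        logger.info(message)
    return events, report


def concat_events(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate event frames from the three tables into one."""
    frames = list(frames)
    if not frames:
        return pd.DataFrame(columns=EVENT_FRAME_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def read_persons(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read the person table (person_id plus the three demographic ids).

    Demographic ids of 0 mean "unmapped" and are kept here; downstream
    counting treats them as absent.  A duplicate ``person_id`` raises
    :class:`IntegrityError` — person ids are assumed to uniquely identify
    patients.
    """
    frame = _read_table(path, delimiter, PERSON_COLUMNS)
    persons = frame[PERSON_COLUMNS].apply(pd.to_numeric).astype(int)
    duplicated = persons["person_id"].duplicated()
    if duplicated.any():
        dup_id = int(persons["person_id"][duplicated].iloc[0])
        raise IntegrityError(f"duplicate person_id {dup_id} in {Path(path).name}")
    return persons.reset_index(drop=True)


def write_persons(persons: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    persons[PERSON_COLUMNS].to_csv(path, sep=delimiter, index=False)


def load_iatrogenic_codes(path: str | Path, delimiter: str = "\t") -> set[tuple[str, str]]:
    """Load a two-column (vocabulary_id, concept_code) iatrogenic-code list.

    The file has no header.  Returns a set of (vocabulary, code) string
    pairs; a malformed row raises :class:`RowError` with its line number.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise RowError(
                    f"{Path(path).name} line {line_no}: expected two fields "
                    f"(vocabulary, code), got {line!r}"
                )
            pairs.add((parts[0].strip(), parts[1].strip()))
    return pairs


def match_iatrogenic(
    concepts: dict[int, Concept], codes: set[tuple[str, str]]
) -> set[int]:
    """Resolve (vocabulary, code) pairs to concept ids via the dictionary.

    Pairs absent from the dictionary match nothing; the count of unmatched
    pairs is logged.
    """
    index = {(c.vocabulary_id, c.concept_code): c.concept_id for c in concepts.values()}
    matched = {index[pair] for pair in codes if pair in index}
    unmatched = len(codes) - sum(1 for pair in codes if pair in index)
    if unmatched:
        logger.info("%d iatrogenic code(s) not present in the concept dictionary", unmatched)
    return matched
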