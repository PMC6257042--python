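"""Read and write the nine-file flat-file bundle of released counts.

A bundle holds, per dataset (e.g. ``lifetime`` and ``5year``), four
tab-delimited files — single-concept counts, paired-concept counts, and
the annual-deviation companions of each — plus one shared concept
dictionary:

* ``{dataset}_single_concepts.txt``: concept_id, count, prevalence
* ``{dataset}_paired_concepts.txt``: concept_id_1, concept_id_2, count, prevalence
* ``{dataset}_single_concept_deviations.txt``: concept_id, mean, sd
* ``{dataset}_paired_concept_deviations.txt``: concept_id_1, concept_id_2, mean, sd
* ``concepts.txt``: concept_id, concept_name, domain_id, vocabulary_id,
  concept_class_id, concept_code

All frequencies are relative to a maximum of 1.0 (1.0 = 100%).  Rows are
deterministically ordered (singles by concept_id, pairs by the canonical
ascending id pair) and frequencies rendered at a fixed precision, so
write → read → write is a byte-identical round trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ehrfreq.cooccurrence import (
    DatasetMetadata,
    PAIR_COLUMNS,
    PAIR_DEV_COLUMNS,
    SINGLE_COLUMNS,
    SINGLE_DEV_COLUMNS,
)
from ehrfreq.errors import SchemaError
from ehrfreq.omop_io import Concept, read_concepts, write_concepts

logger = logging.getLogger(__name__)

#: Decimal places used to render frequency columns (matches the released
#: files' 6-decimal prevalence rendering); None = full precision.
DEFAULT_FREQUENCY_DECIMALS = 6


@dataclass
class DatasetTables:
    """Released tables of one dataset, plus its metadata."""

    metadata: DatasetMetadata
    singles: pd.DataFrame
    pairs: pd.DataFrame
    single_deviations: pd.DataFrame | None = None
    pair_deviations: pd.DataFrame | None = None

    @property
    def has_deviations(self) -> bool:
        return self.single_deviations is not None and self.pair_deviations is not None


@dataclass
class CohdBundle:
    """A complete release: per-dataset tables plus the shared concept dictionary."""

    datasets: dict[str, DatasetTables] = field(default_factory=dict)
    concepts: dict[int, Concept] = field(default_factory=dict)


def _render(frame: pd.DataFrame, float_columns: list[str], decimals: int | None) -> pd.DataFrame:
    out = frame.copy()
    for column in float_columns:
        if decimals is None:
            out[column] = out[column].map(repr)
        else:
            out[column] = out[column].map(lambda v: f"{v:.{decimals}f}")
    return out


def write_bundle(
    bundle: CohdBundle,
    directory: str | Path,
    decimals: int | None = DEFAULT_FREQUENCY_DECIMALS,
    header: bool = True,
) -> list[str]:
    """Write a bundle as tab-delimited files under ``directory``.

    ``decimals`` controls frequency rendering (None = full precision);
    ``header=False`` omits the header row for strict positional layouts.
    Returns the list of written file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _write(frame: pd.DataFrame, columns: list[str], floats: list[str], name: str) -> None:
        path = directory / name
        rendered = _render(frame[columns], floats, decimals)
        rendered.to_csv(path, sep="\t", index=False, header=header, lineterminator="\n")
        written.append(str(path))

    meta_records = {}
    for dataset_id, tables in bundle.datasets.items():
        singles = tables.singles.sort_values("concept_id")
        pairs = tables.pairs.sort_values(["concept_id_1", "concept_id_2"])
        _write(singles, SINGLE_COLUMNS, ["prevalence"], f"{dataset_id}_single_concepts.txt")
        _write(pairs, PAIR_COLUMNS, ["prevalence"], f"{dataset_id}_paired_concepts.txt")
        if tables.single_deviations is not None:
            _write(
                tables.single_deviations.sort_values("concept_id"),
                SINGLE_DEV_COLUMNS, ["mean", "sd"],
                f"{dataset_id}_single_concept_deviations.txt",
            )
        if tables.pair_deviations is not None:
            _write(
                tables.pair_deviations.sort_values(["concept_id_1", "concept_id_2"]),
                PAIR_DEV_COLUMNS, ["mean", "sd"],
                f"{dataset_id}_paired_concept_deviations.txt",
            )
        meta = tables.metadata
        meta_records[dataset_id] = {
            "dataset_id": meta.dataset_id,
            "date_window": [str(d) for d in meta.date_window] if meta.date_window else None,
            "patient_count": meta.patient_count,
            "full_years": list(meta.full_years),
        }

    write_concepts(bundle.concepts, directory / "concepts.txt")
    written.append(str(directory / "concepts.txt"))
    with open(directory / "metadata.json", "w", encoding="utf-8") as handle:
        json.dump(meta_records, handle, indent=1, sort_keys=True)
        handle.write("\n")
    written.append(str(directory / "metadata.json"))
    return written


def _read_file(path: Path, columns: list[str], int_columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != columns:
        missing = [c for c in columns if c not in frame.columns]
        detail = f"missing column(s) {missing}" if missing else f"got {list(frame.columns)}"
        raise SchemaError(f"{path.name}: expected columns {columns}; {detail}")
    for column in int_columns:
        frame[column] = frame[column].astype(int)
    return frame


def _normalize_pairs(frame: pd.DataFrame, filename: str) -> pd.DataFrame:
    flipped = frame["concept_id_1"] > frame["concept_id_2"]
    if flipped.any():
        logger.warning(
            "%s: %d pair row(s) not in canonical ascending-id order; normalized",
            filename, int(flipped.sum()),
        )
        frame = frame.copy()
        c1 = frame["concept_id_1"].where(~flipped, frame["concept_id_2"])
        c2 = frame["concept_id_2"].where(~flipped, frame["concept_id_1"])
        frame["concept_id_1"], frame["concept_id_2"] = c1, c2
        frame = frame.sort_values(["concept_id_1", "concept_id_2"]).reset_index(drop=True)
    return frame


def read_bundle(directory: str | Path) -> CohdBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    Datasets are discovered from ``*_single_concepts.txt`` filenames.
    Missing deviation files leave the corresponding tables ``None``
    (``DatasetTables.has_deviations`` is then False).  Pair rows stored
    out of canonical order are normalized with a warning.
    """
    directory = Path(directory)
    concepts = read_concepts(directory / "concepts.txt")

    meta_path = directory / "metadata.json"
    meta_records: dict[str, dict] = {}
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as handle:
            meta_records = json.load(handle)

    bundle = CohdBundle(concepts=concepts)
    for singles_path in sorted(directory.glob("*_single_concepts.txt")):
        dataset_id = singles_path.name[: -len("_single_concepts.txt")]
        singles = _read_file(singles_path, SINGLE_COLUMNS, ["concept_id", "count"])
        pairs_path = directory / f"{dataset_id}_paired_concepts.txt"
        if not pairs_path.exists():
            raise SchemaError(f"{pairs_path.name} missing for dataset {dataset_id!r}")
        pairs = _normalize_pairs(
            _read_file(pairs_path, PAIR_COLUMNS,
                       ["concept_id_1", "concept_id_2", "count"]),
            pairs_path.name,
        )

        single_dev = pair_dev = None
        sdev_path = directory / f"{dataset_id}_single_concept_deviations.txt"
        pdev_path = directory / f"{dataset_id}_paired_concept_deviations.txt"
        if sdev_path.exists():
            single_dev = _read_file(sdev_path, SINGLE_DEV_COLUMNS, ["concept_id"])
        if pdev_path.exists():
            pair_dev = _normalize_pairs(
                _read_file(pdev_path, PAIR_DEV_COLUMNS, ["concept_id_1", "concept_id_2"]),
                pdev_path.name,
            )

        record = meta_records.get(dataset_id, {})
        window = record.get("date_window")
        metadata = DatasetMetadata(
            dataset_id=dataset_id,
            date_window=tuple(pd.to_datetime(d).date() for d in window) if window else None,
            patient_count=int(record.get("patient_count", 0)),
            full_years=tuple(record.get("full_years", [])),
        )
        bundle.datasets[dataset_id] = DatasetTables(
            metadata=metadata,
            singles=singles,
            pairs=pairs,
            single_deviations=single_dev,
            pair_deviations=pair_dev,
        )
    return bundle
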