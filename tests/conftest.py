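"""Shared fixtures: worked-example cohort on disk, loaded tables, a released bundle."""

from __future__ import annotations

from itertools import combinations

import pandas as pd
import pytest

import ehrfreq as ef
from ehrfreq.omop_io import concat_events
from ehrfreq.privacy import PrivacyConfig
from ehrfreq.synthetic_cohort import WORKED_EXAMPLE_WINDOW, worked_example_cohort

TABLE_FILES = {
    "person": "person.txt",
    "condition": "condition_occurrence.txt",
    "drug": "drug_exposure.txt",
    "procedure": "procedure_occurrence.txt",
    "concept": "concept.txt",
}


def write_omop_dir(directory, person, condition, drug, procedure, concept):
    """Write five OMOP frames as tab-delimited files; returns the directory."""
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in zip(TABLE_FILES, (person, condition, drug, procedure, concept)):
        frame.to_csv(directory / TABLE_FILES[name], sep="\t", index=False)
    return directory


def load_omop_dir(directory):
    """Read an OMOP directory back into (events, persons, concepts)."""
    persons = ef.read_persons(directory / TABLE_FILES["person"])
    concepts = ef.read_concepts(directory / TABLE_FILES["concept"])
    frames = [
        ef.read_events(directory / TABLE_FILES[table], table)[0]
        for table in ("condition", "drug", "procedure")
    ]
    return concat_events(frames), persons, concepts


def brute_force_counts(pcm):
    """Independent oracle: single and pair unique-patient counts by double loop."""
    concepts = sorted({c for s in pcm.values() for c in s})
    singles = {
        c: sum(1 for s in pcm.values() if c in s) for c in concepts
    }
    pairs = {}
    for c1, c2 in combinations(concepts, 2):
        n = sum(1 for s in pcm.values() if c1 in s and c2 in s)
        if n:
            pairs[(c1, c2)] = n
    return singles, pairs


@pytest.fixture(scope="session")
def worked_example_dir(tmp_path_factory):
    directory = tmp_path_factory.mktemp("omop")
    return write_omop_dir(directory, *worked_example_cohort())


@pytest.fixture(scope="session")
def worked_example_tables(worked_example_dir):
    return load_omop_dir(worked_example_dir)


@pytest.fixture(scope="session")
def worked_example_bundle(worked_example_tables):
    """Released bundle over the worked example (threshold 0 keeps tiny counts)."""
    events, persons, concepts = worked_example_tables
    config = PrivacyConfig(min_count_threshold=0, seed=11)
    return ef.build_bundle(
        events,
        persons,
        concepts,
        config,
        windows={"lifetime": None, "5year": WORKED_EXAMPLE_WINDOW},
        full_years={"5year": range(2013, 2018)},
    )


def singles_as_dict(frame: pd.DataFrame) -> dict[int, int]:
    return {int(c): int(n) for c, n in zip(frame["concept_id"], frame["count"])}


def pairs_as_dict(frame: pd.DataFrame) -> dict[tuple[int, int], int]:
    return {
        (int(a), int(b)): int(n)
        for a, b, n in zip(frame["concept_id_1"], frame["concept_id_2"], frame["count"])
    }
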