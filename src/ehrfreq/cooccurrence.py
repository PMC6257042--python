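"""Per-patient concept sets and true single/pair patient counts.

EHR prevalence of a concept C is ``P_EHR(C) = N_C / N_P`` where ``N_C``
is the number of unique patients observed with C inside the dataset
window and ``N_P`` the number of unique patients with at least one
clinical (condition/drug/procedure) event in that window.  Co-occurrence
frequency of a pair is ``CO_EHR(C1, C2) = N_{C1,C2} / N_P`` with
``N_{C1,C2}`` the number of unique patients observed with both concepts.

A patient qualifies for a dataset only through clinical events; the
person's non-zero demographic concepts (gender/race/ethnicity) then join
the patient's concept set and are counted singly and in pairs like any
other concept, but never qualify the patient by themselves.

Counting ignores temporal relations between concepts: a pair counts if
both members appear anywhere in the patient's in-window record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ehrfreq.errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

SINGLE_COLUMNS = ["concept_id", "count", "prevalence"]
PAIR_COLUMNS = ["concept_id_1", "concept_id_2", "count", "prevalence"]
SINGLE_DEV_COLUMNS = ["concept_id", "mean", "sd"]
PAIR_DEV_COLUMNS = ["concept_id_1", "concept_id_2", "mean", "sd"]

DEMOGRAPHIC_COLUMNS = ["gender_concept_id", "race_concept_id", "ethnicity_concept_id"]


@dataclass(frozen=True)
class DatasetMetadata:
    """Descriptor of one counting window.

    ``patient_count`` (N_P) equals the number of distinct patients with at
    least one in-window clinical event.  ``full_years`` lists calendar
    years fully covered by data, used for annual-stability statistics.
    """

    dataset_id: str
    date_window: tuple[date, date] | None
    patient_count: int
    full_years: tuple[int, ...] = ()


def prevalence(n_c: int | float, n_p: int) -> float:
    """EHR prevalence (or co-occurrence frequency): ``n_c / n_p``.

    True counts satisfy ``n_c <= n_p``; Poisson-randomized counts may not,
    so no upper bound is enforced here.
    """
    if n_p <= 0:
        raise UndefinedStatisticError("prevalence undefined: patient count N_P is 0")
    if n_c < 0:
        raise UndefinedStatisticError(f"negative count {n_c}")
    return n_c / n_p


def build_patient_concepts(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    window: tuple[date, date] | None = None,
    dataset_id: str = "lifetime",
    full_years: Iterable[int] = (),
) -> tuple[dict[int, set[int]], DatasetMetadata]:
    """Build each patient's deduplicated concept set for one dataset window.

    Parameters
    ----------
    events
        Normalized event frame (person_id, concept_id, event_date, source_table).
    persons
        Person table with the three demographic concept-id columns.
    window
        Optional inclusive (start, end) date interval; ``None`` keeps all events.

    Returns
    -------
    (patient_concept_map, metadata)
        ``patient_concept_map`` maps person_id to the set of clinical
        concept ids observed in-window plus the person's non-zero
        demographic concept ids.  Patients with no in-window clinical
        event are absent, and absent from ``metadata.patient_count``.
    """
    if window is not None:
        start, end = window
        mask = (events["event_date"] >= start) & (events["event_date"] <= end)
        events = events[mask]

    pcm: dict[int, set[int]] = {}
    grouped = events.groupby("person_id")["concept_id"]
    for person_id, concept_ids in grouped:
        pcm[int(person_id)] = set(int(c) for c in concept_ids)

    demo = persons.set_index("person_id")[DEMOGRAPHIC_COLUMNS]
    for person_id, concepts in pcm.items():
        if person_id in demo.index:
            for value in demo.loc[person_id]:
                if int(value) != 0:
                    concepts.add(int(value))

    meta = DatasetMetadata(
        dataset_id=dataset_id,
        date_window=window,
        patient_count=len(pcm),
        full_years=tuple(full_years),
    )
    return pcm, meta


def count_singles(
    pcm: Mapping[int, set[int]], metadata: DatasetMetadata | None = None
) -> pd.DataFrame:
    """True unique-patient counts N_C for every concept in any patient set.

    Returns a frame (concept_id, count, prevalence) sorted by concept_id;
    prevalence is computed against N_P when ``metadata`` is given, else NaN.
    """
    tally: dict[int, int] = {}
    for concepts in pcm.values():
        for concept_id in concepts:
            tally[concept_id] = tally.get(concept_id, 0) + 1
    frame = pd.DataFrame(
        sorted(tally.items()), columns=["concept_id", "count"], dtype=np.int64
    )
    if frame.empty:
        frame = pd.DataFrame({"concept_id": pd.Series(dtype=np.int64),
                              "count": pd.Series(dtype=np.int64)})
    n_p = metadata.patient_count if metadata is not None else 0
    frame["prevalence"] = frame["count"] / n_p if n_p > 0 else np.nan
    return frame


def count_pairs(
    pcm: Mapping[int, set[int]], metadata: DatasetMetadata | None = None
) -> pd.DataFrame:
    """True unique-patient counts N_{C1,C2} for every observed unordered pair.

    Pairs are stored once, in canonical ascending-id order; self-pairs are
    not emitted.  Returns (concept_id_1, concept_id_2, count, prevalence)
    sorted by (concept_id_1, concept_id_2).
    """
    tally: dict[tuple[int, int], int] = {}
    for concepts in pcm.values():
        for pair in combinations(sorted(concepts), 2):
            tally[pair] = tally.get(pair, 0) + 1
    rows = [(c1, c2, n) for (c1, c2), n in sorted(tally.items())]
    frame = pd.DataFrame(rows, columns=["concept_id_1", "concept_id_2", "count"],
                         dtype=np.int64)
    if frame.empty:
        frame = pd.DataFrame({"concept_id_1": pd.Series(dtype=np.int64),
                              "concept_id_2": pd.Series(dtype=np.int64),
                              "count": pd.Series(dtype=np.int64)})
    n_p = metadata.patient_count if metadata is not None else 0
    frame["prevalence"] = frame["count"] / n_p if n_p > 0 else np.nan
    return frame


def annual_deviations(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    full_years: Iterable[int],
    seed: int,
    dataset_id: str = "lifetime",
    sd_ddof: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and SD of annual prevalence / co-occurrence rates.

    Each full calendar year is counted as its own window with its own
    annual N_P.  Per concept (and per pair), the *mean* annual rate is
    taken over Poisson-randomized annual counts while the *standard
    deviation* is taken over the true annual counts; randomizing the mean
    protects the released statistic, while the true-count SD preserves an
    unbiased stability signal.  A concept absent in a year contributes
    rate 0 for that year.  Years with no clinical events at all have an
    undefined annual N_P and are skipped (logged).

    ``sd_ddof`` selects the SD convention: 0 (population, default) or 1
    (sample).

    Returns (single_deviations, pair_deviations) frames with columns
    (concept_id[, concept_id_2], mean, sd).
    """
    from ehrfreq.privacy import poisson_randomize  # local import avoids a cycle

    years = sorted(set(int(y) for y in full_years))
    if not years:
        raise ValueError("full_years must be non-empty")

    single_true: dict[int, list[float]] = {}
    single_rand: dict[int, list[float]] = {}
    pair_true: dict[tuple[int, int], list[float]] = {}
    pair_rand: dict[tuple[int, int], list[float]] = {}
    used_years: list[int] = []

    for year in years:
        window = (date(year, 1, 1), date(year, 12, 31))
        pcm, meta = build_patient_concepts(
            events, persons, window=window, dataset_id=f"{dataset_id}:{year}"
        )
        if meta.patient_count == 0:
            logger.info("year %d has no clinical events; skipped", year)
            continue
        used_years.append(year)
        n_p = meta.patient_count
        singles = count_singles(pcm, meta)
        pairs = count_pairs(pcm, meta)
        singles_r = poisson_randomize(singles, seed, dataset_id=f"{dataset_id}:{year}")
        pairs_r = poisson_randomize(pairs, seed, dataset_id=f"{dataset_id}:{year}")

        year_index = len(used_years) - 1
        for frame, store in ((singles, single_true), (singles_r, single_rand)):
            for row in frame.itertuples(index=False):
                series = store.setdefault(int(row.concept_id), [])
                series.extend([0.0] * (year_index - len(series)))
                series.append(row.count / n_p)
        for frame, store in ((pairs, pair_true), (pairs_r, pair_rand)):
            for row in frame.itertuples(index=False):
                key = (int(row.concept_id_1), int(row.concept_id_2))
                series = store.setdefault(key, [])
                series.extend([0.0] * (year_index - len(series)))
                series.append(row.count / n_p)

    n_years = len(used_years)
    if n_years == 0:
        raise UndefinedStatisticError("no full year contains any clinical events")

    def _pad(series: list[float]) -> np.ndarray:
        return np.asarray(series + [0.0] * (n_years - len(series)))

    single_rows = [
        (cid,
         float(_pad(single_rand.get(cid, [])).mean()),
         float(_pad(single_true[cid]).std(ddof=sd_ddof)))
        for cid in sorted(single_true)
    ]
    pair_rows = [
        (c1, c2,
         float(_pad(pair_rand.get((c1, c2), [])).mean()),
         float(_pad(pair_true[(c1, c2)]).std(ddof=sd_ddof)))
        for c1, c2 in sorted(pair_true)
    ]
    single_dev = pd.DataFrame(single_rows, columns=SINGLE_DEV_COLUMNS)
    pair_dev = pd.DataFrame(pair_rows, columns=PAIR_DEV_COLUMNS)
    if single_dev.empty:
        single_dev = pd.DataFrame({c: pd.Series(dtype=float) for c in SINGLE_DEV_COLUMNS})
    if pair_dev.empty:
        pair_dev = pd.DataFrame({c: pd.Series(dtype=float) for c in PAIR_DEV_COLUMNS})
    return single_dev, pair_dev
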