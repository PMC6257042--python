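"""OMOP-shaped synthetic cohorts with known statistical structure.

The generator draws, per patient, a set of clinical concepts from a
catalog of (concept_id, domain, marginal prevalence) entries.  Concepts
are mutually independent except for explicitly listed disjoint pairs, for
which joint presence follows the 2×2 distribution determined by the two
marginals and a specified odds ratio (the joint cell solved from the
quadratic identity).  Each patient-positive concept emits one or more
duplicate event rows with dates uniform over the configured year range —
the counting stages must deduplicate them.  Demographics (gender / race /
ethnicity concepts) are drawn per-category; unassigned probability mass
maps to concept id 0 (unmapped).

Everything is deterministic under a fixed seed, and the emitted tables
use exactly the delimited layouts the OMOP readers expect.

What this emulates — and what it does not: per-patient concept sets with
controlled marginal prevalence and pairwise dependence, multi-year event
dates, unmapped demographics.  It has no visit structure, no temporal
correlation within patients, and no coding-system drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from ehrfreq.errors import InfeasibleSpecError
from ehrfreq.omop_io import CONCEPT_COLUMNS, PERSON_COLUMNS, EVENT_TABLE_COLUMNS

_DOMAIN_TO_TABLE = {"Condition": "condition", "Drug": "drug", "Procedure": "procedure"}

#: Default demographics: two genders, two races, one ethnicity, with a
#: slice of unmapped (id 0) mass, loosely shaped like a US academic
#: medical center's mapped/unmapped mix.
DEFAULT_DEMOGRAPHICS: dict[str, dict[int, float]] = {
    "gender": {8532: 0.55, 8507: 0.44},          # FEMALE, MALE; 1% unmapped
    "race": {8527: 0.40, 8516: 0.25},            # White, Black; 35% unmapped
    "ethnicity": {38003564: 0.60, 38003563: 0.20},  # Not Hispanic, Hispanic
}

_DEMOGRAPHIC_CONCEPTS: dict[int, tuple[str, str]] = {
    8532: ("FEMALE", "Gender"),
    8507: ("MALE", "Gender"),
    8527: ("White", "Race"),
    8516: ("Black or African American", "Race"),
    38003564: ("Not Hispanic or Latino", "Ethnicity"),
    38003563: ("Hispanic or Latino", "Ethnicity"),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``concept_catalog`` lists (concept_id, domain, marginal_prevalence);
    ``dependence_list`` lists (concept_id_1, concept_id_2, odds_ratio) for
    disjoint pairs; every other concept is independent of all others.
    ``events_per_positive`` is the mean number of duplicate event rows per
    positive patient-concept (≥ 1; the excess over 1 is Poisson).
    """

    n_patients: int
    year_range: tuple[int, int] = (2013, 2017)
    concept_catalog: tuple[tuple[int, str, float], ...] = ()
    dependence_list: tuple[tuple[int, int, float], ...] = ()
    demographics_spec: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    events_per_positive: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for cid, domain, p in self.concept_catalog:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal prevalence of concept {cid} not in [0,1]")
            if domain not in _DOMAIN_TO_TABLE:
                raise ValueError(f"concept {cid}: unsupported domain {domain!r}")
        for c1, c2, odds in self.dependence_list:
            if odds <= 0:
                raise ValueError(f"odds ratio of pair ({c1},{c2}) must be > 0")
        for group, probs in self.demographics_spec.items():
            total = sum(probs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"demographic probabilities for {group} sum to {total} > 1")
        if self.events_per_positive < 1.0:
            raise ValueError("events_per_positive must be >= 1")


def joint_probability(p1: float, p2: float, odds_ratio: float) -> float:
    """Joint presence probability P(C1 ∧ C2) for given marginals and odds ratio.

    Solves the 2×2 identity ``OR = p11·p00 / (p10·p01)`` for ``p11``; the
    quadratic root inside the Fréchet bounds ``[max(0, p1+p2-1),
    min(p1, p2)]`` is returned.  Raises :class:`InfeasibleSpecError` when
    no such root exists.
    """
    if abs(odds_ratio - 1.0) >= 1e-12 and not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise InfeasibleSpecError(
            f"cannot impose odds ratio {odds_ratio} on degenerate marginals "
            f"({p1}, {p2}); both must lie strictly inside (0, 1)"
        )
    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p1 * p2
    else:
        a = odds_ratio - 1.0
        s = 1.0 + (p1 + p2) * a
        disc = s * s - 4.0 * odds_ratio * a * p1 * p2
        if disc < 0:
            raise InfeasibleSpecError(
                f"no joint cell for marginals ({p1}, {p2}) with odds ratio {odds_ratio}"
            )
        p11 = (s - math.sqrt(disc)) / (2.0 * a)
    lower = max(0.0, p1 + p2 - 1.0)
    upper = min(p1, p2)
    if not lower - 1e-9 <= p11 <= upper + 1e-9:
        raise InfeasibleSpecError(
            f"joint cell {p11:.6g} outside feasible range [{lower:.6g}, {upper:.6g}] "
            f"for marginals ({p1}, {p2}) with odds ratio {odds_ratio}"
        )
    return min(max(p11, lower), upper)


def _uniform_dates(rng: np.random.Generator, n: int, year_range: tuple[int, int]) -> list[date]:
    start = date(year_range[0], 1, 1)
    end = date(year_range[1], 12, 31)
    span = (end - start).days + 1
    return [start + timedelta(days=int(d)) for d in rng.integers(0, span, size=n)]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (person, condition, drug, procedure, concept) tables.

    Returned frames use the exact OMOP column layouts the readers expect
    and are byte-stable under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    catalog = {cid: (domain, p) for cid, domain, p in spec.concept_catalog}

    in_pairs: set[int] = set()
    for c1, c2, odds in spec.dependence_list:
        for cid in (c1, c2):
            if cid not in catalog:
                raise InfeasibleSpecError(f"dependence pair references unknown concept {cid}")
            if cid in in_pairs:
                raise InfeasibleSpecError(
                    f"concept {cid} appears in more than one dependence pair; "
                    "only disjoint pairs are supported"
                )
            in_pairs.add(cid)

    n = spec.n_patients
    presence: dict[int, np.ndarray] = {}
    for c1, c2, odds in spec.dependence_list:
        p1, p2 = catalog[c1][1], catalog[c2][1]
        p11 = joint_probability(p1, p2, odds)
        # cell probabilities: (both, c1 only, c2 only, neither)
        probs = [p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11]
        cells = rng.choice(4, size=n, p=probs)
        presence[c1] = (cells == 0) | (cells == 1)
        presence[c2] = (cells == 0) | (cells == 2)
    for cid, (domain, p) in catalog.items():
        if cid not in presence:
            presence[cid] = rng.random(n) < p

    person_ids = np.arange(1, n + 1)
    demo_columns: dict[str, np.ndarray] = {}
    for group in ("gender", "race", "ethnicity"):
        probs = spec.demographics_spec.get(group, {})
        ids = list(probs.keys())
        weights = [probs[i] for i in ids]
        ids.append(0)  # unmapped remainder
        weights.append(max(0.0, 1.0 - sum(weights)))
        weights = np.asarray(weights) / np.sum(weights)
        demo_columns[f"{group}_concept_id"] = rng.choice(ids, size=n, p=weights)

    person = pd.DataFrame({"person_id": person_ids, **demo_columns})[PERSON_COLUMNS]

    event_rows: dict[str, list[tuple[int, int, date]]] = {
        "condition": [], "drug": [], "procedure": []
    }
    extra_rate = spec.events_per_positive - 1.0
    for cid in sorted(presence):
        domain, _ = catalog[cid]
        table = _DOMAIN_TO_TABLE[domain]
        positives = person_ids[presence[cid]]
        if len(positives) == 0:
            continue
        n_events = 1 + rng.poisson(extra_rate, size=len(positives))
        total = int(n_events.sum())
        dates = _uniform_dates(rng, total, spec.year_range)
        cursor = 0
        for pid, k in zip(positives, n_events):
            for _ in range(int(k)):
                event_rows[table].append((int(pid), cid, dates[cursor]))
                cursor += 1

    tables: dict[str, pd.DataFrame] = {}
    for table, rows in event_rows.items():
        id_col, date_col = EVENT_TABLE_COLUMNS[table]
        frame = pd.DataFrame(rows, columns=["person_id", id_col, date_col])
        frame = frame.sort_values(["person_id", id_col, date_col]).reset_index(drop=True)
        tables[table] = frame

    concept_rows = []
    for cid, (domain, _) in sorted(catalog.items()):
        concept_rows.append(
            (cid, f"Synthetic {domain.lower()} {cid}", domain, "SyntheticVocab",
             f"{domain} Class", f"SYN-{cid}")
        )
    demographic_ids = sorted(
        {int(v) for column in demo_columns.values() for v in column if int(v) != 0}
    )
    for cid in demographic_ids:
        name, domain = _DEMOGRAPHIC_CONCEPTS.get(cid, (f"Demographic {cid}", "Observation"))
        concept_rows.append((cid, name, domain, "SyntheticVocab", domain, f"SYN-{cid}"))
    concept = pd.DataFrame(concept_rows, columns=CONCEPT_COLUMNS)

    return person, tables["condition"], tables["drug"], tables["procedure"], concept


def write_cohort(
    spec: CohortSpec, directory, delimiter: str = "\t"
) -> dict[str, str]:
    """Generate a cohort and write its five tables under ``directory``.

    Returns a name → path map for the written files.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    person, condition, drug, procedure, concept = generate_cohort(spec)
    frames = {
        "person": person,
        "condition_occurrence": condition,
        "drug_exposure": drug,
        "procedure_occurrence": procedure,
        "concept": concept,
    }
    paths = {}
    for name, frame in frames.items():
        path = directory / f"{name}.txt"
        frame.to_csv(path, sep=delimiter, index=False)
        paths[name] = str(path)
    return paths


def worked_example_cohort() -> tuple[
    pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame
]:
    """A frozen 6-patient cohort whose every count is hand-enumerable.

    Layout (clinical concepts: condition 101 "a", condition 102 "b",
    drug 201 "c"; window of interest [2013-01-01, 2017-12-31]):

    * p1: a, b            (two events of a — deduplicated to one)
    * p2: a, b, c
    * p3: a
    * p4: c only, dated 2012 — outside the 5-year window
    * p5: no clinical events at all (demographics only; never counted)
    * p6: b, c

    In-window expected values (see :func:`worked_example_expected`):
    N_P = 4; singles a:3 b:3 c:2; pairs (a,b):2, (a,c):1, (b,c):2 —
    plus demographic singles/pairs for FEMALE (8532) and MALE (8507).
    """
    person = pd.DataFrame(
        {
            "person_id": [1, 2, 3, 4, 5, 6],
            "gender_concept_id": [8532, 8507, 8532, 8507, 8532, 0],
            "race_concept_id": [0, 0, 0, 0, 0, 0],
            "ethnicity_concept_id": [0, 0, 0, 0, 0, 0],
        }
    )
    condition = pd.DataFrame(
        {
            "person_id": [1, 1, 1, 2, 2, 3, 6],
            "condition_concept_id": [101, 101, 102, 101, 102, 101, 102],
            "condition_start_date": [
                "2013-05-01", "2014-06-01", "2015-07-01", "2013-08-01",
                "2016-09-01", "2017-10-01", "2013-11-01",
            ],
        }
    )
    drug = pd.DataFrame(
        {
            "person_id": [2, 4, 6],
            "drug_concept_id": [201, 201, 201],
            "drug_exposure_start_date": ["2014-03-15", "2012-06-30", "2015-01-20"],
        }
    )
    procedure = pd.DataFrame(
        {
            "person_id": pd.Series(dtype=int),
            "procedure_concept_id": pd.Series(dtype=int),
            "procedure_date": pd.Series(dtype=str),
        }
    )
    concept = pd.DataFrame(
        [
            (101, "Synthetic condition a", "Condition", "SyntheticVocab", "Clinical Finding", "SYN-a"),
            (102, "Synthetic condition b", "Condition", "SyntheticVocab", "Clinical Finding", "SYN-b"),
            (201, "Synthetic drug c", "Drug", "SyntheticVocab", "Clinical Drug", "SYN-c"),
            (8532, "FEMALE", "Gender", "SyntheticVocab", "Gender", "SYN-F"),
            (8507, "MALE", "Gender", "SyntheticVocab", "Gender", "SYN-M"),
        ],
        columns=CONCEPT_COLUMNS,
    )
    return person, condition, drug, procedure, concept


#: Brute-force enumerated expectations for :func:`worked_example_cohort`
#: restricted to the [2013-01-01, 2017-12-31] window.  Patient sets:
#: p1 {101,102,8532}, p2 {101,102,201,8507}, p3 {101,8532}, p6 {102,201}.
WORKED_EXAMPLE_WINDOW = (date(2013, 1, 1), date(2017, 12, 31))
WORKED_EXAMPLE_EXPECTED = {
    "n_p": 4,
    "singles": {101: 3, 102: 3, 201: 2, 8532: 2, 8507: 1},
    "pairs": {
        (101, 102): 2,
        (101, 201): 1,
        (101, 8507): 1,
        (101, 8532): 2,
        (102, 201): 2,
        (102, 8507): 1,
        (102, 8532): 1,
        (201, 8507): 1,
    },
}
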