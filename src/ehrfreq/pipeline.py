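"""End-to-end orchestration: OMOP tables → released dataset tables → bundle.

``build_dataset`` runs the whole chain for one window: patient concept
sets → true single/pair counts → iatrogenic removal → rare-count
exclusion → Poisson randomization → annual-deviation statistics.  The
pipeline order is fixed; exclusion always precedes randomization so λ is
always above the threshold, and randomized values are never re-filtered.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable

import pandas as pd

from ehrfreq.cohd_files import CohdBundle, DatasetTables
from ehrfreq.cooccurrence import (
    annual_deviations,
    build_patient_concepts,
    count_pairs,
    count_singles,
)
from ehrfreq.omop_io import Concept
from ehrfreq.privacy import (
    PrivacyConfig,
    exclude_iatrogenic,
    exclude_rare,
    poisson_randomize,
)


def build_dataset(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    dataset_id: str,
    config: PrivacyConfig,
    window: tuple[date, date] | None = None,
    full_years: Iterable[int] = (),
    iatrogenic_ids: set[int] | None = None,
    with_deviations: bool = True,
) -> DatasetTables:
    """Build the released tables of one dataset window.

    ``full_years`` lists the calendar years fully covered by data; annual
    deviations are computed over them (skipped entirely when empty or
    ``with_deviations`` is False).
    """
    iatrogenic_ids = iatrogenic_ids or set()
    full_years = tuple(full_years)

    pcm, metadata = build_patient_concepts(
        events, persons, window=window, dataset_id=dataset_id, full_years=full_years
    )
    singles = count_singles(pcm, metadata)
    pairs = count_pairs(pcm, metadata)

    singles, pairs = exclude_iatrogenic(singles, pairs, iatrogenic_ids)
    singles = exclude_rare(singles, config.min_count_threshold)
    pairs = exclude_rare(pairs, config.min_count_threshold)
    n_p = metadata.patient_count
    singles = poisson_randomize(singles, config.seed, dataset_id=dataset_id, n_p=n_p)
    pairs = poisson_randomize(pairs, config.seed, dataset_id=dataset_id, n_p=n_p)

    single_dev = pair_dev = None
    if with_deviations and full_years:
        single_dev, pair_dev = annual_deviations(
            events, persons, full_years, config.seed, dataset_id=dataset_id
        )
        # deviations are released for retained concepts/pairs only
        single_dev = single_dev[single_dev["concept_id"].isin(singles["concept_id"])]
        keys = set(zip(pairs["concept_id_1"], pairs["concept_id_2"]))
        mask = [
            (c1, c2) in keys
            for c1, c2 in zip(pair_dev["concept_id_1"], pair_dev["concept_id_2"])
        ]
        pair_dev = pair_dev[mask].reset_index(drop=True)
        single_dev = single_dev.reset_index(drop=True)

    return DatasetTables(
        metadata=metadata,
        singles=singles,
        pairs=pairs,
        single_deviations=single_dev,
        pair_deviations=pair_dev,
    )


def build_bundle(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    concepts: dict[int, Concept],
    config: PrivacyConfig,
    windows: dict[str, tuple[date, date] | None] | None = None,
    full_years: dict[str, Iterable[int]] | None = None,
    iatrogenic_ids: set[int] | None = None,
    with_deviations: bool = True,
) -> CohdBundle:
    """Build a complete bundle over one or more dataset windows.

    ``windows`` defaults to a single unrestricted ``lifetime`` dataset;
    the conventional release pairs it with a ``5year`` window.
    """
    if windows is None:
        windows = {"lifetime": None}
    full_years = full_years or {}
    bundle = CohdBundle(concepts=dict(concepts))
    for dataset_id, window in windows.items():
        bundle.datasets[dataset_id] = build_dataset(
            events,
            persons,
            dataset_id,
            config,
            window=window,
            full_years=full_years.get(dataset_id, ()),
            iatrogenic_ids=iatrogenic_ids,
            with_deviations=with_deviations,
        )
    return bundle
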