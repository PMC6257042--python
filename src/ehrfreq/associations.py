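"""Concept-association measures over released co-occurrence counts.

Three complementary views of the dependence between concepts C1 and C2,
all computable from the released single counts (N1, N2), the pair count
(N12) and the dataset patient count (N_P):

* chi-square — Pearson test of independence on the implied 2×2 patient
  contingency table, df = 1, no continuity correction.  Sensitive at
  large N_P: statistical significance does not imply scientific relevance.
* relative frequency — ``FR(C1|C2) = N12 / N2``, the empirical analogue
  of the conditional probability of C1 given C2.  With true counts
  FR ≤ 1; because singles and pairs are Poisson-randomized independently,
  released FR can exceed 1.
* observed/expected log ratio — ``LR = ln(N12 · N_P / (N1 · N2))``, the
  natural log of the observed pair count over the count expected under
  independence (``N1·N2/N_P``).  Positive LR means the pair co-occurs
  more often than independence predicts; LR is symmetric in C1 and C2.

Queries (``most_frequent``, ``top_associated``) operate on released
(post-privacy) tables; ranking ties are broken by ascending concept id
so results are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ehrfreq.errors import (
    InconsistentCountsError,
    NotFoundError,
    UndefinedStatisticError,
)
from ehrfreq.omop_io import Concept


@dataclass(frozen=True)
class AssociationResult:
    """All association measures for one concept pair."""

    concept_id_1: int
    concept_id_2: int
    pair_count: float
    chi2: float
    p_value: float
    relative_frequency: float
    log_ratio: float
    expected_count: float


def relative_frequency(n12: float, n2: float) -> float:
    """``FR(C1|C2) = n12 / n2`` — how often C1 occurs among patients with C2."""
    if n2 <= 0:
        raise UndefinedStatisticError(
            "relative frequency undefined: base concept count is 0"
        )
    if n12 < 0:
        raise UndefinedStatisticError(f"negative pair count {n12}")
    return n12 / n2


def expected_count(n1: float, n2: float, n_p: float) -> float:
    """Pair count expected under independence: ``n1 * n2 / n_p``."""
    if n_p <= 0:
        raise UndefinedStatisticError("expected count undefined: N_P is 0")
    return n1 * n2 / n_p


def log_ratio(n12: float, n1: float, n2: float, n_p: float) -> float:
    """``LR = ln(n12 * n_p / (n1 * n2))`` — observed/expected log ratio."""
    if min(n1, n2, n_p) <= 0:
        raise UndefinedStatisticError("log ratio undefined: a marginal count is 0")
    if n12 <= 0:
        raise UndefinedStatisticError(
            "log ratio undefined for a zero pair count (ln 0)"
        )
    return math.log(n12 * n_p / (n1 * n2))


def chi_square(n12: float, n1: float, n2: float, n_p: float) -> tuple[float, float]:
    """Pearson chi-square of independence on the implied 2×2 table.

    The table cells are [[n12, n1-n12], [n2-n12, n_p-n1-n2+n12]] — patients
    with both concepts, with C1 only, with C2 only, and with neither.
    True counts always yield non-negative cells; randomized counts may
    not, in which case :class:`InconsistentCountsError` is raised naming
    the offending cell.  Returns ``(statistic, p_value)`` with df = 1 and
    no continuity correction.
    """
    cells = {
        "both": n12,
        "c1_only": n1 - n12,
        "c2_only": n2 - n12,
        "neither": n_p - n1 - n2 + n12,
    }
    for name, value in cells.items():
        if value < 0:
            raise InconsistentCountsError(
                f"contingency cell {name!r} is negative ({value}); "
                "counts are mutually inconsistent"
            )
    table = np.array(
        [[cells["both"], cells["c1_only"]], [cells["c2_only"], cells["neither"]]],
        dtype=float,
    )
    statistic, p_value, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p_value)


def associate(
    n12: float, n1: float, n2: float, n_p: float,
    concept_id_1: int = 0, concept_id_2: int = 0,
) -> AssociationResult:
    """Compute all association measures for one pair from its four counts."""
    chi2, p_value = chi_square(n12, n1, n2, n_p)
    return AssociationResult(
        concept_id_1=concept_id_1,
        concept_id_2=concept_id_2,
        pair_count=n12,
        chi2=chi2,
        p_value=p_value,
        relative_frequency=relative_frequency(n12, n2),
        log_ratio=log_ratio(n12, n1, n2, n_p),
        expected_count=expected_count(n1, n2, n_p),
    )


def most_frequent(
    singles: pd.DataFrame,
    concepts: dict[int, Concept],
    domain: str | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Top-``k`` concepts by count, optionally restricted to one domain.

    Rows are ordered by descending count, ties by ascending concept_id.
    Returns (concept_id, concept_name, domain_id, count, prevalence).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    valid_domains = sorted({c.domain_id for c in concepts.values()})
    if domain is not None and domain not in valid_domains:
        raise NotFoundError(
            f"unknown domain {domain!r}; valid domains: {valid_domains}"
        )
    frame = singles.copy()
    frame["concept_name"] = frame["concept_id"].map(
        lambda cid: concepts[cid].concept_name if cid in concepts else ""
    )
    frame["domain_id"] = frame["concept_id"].map(
        lambda cid: concepts[cid].domain_id if cid in concepts else ""
    )
    if domain is not None:
        frame = frame[frame["domain_id"] == domain]
    frame = frame.sort_values(
        ["count", "concept_id"], ascending=[False, True]
    ).head(k)
    columns = ["concept_id", "concept_name", "domain_id", "count", "prevalence"]
    return frame[columns].reset_index(drop=True)


def top_associated(
    pairs: pd.DataFrame,
    singles: pd.DataFrame,
    anchor: int,
    n_p: int,
    concepts: dict[int, Concept] | None = None,
    domain: str | None = None,
    metric: str = "count",
    k: int = 10,
) -> list[AssociationResult]:
    """Partners of ``anchor`` ranked by a chosen association metric.

    ``metric`` is one of ``count`` (raw pair count), ``relative_frequency``
    (FR(anchor | partner): among patients with the partner concept, the
    fraction also observed with the anchor), or ``log_ratio``.  The partner
    list may be restricted to one domain when a concept dictionary is
    given.  Ranking is descending by metric, ties by ascending partner id.
    """
    if metric not in ("count", "relative_frequency", "log_ratio"):
        raise ValueError(f"unknown metric {metric!r}")
    single_index = dict(zip(singles["concept_id"].astype(int), singles["count"]))
    if anchor not in single_index:
        raise NotFoundError(f"concept {anchor} not present in released single counts")

    mask = (pairs["concept_id_1"] == anchor) | (pairs["concept_id_2"] == anchor)
    results: list[AssociationResult] = []
    for row in pairs[mask].itertuples(index=False):
        partner = int(row.concept_id_2 if row.concept_id_1 == anchor else row.concept_id_1)
        if domain is not None:
            if concepts is None:
                raise ValueError("domain filtering requires a concept dictionary")
            if partner not in concepts or concepts[partner].domain_id != domain:
                continue
        if partner not in single_index:
            continue
        n12 = float(row.count)
        n_anchor = float(single_index[anchor])
        n_partner = float(single_index[partner])
        try:
            chi2, p_value = chi_square(n12, n_anchor, n_partner, n_p)
        except InconsistentCountsError:
            chi2, p_value = float("nan"), float("nan")
        results.append(
            AssociationResult(
                concept_id_1=anchor,
                concept_id_2=partner,
                pair_count=n12,
                chi2=chi2,
                p_value=p_value,
                relative_frequency=relative_frequency(n12, n_partner),
                log_ratio=log_ratio(n12, n_anchor, n_partner, n_p)
                if n12 > 0 else float("nan"),
                expected_count=expected_count(n_anchor, n_partner, n_p),
            )
        )

    def sort_key(result: AssociationResult) -> tuple[float, int]:
        value = {
            "count": result.pair_count,
            "relative_frequency": result.relative_frequency,
            "log_ratio": result.log_ratio,
        }[metric]
        if isinstance(value, float) and math.isnan(value):
            value = -math.inf
        return (-value, result.concept_id_2)

    return sorted(results, key=sort_key)[:k]
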