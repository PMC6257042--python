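"""Disclosure-protection pipeline for released counts.

The release pipeline is fixed: (1) remove iatrogenic concepts, (2) exclude
rare counts (``count <= threshold``, threshold 10 by default), (3) replace
every remaining count with one draw from a Poisson distribution whose mean
λ equals the true count.  Exclusion happens before randomization, so λ is
always > threshold; randomized values of any non-negative size (including
values ≤ 10) are retained, because re-excluding them would bias the
released count distribution.

Randomization draws are keyed per (master seed, dataset id, concept key),
so the draw for a given count does not depend on table ordering or on the
other rows present.

``randomization_impact`` quantifies how often randomization makes a
released count significantly different from its true value, using a
one-degree-of-freedom Pearson goodness-of-fit statistic
``(randomized - true)^2 / true``; for calibrated Poisson noise the
significant fraction converges to the test's alpha as λ grows.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ehrfreq.errors import EhrFreqError

DEFAULT_MIN_COUNT = 10


@dataclass(frozen=True)
class PrivacyConfig:
    """Parameters of the disclosure-protection pipeline.

    ``min_count_threshold``: counts ≤ this value are excluded (default 10).
    ``seed``: master seed for Poisson randomization.
    ``alpha``: significance level used by the impact validation (default 0.05).
    """

    min_count_threshold: int = DEFAULT_MIN_COUNT
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_count_threshold < 0:
            raise ValueError("min_count_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def exclude_iatrogenic(
    singles: pd.DataFrame,
    pairs: pd.DataFrame,
    iatrogenic_ids: set[int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop iatrogenic concepts from the single table and any pair containing one."""
    if not iatrogenic_ids:
        return singles.copy(), pairs.copy()
    singles_out = singles[~singles["concept_id"].isin(iatrogenic_ids)]
    pairs_out = pairs[
        ~pairs["concept_id_1"].isin(iatrogenic_ids)
        & ~pairs["concept_id_2"].isin(iatrogenic_ids)
    ]
    return singles_out.reset_index(drop=True), pairs_out.reset_index(drop=True)


def exclude_rare(counts: pd.DataFrame, threshold: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Drop rows whose true count is ≤ ``threshold`` (boundary excluded)."""
    return counts[counts["count"] > threshold].reset_index(drop=True)


def _row_seed(master_seed: int, dataset_id: str, key: tuple[int, ...]) -> np.random.Generator:
    entropy = [master_seed & 0xFFFFFFFF, zlib.crc32(dataset_id.encode("utf-8")), *key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def poisson_randomize(
    counts: pd.DataFrame,
    seed: int,
    dataset_id: str = "",
    n_p: int | None = None,
) -> pd.DataFrame:
    """Replace each count with one Poisson draw with λ = the true count.

    The draw for each row is keyed by (seed, dataset_id, concept key), so
    the result is deterministic and independent of row order.  Single and
    pair tables are randomized independently, which is why released
    relative frequencies can exceed 1.  When ``n_p`` is given, the
    ``prevalence`` column is recomputed from the randomized counts.
    """
    key_columns = [c for c in ("concept_id", "concept_id_1", "concept_id_2")
                   if c in counts.columns]
    if not key_columns:
        raise EhrFreqError("counts table has no concept-id key columns")
    out = counts.copy()
    lam = out["count"].to_numpy()
    if (lam < 0).any():
        raise EhrFreqError("negative count cannot be used as a Poisson mean")
    keys = out[key_columns].to_numpy()
    draws = np.empty(len(out), dtype=np.int64)
    for i, (key, lam_i) in enumerate(zip(keys, lam)):
        rng = _row_seed(seed, dataset_id, tuple(int(k) for k in key))
        draws[i] = rng.poisson(lam_i)
    out["count"] = draws
    if n_p is not None and "prevalence" in out.columns:
        out["prevalence"] = out["count"] / n_p
    return out


def randomization_impact(
    true_counts: pd.DataFrame | np.ndarray,
    randomized_counts: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
) -> tuple[int, int, float]:
    """Fraction of randomized counts significantly different from the truth.

    Applies the Pearson one-cell goodness-of-fit statistic
    ``(O - E)^2 / E`` with ``E`` the true count and ``O`` the randomized
    count, compared against the chi-square(1) critical value at ``alpha``
    (no continuity correction).

    Accepts either aligned count tables (matched on their concept-id key
    columns) or bare arrays of equal length.

    Returns ``(n_significant, n_total, fraction)``.
    """
    if isinstance(true_counts, pd.DataFrame) and isinstance(randomized_counts, pd.DataFrame):
        key_columns = [c for c in ("concept_id", "concept_id_1", "concept_id_2")
                       if c in true_counts.columns]
        merged = true_counts[key_columns + ["count"]].merge(
            randomized_counts[key_columns + ["count"]],
            on=key_columns,
            how="inner",
            suffixes=("_true", "_rand"),
        )
        if len(merged) != len(true_counts) or len(merged) != len(randomized_counts):
            raise EhrFreqError(
                f"tables not aligned: {len(true_counts)} true vs "
                f"{len(randomized_counts)} randomized items, {len(merged)} shared keys"
            )
        true_values = merged["count_true"].to_numpy(dtype=float)
        rand_values = merged["count_rand"].to_numpy(dtype=float)
    else:
        true_values = np.asarray(true_counts, dtype=float)
        rand_values = np.asarray(randomized_counts, dtype=float)
        if len(true_values) != len(rand_values):
            raise EhrFreqError(
                f"arrays not aligned: {len(true_values)} true vs "
                f"{len(rand_values)} randomized items"
            )
    if len(true_values) == 0:
        return 0, 0, 0.0
    if (true_values <= 0).any():
        raise EhrFreqError("true counts must be positive for the goodness-of-fit test")
    statistic = (rand_values - true_values) ** 2 / true_values
    critical = stats.chi2.ppf(1.0 - alpha, df=1)
    n_significant = int((statistic > critical).sum())
    return n_significant, len(true_values), n_significant / len(true_values)
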