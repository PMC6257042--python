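"""Association measures: relative frequency, log ratio, chi-square, ranked queries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ehrfreq.associations import (
    chi_square,
    expected_count,
    log_ratio,
    most_frequent,
    relative_frequency,
    top_associated,
)
from ehrfreq.errors import (
    InconsistentCountsError,
    NotFoundError,
    UndefinedStatisticError,
)
from ehrfreq.omop_io import Concept


def _concept(cid, name, domain):
    return Concept(cid, name, domain, "V", "K", str(cid))


class TestRelativeFrequency:
    @pytest.mark.parametrize(
        "n12,n2,expected,decimals",
        [
            (15, 11, 1.364, 3),        # idarucizumab | atrial fibrillation
            (45, 37, 1.216, 3),        # dronedarone | atrial fibrillation
            (16, 13, 1.23076923, 8),   # gastrostomy hemorrhage | albuterol
            (191, 183, 1.043715846, 9),
        ],
    )
    def test_reported_values(self, n12, n2, expected, decimals):
        # published renderings round in one table and truncate in another;
        # agree within one unit of the last printed digit
        assert abs(relative_frequency(n12, n2) - expected) < 10 ** -decimals

    def test_whole_base_pair(self):
        assert relative_frequency(31, 31) == 1.0

    def test_zero_base_raises(self):
        with pytest.raises(UndefinedStatisticError):
            relative_frequency(5, 0)


class TestLogRatio:
    def test_zero_at_exact_independence(self):
        assert log_ratio(10, 100, 100, 1000) == pytest.approx(0.0)

    def test_positive_association_closed_form(self):
        assert log_ratio(100, 100, 100, 1000) == pytest.approx(math.log(10))

    def test_negative_association_closed_form(self):
        assert log_ratio(1, 100, 100, 1000) == pytest.approx(math.log(0.1))

    def test_zero_pair_count_signalled(self):
        with pytest.raises(UndefinedStatisticError, match="ln 0"):
            log_ratio(0, 100, 100, 1000)

    def test_symmetric_in_concepts(self):
        assert log_ratio(7, 20, 50, 400) == pytest.approx(log_ratio(7, 50, 20, 400))

    def test_expected_count_formula(self):
        assert expected_count(100, 100, 1000) == pytest.approx(10.0)


class TestChiSquare:
    def test_zero_at_independence(self):
        statistic, p = chi_square(10, 100, 100, 1000)
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_derived_fixture_value(self):
        """Cells (50,50,50,850), expected (10,90,90,810):
        160 + 17.78 + 17.78 + 1.98 = 197.53."""
        statistic, p = chi_square(50, 100, 100, 1000)
        assert round(statistic, 2) == 197.53
        assert p == pytest.approx(stats.chi2.sf(statistic, df=1))

    def test_matches_brute_force_pearson(self):
        """Cross-check against explicit (O-E)²/E over the 2×2 cells."""
        n12, n1, n2, n_p = 37, 120, 85, 5000
        cells = np.array([[n12, n1 - n12], [n2 - n12, n_p - n1 - n2 + n12]], float)
        expected = np.outer(cells.sum(1), cells.sum(0)) / cells.sum()
        brute = ((cells - expected) ** 2 / expected).sum()
        assert chi_square(n12, n1, n2, n_p)[0] == pytest.approx(brute)

    def test_negative_cell_named(self):
        with pytest.raises(InconsistentCountsError, match="c1_only"):
            chi_square(60, 50, 100, 1000)


@pytest.fixture
def toy_release():
    singles = pd.DataFrame(
        {"concept_id": [1, 2, 3, 4], "count": [50, 100, 20, 40],
         "prevalence": [0.05, 0.10, 0.02, 0.04]}
    )
    pairs = pd.DataFrame(
        [(1, 2, 30), (1, 3, 20), (1, 4, 10)],
        columns=["concept_id_1", "concept_id_2", "count"],
    )
    concepts = {
        1: _concept(1, "Anchor condition", "Condition"),
        2: _concept(2, "Common drug", "Drug"),
        3: _concept(3, "Specific drug", "Drug"),
        4: _concept(4, "Procedure x", "Procedure"),
    }
    return singles, pairs, concepts


class TestMostFrequent:
    def test_ranked_with_id_tie_break(self):
        singles = pd.DataFrame(
            {"concept_id": [10, 20, 30], "count": [5, 9, 9],
             "prevalence": [0.05, 0.09, 0.09]}
        )
        concepts = {c: _concept(c, f"c{c}", "Condition") for c in (10, 20, 30)}
        top = most_frequent(singles, concepts, k=2)
        assert list(top["concept_id"]) == [20, 30]

    def test_k_zero_empty(self, toy_release):
        singles, _, concepts = toy_release
        assert len(most_frequent(singles, concepts, k=0)) == 0

    def test_domain_filter(self, toy_release):
        singles, _, concepts = toy_release
        top = most_frequent(singles, concepts, domain="Drug", k=10)
        assert set(top["concept_id"]) == {2, 3}

    def test_unknown_domain_lists_valid(self, toy_release):
        singles, _, concepts = toy_release
        with pytest.raises(NotFoundError, match="Condition"):
            most_frequent(singles, concepts, domain="Banana")


class TestTopAssociated:
    def test_relative_frequency_conditions_on_partner(self, toy_release):
        """FR(anchor | partner): partner 3 (20/20 = 1.0) outranks partner 2 (30/100)."""
        singles, pairs, concepts = toy_release
        results = top_associated(pairs, singles, anchor=1, n_p=1000,
                                 concepts=concepts, metric="relative_frequency", k=2)
        assert [r.concept_id_2 for r in results] == [3, 2]
        assert results[0].relative_frequency == pytest.approx(1.0)
        assert results[1].relative_frequency == pytest.approx(0.30)

    def test_count_metric_dominated_by_prevalent_partner(self, toy_release):
        """Raw pair counts rank the common partner first even though the
        specific partner is the stronger association."""
        singles, pairs, concepts = toy_release
        by_count = top_associated(pairs, singles, anchor=1, n_p=1000, metric="count")
        by_fr = top_associated(pairs, singles, anchor=1, n_p=1000,
                               metric="relative_frequency")
        assert by_count[0].concept_id_2 == 2
        assert by_fr[0].concept_id_2 == 3

    def test_domain_filter_restricts_partners(self, toy_release):
        singles, pairs, concepts = toy_release
        results = top_associated(pairs, singles, anchor=1, n_p=1000,
                                 concepts=concepts, domain="Procedure")
        assert [r.concept_id_2 for r in results] == [4]

    def test_unknown_anchor_raises(self, toy_release):
        singles, pairs, _ = toy_release
        with pytest.raises(NotFoundError):
            top_associated(pairs, singles, anchor=999, n_p=1000)

    def test_anchor_without_pairs_empty(self, toy_release):
        singles, pairs, _ = toy_release
        assert top_associated(pairs, singles, anchor=2, n_p=1000,
                              metric="log_ratio") != []  # pair (1,2) includes anchor 2
        lonely = pd.DataFrame(columns=["concept_id_1", "concept_id_2", "count"])
        assert top_associated(lonely, singles, anchor=2, n_p=1000) == []


class TestIdentities:
    def test_fr_antisymmetry_identity(self, worked_example_bundle):
        """FR(C1|C2)·N2 = FR(C2|C1)·N1 = N12 exactly, on released tables."""
        tables = worked_example_bundle.datasets["5year"]
        singles = dict(zip(tables.singles["concept_id"], tables.singles["count"]))
        for row in tables.pairs.itertuples(index=False):
            n1, n2 = singles[row.concept_id_1], singles[row.concept_id_2]
            if n1 == 0 or n2 == 0:
                continue
            fr12 = relative_frequency(row.count, n2)
            fr21 = relative_frequency(row.count, n1)
            assert fr12 * n2 == pytest.approx(row.count)
            assert fr21 * n1 == pytest.approx(row.count)

    def test_lr_sign_tracks_observed_vs_expected(self):
        for n12, n1, n2, n_p in [(100, 100, 100, 1000), (1, 100, 100, 1000)]:
            lr = log_ratio(n12, n1, n2, n_p)
            assert (lr > 0) == (n12 > expected_count(n1, n2, n_p))

    def test_injected_odds_ratio_drives_lr_sign(self):
        """Synthetic pair with odds ratio 4 shows LR > 0; an independent pair ≈ 0."""
        from ehrfreq.synthetic_cohort import CohortSpec, generate_cohort

        spec = CohortSpec(
            n_patients=10_000, seed=17,
            concept_catalog=((1, "Condition", 0.2), (2, "Drug", 0.2),
                             (3, "Condition", 0.2), (4, "Drug", 0.2)),
            dependence_list=((1, 2, 4.0), (3, 4, 1.0)),
        )
        person, cond, drug, _, _ = generate_cohort(spec)
        sets = {
            1: set(cond[cond["condition_concept_id"] == 1]["person_id"]),
            3: set(cond[cond["condition_concept_id"] == 3]["person_id"]),
            2: set(drug[drug["drug_concept_id"] == 2]["person_id"]),
            4: set(drug[drug["drug_concept_id"] == 4]["person_id"]),
        }
        lr_dep = log_ratio(len(sets[1] & sets[2]), len(sets[1]), len(sets[2]), 10_000)
        lr_ind = log_ratio(len(sets[3] & sets[4]), len(sets[3]), len(sets[4]), 10_000)
        assert lr_dep > 0.5
        assert abs(lr_ind) < 0.2
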