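"""Reading OMOP-shaped delimited extracts and auxiliary lists."""

import pandas as pd
import pytest

from ehrfreq.errors import IntegrityError, RowError, SchemaError
from ehrfreq.omop_io import (
    CONCEPT_COLUMNS,
    load_iatrogenic_codes,
    match_iatrogenic,
    read_concepts,
    read_events,
    read_persons,
    write_concepts,
)


def _concept_file(path, rows):
    pd.DataFrame(rows, columns=CONCEPT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


class TestReadConcepts:
    def test_single_row_maps_by_id(self, tmp_path):
        path = _concept_file(
            tmp_path / "c.txt",
            [(313217, "Atrial fibrillation", "Condition", "SNOMED",
              "Clinical Finding", "49436004")],
        )
        concepts = read_concepts(path)
        assert set(concepts) == {313217}
        assert concepts[313217].concept_name == "Atrial fibrillation"
        assert concepts[313217].domain_id == "Condition"

    def test_header_only_file_yields_empty_dict(self, tmp_path):
        path = _concept_file(tmp_path / "c.txt", [])
        assert read_concepts(path) == {}

    def test_duplicate_concept_id_raises(self, tmp_path):
        rows = [(1, "A", "Condition", "V", "K", "x"),
                (1, "B", "Condition", "V", "K", "y")]
        path = _concept_file(tmp_path / "c.txt", rows)
        with pytest.raises(IntegrityError, match="duplicate concept_id 1"):
            read_concepts(path)

    def test_missing_column_names_it(self, tmp_path):
        frame = pd.DataFrame({"concept_id": [1], "concept_name": ["A"]})
        path = tmp_path / "c.txt"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="domain_id"):
            read_concepts(path)

    @pytest.mark.parametrize("policy,expect_len", [("truncate", 255), ("error", None)])
    def test_long_name_policy(self, tmp_path, policy, expect_len):
        name = "x" * 300
        path = _concept_file(
            tmp_path / "c.txt", [(5, name, "Condition", "V", "K", "c")]
        )
        if expect_len is None:
            with pytest.raises(IntegrityError, match="255"):
                read_concepts(path, long_names=policy)
        else:
            concepts = read_concepts(path, long_names=policy)
            assert len(concepts[5].concept_name) == expect_len

    def test_write_read_round_trip(self, tmp_path):
        path = _concept_file(
            tmp_path / "c.txt",
            [(2, "B", "Drug", "RxNorm", "Clinical Drug", "b1"),
             (1, "A", "Condition", "SNOMED", "Clinical Finding", "a1")],
        )
        concepts = read_concepts(path)
        out = tmp_path / "copy.txt"
        write_concepts(concepts, out)
        assert read_concepts(out) == concepts

    def test_comma_dialect(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            [(1, "A", "Condition", "V", "K", "x")], columns=CONCEPT_COLUMNS
        ).to_csv(path, index=False)
        assert set(read_concepts(path, delimiter=",")) == {1}


class TestReadEvents:
    def _event_file(self, path, rows, id_col="condition_concept_id",
                    date_col="condition_start_date"):
        pd.DataFrame(rows, columns=["person_id", id_col, date_col]).to_csv(
            path, sep="\t", index=False
        )
        return path

    def test_rows_become_events_with_source_table(self, tmp_path):
        path = self._event_file(
            tmp_path / "e.txt",
            [(1, 101, "2013-01-02"), (2, 102, "2014-03-04"), (1, 103, "2015-05-06")],
        )
        events, report = read_events(path, "condition")
        assert len(events) == 3
        assert set(events["source_table"]) == {"condition"}
        assert report.rows_kept == 3

    def test_zero_concept_rows_dropped_and_tallied(self, tmp_path):
        path = self._event_file(
            tmp_path / "e.txt", [(1, 0, "2013-01-02"), (1, 101, "2013-01-03")]
        )
        events, report = read_events(path, "condition")
        assert len(events) == 1
        assert report.dropped_zero_concept == 1
        assert report.rows_read == report.rows_kept + 1

    def test_invalid_date_fail_policy_names_row(self, tmp_path):
        path = self._event_file(
            tmp_path / "e.txt", [(1, 101, "2013-01-02"), (2, 102, "2014-02-30")]
        )
        with pytest.raises(RowError, match="line 3"):
            read_events(path, "condition", bad_dates="fail")

    def test_invalid_date_skip_policy_tallies(self, tmp_path):
        path = self._event_file(
            tmp_path / "e.txt", [(1, 101, "2013-01-02"), (2, 102, "not-a-date")]
        )
        events, report = read_events(path, "condition", bad_dates="skip")
        assert len(events) == 1
        assert report.dropped_bad_date == 1

    def test_datetime_truncated_to_date(self, tmp_path):
        path = self._event_file(tmp_path / "e.txt", [(1, 101, "2013-01-02 13:45:00")])
        events, _ = read_events(path, "condition")
        assert str(events["event_date"].iloc[0]) == "2013-01-02"

    def test_table_specific_columns(self, tmp_path):
        path = self._event_file(
            tmp_path / "d.txt", [(1, 201, "2013-06-01")],
            id_col="drug_concept_id", date_col="drug_exposure_start_date",
        )
        events, _ = read_events(path, "drug")
        assert events["concept_id"].iloc[0] == 201

    def test_unknown_source_table_rejected(self, tmp_path):
        path = self._event_file(tmp_path / "e.txt", [(1, 101, "2013-01-02")])
        with pytest.raises(ValueError, match="source_table"):
            read_events(path, "visit")


class TestReadPersons:
    def test_distinct_persons(self, tmp_path):
        path = tmp_path / "p.txt"
        pd.DataFrame(
            {"person_id": [1, 2], "gender_concept_id": [8532, 8507],
             "race_concept_id": [0, 8527], "ethnicity_concept_id": [0, 0]}
        ).to_csv(path, sep="\t", index=False)
        persons = read_persons(path)
        assert list(persons["person_id"]) == [1, 2]

    def test_duplicate_person_id_raises(self, tmp_path):
        path = tmp_path / "p.txt"
        pd.DataFrame(
            {"person_id": [1, 1], "gender_concept_id": [8532, 8507],
             "race_concept_id": [0, 0], "ethnicity_concept_id": [0, 0]}
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(IntegrityError, match="duplicate person_id 1"):
            read_persons(path)

    def test_all_zero_demographics_kept(self, tmp_path):
        path = tmp_path / "p.txt"
        pd.DataFrame(
            {"person_id": [9], "gender_concept_id": [0],
             "race_concept_id": [0], "ethnicity_concept_id": [0]}
        ).to_csv(path, sep="\t", index=False)
        persons = read_persons(path)
        assert len(persons) == 1
        assert persons.iloc[0]["gender_concept_id"] == 0


class TestIatrogenicCodes:
    def test_pairs_loaded(self, tmp_path):
        path = tmp_path / "iat.txt"
        path.write_text("ICD9CM\t996.82\n")
        assert load_iatrogenic_codes(path) == {("ICD9CM", "996.82")}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "iat.txt"
        path.write_text("")
        assert load_iatrogenic_codes(path) == set()

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "iat.txt"
        path.write_text("ICD9CM\t996.82\nonly-one-field\n")
        with pytest.raises(RowError, match="line 2"):
            load_iatrogenic_codes(path)

    def test_match_resolves_ids_and_ignores_absent_codes(self, tmp_path):
        path = _concept_file(
            tmp_path / "c.txt",
            [(44515822, "Complication of transplanted liver", "Condition",
              "ICD9CM", "4-dig billing code", "996.82")],
        )
        concepts = read_concepts(path)
        codes = {("ICD9CM", "996.82"), ("ICD10CM", "T86.41")}
        assert match_iatrogenic(concepts, codes) == {44515822}


def test_event_tallies_reconcile_exactly(tmp_path):
    """rows read = kept + zero-concept drops + bad-date drops."""
    path = tmp_path / "e.txt"
    pd.DataFrame(
        {"person_id": [1, 2, 3, 4], "condition_concept_id": [101, 0, 102, 103],
         "condition_start_date": ["2013-01-01", "2013-01-02", "bad", "2013-01-04"]}
    ).to_csv(path, sep="\t", index=False)
    events, report = read_events(path, "condition", bad_dates="skip")
    assert report.rows_read == 4
    assert report.dropped_zero_concept == 1
    assert report.dropped_bad_date == 1
    assert len(events) == report.rows_kept == 2
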