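"""Data model, CSV round trip, packaged table integrity, and filtering."""

import dataclasses

import pytest

from mpvmeta import (
    StudyRecord,
    StudyTable,
    StudyValidationError,
    SchemaError,
    all_of,
    apd_recent_is,
    builtin_table,
    diagnosis_is,
    filter_studies,
    min_total_n,
    read_study_table,
    write_study_table,
)

DIAGNOSIS_COUNTS = {"depression": 6, "anxiety": 8, "bipolar": 4, "schizophrenia": 6}

# Studies whose total sample (both arms) is below 100 in the packaged table.
SMALL_STUDIES = {
    "Ataoglu", "Wang", "Ozturk", "Asoglu-PD", "GogcegozGul",
    "Kirlioglu", "Semiz", "Asoglu-SCZ", "Ali",
}


class TestBuiltinTable:
    def test_has_24_studies_with_published_group_sizes(self, table24):
        assert len(table24) == 24
        counts = {}
        for r in table24:
            counts[r.diagnosis] = counts.get(r.diagnosis, 0) + 1
        assert counts == DIAGNOSIS_COUNTS

    def test_participant_totals_match_published_abstract(self, table24):
        assert sum(r.n_case for r in table24) == 2450
        assert sum(r.n_control for r in table24) == 2393

    def test_mukta_is_the_only_study_without_ages(self, table24):
        missing = [r.study_id for r in table24 if r.age_case is None]
        assert missing == ["Mukta"]
        assert table24["Mukta"].age_control is None

    def test_unpublished_moderators_are_missing_throughout(self, table24):
        # per-study APD history, sex ratio and NOS score were not published
        for r in table24:
            assert r.apd_recent is None
            assert r.male_fraction is None
            assert r.nos_score is None

    def test_region_and_design_composition(self, table24):
        regions = {}
        for r in table24:
            regions[r.region] = regions.get(r.region, 0) + 1
        assert regions == {"Turkey": 16, "China": 3, "India": 3, "Bangladesh": 1, "Egypt": 1}
        designs = [r.design for r in table24]
        assert designs.count("case-control") == 19
        assert designs.count("cross-sectional") == 4
        assert designs.count("prospective-cohort") == 1


class TestRoundTrip:
    def test_write_then_read_is_identity(self, table24, tmp_path):
        path = tmp_path / "t.csv"
        write_study_table(table24, path)
        back = read_study_table(path)
        assert back.records == table24.records

    def test_missing_moderators_survive_round_trip(self, tmp_path):
        rec = StudyRecord("x", "anxiety", "Turkey", "case-control", "DSM-5",
                          20, 9.0, 1.0, 20, 8.5, 1.1,
                          age_case=None, male_fraction=0.4, apd_recent=True)
        path = tmp_path / "one.csv"
        write_study_table(StudyTable((rec,)), path)
        back = read_study_table(path)[0]
        assert back.age_case is None and back.age_control is None
        assert back.apd_recent is True
        assert back.male_fraction == pytest.approx(0.4)


class TestValidation:
    def test_zero_sd_is_rejected_with_row_number(self, table24, tmp_path):
        df = table24.to_frame()
        df.loc[0, "sd_case"] = 0.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False, na_rep="NA")
        with pytest.raises(StudyValidationError, match="row 2.*sd_case"):
            read_study_table(path)

    def test_missing_mandatory_column_names_the_column(self, table24, tmp_path):
        df = table24.to_frame().drop(columns=["n_control"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False, na_rep="NA")
        with pytest.raises(SchemaError, match="n_control"):
            read_study_table(path)

    def test_non_numeric_cell_reports_row_and_column(self, table24, tmp_path):
        df = table24.to_frame()
        df["mean_case"] = df["mean_case"].astype(object)
        df.loc[4, "mean_case"] = "??"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False, na_rep="NA")
        with pytest.raises(SchemaError, match="row 6.*mean_case"):
            read_study_table(path)

    def test_duplicate_study_id_rejected(self, table24):
        with pytest.raises(StudyValidationError, match="duplicate"):
            StudyTable(table24.records + (table24.records[0],))

    def test_single_subject_arm_rejected(self):
        rec = StudyRecord("x", "anxiety", "Turkey", "case-control", "DSM-5",
                          1, 9.0, 1.0, 20, 8.5, 1.1)
        assert any("n_case" in p for p in rec.validate())


class TestFilterStudies:
    def test_diagnosis_filter_matches_subgroup_sizes(self, table24):
        for dx, k in DIAGNOSIS_COUNTS.items():
            assert len(filter_studies(table24, diagnosis_is(dx))) == k

    def test_small_study_rule_excludes_exactly_the_small_ones(self, table24):
        kept = filter_studies(table24, min_total_n(100))
        assert set(table24.study_ids) - set(kept.study_ids) == SMALL_STUDIES
        assert all(r.n_total >= 100 for r in kept)

    def test_tautology_preserves_table(self, table24):
        same = filter_studies(table24, lambda r: True)
        assert same.records == table24.records

    def test_filter_is_idempotent_and_order_preserving(self, table24):
        rule = min_total_n(100)
        once = filter_studies(table24, rule)
        twice = filter_studies(once, rule)
        assert once.records == twice.records
        order = [table24.study_ids.index(s) for s in once.study_ids]
        assert order == sorted(order)

    def test_all_missing_moderator_predicate_errors(self, table24):
        with pytest.raises(StudyValidationError, match="apd_recent"):
            filter_studies(table24, apd_recent_is(False))

    def test_composite_predicate(self, table24):
        both = filter_studies(table24, all_of(diagnosis_is("anxiety"), min_total_n(100)))
        assert set(both.study_ids) == {
            "Almis", "Bondade", "Mukta", "Kokacya", "Ransing", "Yalamanchili"
        }
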