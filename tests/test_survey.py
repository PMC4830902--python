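"""Weighted survey tabulation: loading, joint categories, adoption series."""

import textwrap

import numpy as np
import pytest

from phrdiffusion import (
    AdoptionSeries,
    AdoptionTable,
    SurveyRecord,
    adoption_series,
    datasets,
    load_survey,
    tabulate_adoption,
)
from phrdiffusion.survey import EmptyYearError, SchemaError


def _write(tmp_path, text, name="survey.csv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


def _records_from_counts(year, counts):
    """One record per joint category whose weight is the published count."""
    answers = {
        "both_yes": ("yes", "yes"),
        "comm_only": ("no", "yes"),
        "track_only": ("yes", "no"),
        "both_no": ("no", "no"),
    }
    return [
        SurveyRecord(f"{year}-{cat}", year, float(counts[cat]), *answers[cat])
        for cat in counts
    ]


class TestLoadSurvey:
    def test_reads_rows_and_preserves_weights(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            respondent_id,survey_year,weight,item_track,item_comm
            a,2008,1,yes,no
            b,2008,2,No,YES
            c,2011,3,yes,yes
            """,
        )
        records = load_survey(path)
        assert [r.weight for r in records] == [1.0, 2.0, 3.0]
        assert records[1].item_track == "no" and records[1].item_comm == "yes"

    def test_empty_cell_is_missing(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            respondent_id,survey_year,weight,item_track,item_comm
            a,2008,1,yes,
            """,
        )
        assert load_survey(path)[0].item_comm == "missing"

    def test_missing_weight_column_is_schema_error(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            respondent_id,survey_year,item_track,item_comm
            a,2008,yes,no
            """,
        )
        with pytest.raises(SchemaError, match="weight"):
            load_survey(path)

    def test_negative_weight_names_row(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            respondent_id,survey_year,weight,item_track,item_comm
            a,2008,1,yes,no
            b,2008,-2,yes,no
            """,
        )
        with pytest.raises(ValueError, match="row 1"):
            load_survey(path)

    def test_year_out_of_range_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            """\
            respondent_id,survey_year,weight,item_track,item_comm
            a,1900,1,yes,no
            """,
        )
        with pytest.raises(ValueError, match="survey_year"):
            load_survey(path)


class TestTabulate:
    def test_reproduces_published_2008_tabulation(self):
        counts = datasets.HINTS_WEIGHTED_COUNTS[2008]
        table = tabulate_adoption(_records_from_counts(2008, counts), 2008)
        assert table.total == 152_602_082
        assert table.percent("both_yes") == pytest.approx(5.16, abs=0.005)

    def test_all_no_gives_degenerate_percentages(self):
        records = [SurveyRecord(str(i), 2008, 1.0, "no", "no") for i in range(4)]
        table = tabulate_adoption(records, 2008)
        assert table.percent("both_yes") == 0.0
        assert table.percent("both_no") == 100.0

    def test_hand_computed_weighted_fraction(self):
        weights = [10, 20, 30, 40, 50]
        both_yes_at = {20, 50}
        records = [
            SurveyRecord(
                str(w), 2011, float(w),
                "yes" if w in both_yes_at else "no",
                "yes" if w in both_yes_at else "no",
            )
            for w in weights
        ]
        table = tabulate_adoption(records, 2011)
        assert table.adoption_fraction == pytest.approx(70 / 150)

    def test_category_conservation_integer_weights(self):
        rng = np.random.default_rng(3)
        answers = [("yes", "yes"), ("no", "yes"), ("yes", "no"), ("no", "no")]
        records = [
            SurveyRecord(str(i), 2013, float(rng.integers(1, 50)), *answers[i % 4])
            for i in range(40)
        ]
        table = tabulate_adoption(records, 2013)
        assert (
            table.both_yes + table.comm_only + table.track_only + table.both_no
            == table.total
        )

    def test_scale_invariance_of_percentages(self):
        records = _records_from_counts(2011, datasets.HINTS_WEIGHTED_COUNTS[2011])
        scaled = [
            SurveyRecord(r.respondent_id, r.survey_year, 3.7 * r.weight,
                         r.item_track, r.item_comm)
            for r in records
        ]
        base = tabulate_adoption(records, 2011)
        rescaled = tabulate_adoption(scaled, 2011)
        for cat in ("both_yes", "comm_only", "track_only", "both_no"):
            assert rescaled.percent(cat) == pytest.approx(base.percent(cat), rel=1e-12)

    def test_missing_policies(self):
        records = [
            SurveyRecord("a", 2008, 1.0, "yes", "yes"),
            SurveyRecord("b", 2008, 1.0, "missing", "yes"),
        ]
        excl = tabulate_adoption(records, 2008, "exclude")
        as_no = tabulate_adoption(records, 2008, "treat_as_no")
        assert excl.total == 1.0 and excl.percent("both_yes") == 100.0
        assert as_no.total == 2.0 and as_no.count("comm_only") == 1.0

    def test_policies_agree_without_missing_values(self):
        records = _records_from_counts(2013, datasets.HINTS_WEIGHTED_COUNTS[2013])
        assert tabulate_adoption(records, 2013, "exclude") == tabulate_adoption(
            records, 2013, "treat_as_no"
        )

    def test_empty_year_raises(self):
        records = [SurveyRecord("a", 2008, 1.0, "missing", "yes")]
        with pytest.raises(EmptyYearError):
            tabulate_adoption(records, 2008, "exclude")
        with pytest.raises(EmptyYearError):
            tabulate_adoption(records, 2011)


class TestAdoptionSeries:
    def test_published_tabulation_yields_observed_series(self):
        series = datasets.load_phr_adoption()
        np.testing.assert_array_equal(series.years, [2008, 2011, 2013])
        np.testing.assert_allclose(
            series.fractions, [0.0516, 0.0980, 0.1717], atol=5e-5
        )

    def test_single_table_and_sorting(self):
        t1 = AdoptionTable(2013, 10, 5, 5, 80)
        t2 = AdoptionTable(2008, 5, 5, 5, 85)
        series = adoption_series([t1, t2])
        np.testing.assert_array_equal(series.years, [2008, 2013])
        single = adoption_series([t1])
        assert len(single) == 1 and single.fractions[0] == 0.1

    def test_duplicate_years_rejected(self):
        table = AdoptionTable(2008, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            adoption_series([table, table])
        with pytest.raises(ValueError):
            AdoptionSeries([2008, 2008], [0.1, 0.2])

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            AdoptionSeries([2008], [1.2])

    def test_csv_roundtrip(self, tmp_path, observed_series):
        path = tmp_path / "series.csv"
        observed_series.to_frame().to_csv(path, index=False)
        assert AdoptionSeries.from_csv(path) == observed_series
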