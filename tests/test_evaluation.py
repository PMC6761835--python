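import dataclasses

import pytest

from bivalvelabel.evaluation import (
    completeness_audit,
    score_batch,
    separator_accuracy,
    variant_table,
)
from bivalvelabel.extraction import FieldCandidate
from bivalvelabel.labelgen import make_table1_fixture, sample_record

from conftest import perfect_reading


@pytest.fixture(scope="module")
def truths(vocabularies):
    return [sample_record(seed, vocabularies) for seed in range(10)]


def break_field(reading, vid, value="wrong"):
    fields = dict(reading.fields)
    fields[vid] = FieldCandidate(vid, value, 0.9)
    return dataclasses.replace(reading, fields=fields)


def break_date(reading, day=None, month=None):
    date = reading.date
    new = dataclasses.replace(
        date, day=day if day is not None else date.day,
        month=month if month is not None else date.month,
    )
    return dataclasses.replace(reading, date=new)


class TestScoreBatch:
    def test_perfect_readings_score_100_everywhere(self, truths):
        report = score_batch([perfect_reading(t) for t in truths], truths)
        frame = report.to_frame()
        evaluable = frame["n_evaluable"] > 0
        assert (frame.loc[evaluable, "accuracy_pct"] == 100.0).all()

    def test_partial_zone_errors_hit_only_the_zone_denominator(self, vocabularies):
        import dataclasses as dc

        from bivalvelabel.labelgen import GeneratorOptions

        options = dc.replace(GeneratorOptions(), zone_prob=1.0)
        truths = [sample_record(s, vocabularies, options) for s in range(5)]
        readings = [perfect_reading(t) for t in truths]
        readings[0] = break_field(readings[0], "zone")
        report = score_batch(readings, truths)
        assert report.fields["zone"].n_evaluable == 5
        assert report.fields["zone"].accuracy_pct == pytest.approx(80.0)
        assert report.fields["species"].accuracy_pct == 100.0

    def test_zoneless_truths_are_excluded_from_the_zone_denominator(self, vocabularies):
        import dataclasses as dc

        from bivalvelabel.labelgen import GeneratorOptions

        options = dc.replace(GeneratorOptions(), zone_prob=0.0)
        truths = [sample_record(s, vocabularies, options) for s in range(4)]
        report = score_batch([perfect_reading(t) for t in truths], truths)
        assert report.fields["zone"].n_evaluable == 0
        assert report.fields["zone"].accuracy_pct is None

    def test_day_right_month_wrong_splits_components_and_whole(self, truths):
        truth = truths[0]
        reading = break_date(perfect_reading(truth), month=truth.pack_month % 12 + 1)
        report = score_batch([reading], [truth])
        assert report.date_components.accuracy_pct == pytest.approx(50.0)
        assert report.date_whole.accuracy_pct == pytest.approx(0.0)

    def test_whole_date_never_exceeds_component_accuracy(self, truths):
        readings = [perfect_reading(t) for t in truths]
        readings[0] = break_date(readings[0], day=truths[0].pack_day % 28 + 1)
        readings[1] = break_date(readings[1], month=truths[1].pack_month % 12 + 1)
        report = score_batch(readings, truths)
        assert report.date_whole.accuracy_pct <= report.date_components.accuracy_pct

    def test_conservation_of_counts(self, truths):
        readings = [perfect_reading(t) for t in truths]
        readings[2] = break_field(readings[2], "species")
        report = score_batch(readings, truths)
        for score in report.fields.values():
            assert 0 <= score.n_correct <= score.n_evaluable
        total = sum(s.n_evaluable for s in report.fields.values())
        total += report.date_components.n_evaluable + report.purification.n_evaluable
        assert report.overall.n_evaluable == total

    def test_length_mismatch_rejected(self, truths):
        with pytest.raises(ValueError):
            score_batch([], truths)


class TestSeparatorAccuracy:
    def test_correct_slashes_wrong_dots(self, vocabularies):
        truths, readings = [], []
        for seed in range(40):
            t = sample_record(seed, vocabularies)
            if t.date_separator == "-":
                continue
            r = perfect_reading(t)
            if t.date_separator == ".":
                r = break_date(r, day=t.pack_day % 28 + 1)
            truths.append(t)
            readings.append(r)
        result = separator_accuracy(readings, truths)
        assert result["/"] == pytest.approx(100.0)
        assert result["."] == pytest.approx(0.0)
        assert "-" not in result  # empty subgroup omitted, never 0%

    def test_two_of_three_hyphens(self, vocabularies):
        truths = [
            dataclasses.replace(sample_record(s, vocabularies), date_separator="-")
            for s in range(3)
        ]
        readings = [perfect_reading(t) for t in truths]
        readings[0] = break_date(readings[0], day=truths[0].pack_day % 28 + 1)
        result = separator_accuracy(readings, truths)
        assert result["-"] == pytest.approx(200 / 3)


class TestCompletenessAudit:
    def test_audited_collection_headline_shares(self, vocabularies):
        report = completeness_audit(make_table1_fixture(vocabularies))
        assert report.n_labels == 86
        assert round(report.zone_presence_pct) == 63
        assert round(report.zone_presence_by_country_pct["portugal"]) == 70
        assert round(report.usable_extra_pct) == 74
        assert report.origin_shares_pct["portugal"] == pytest.approx(69.8, abs=0.05)
        assert report.origin_shares_pct["spain"] == pytest.approx(25.6, abs=0.05)
        assert report.non_portugal_pct > 30

    def test_cells_sum_to_totals(self, vocabularies):
        report = completeness_audit(make_table1_fixture(vocabularies))
        assert int(report.table.to_numpy().sum()) == report.n_labels
        assert report.table.sum(axis=1)["portugal"] == 60

    def test_all_records_with_zone_gives_100_percent(self, vocabularies):
        records = [r for r in make_table1_fixture(vocabularies) if r.zone_code]
        assert completeness_audit(records).zone_presence_pct == 100.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            completeness_audit([])


def test_variant_table_has_one_column_per_variant_plus_combined(truths):
    readings = [perfect_reading(t) for t in truths]
    table = variant_table(
        {"greyscale": readings, "sharpened": readings, "blurred": readings},
        readings,
        truths,
    )
    assert list(table.columns) == ["greyscale", "sharpened", "blurred", "combined"]
    assert table.loc["species"].eq(100.0).all()
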