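import json

import pytest

from emadhc.ingest import (
    FilterConfig,
    SchemaError,
    export_iramuteq_corpus,
    filter_corpus,
    normalize_whitespace,
    read_iramuteq_corpus,
    read_records,
    write_records_jsonl,
)
from emadhc.records import EMARecord

from conftest import make_record


class TestReadRecords:
    def test_empty_file_gives_zero_records(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        records, failures = read_records(path, "jsonl")
        assert records == [] and failures == []

    def test_malformed_jsonl_line_is_reported_not_dropped_silently(self, tmp_path):
        rows = [make_record("r1").to_dict(), make_record("r2").to_dict()]
        lines = [json.dumps(rows[0]), "{not json", json.dumps(rows[1])]
        path = tmp_path / "c.jsonl"
        path.write_text("\n".join(lines) + "\n")
        records, failures = read_records(path, "jsonl")
        assert [r.record_id for r in records] == ["r1", "r2"]
        assert len(failures) == 1 and failures[0].line_number == 2

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("record_id,listener_id,country,tech_level,text\nr1,l1,US,1,hello\n")
        with pytest.raises(SchemaError, match="satisfaction"):
            read_records(path, "csv")

    def test_unknown_satisfaction_token_raises_with_record_id(self, tmp_path):
        row = make_record("r9").to_dict()
        row["satisfaction"] = "meh"
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps(row) + "\n")
        with pytest.raises(ValueError, match="r9"):
            read_records(path, "jsonl")

    def test_csv_round_trip_of_delimited_schema(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "record_id,listener_id,country,tech_level,satisfaction,text,timestamp\n"
            'r1,l1,CANADA,2,neg,"I cannot hear the tv at all",2020-01-01T10:00:00\n'
        )
        records, failures = read_records(path, "csv")
        assert not failures
        (record,) = records
        assert record.satisfaction == "negative"
        assert record.tech_level == 2
        assert record.timestamp == "2020-01-01T10:00:00"

    def test_jsonl_write_read_round_trip(self, tmp_path):
        records = [make_record(f"r{i}", text=f"text number {i} long enough") for i in range(5)]
        path = tmp_path / "c.jsonl"
        write_records_jsonl(records, path)
        back, failures = read_records(path, "jsonl")
        assert not failures
        assert back == records


def _cascade_fixture():
    """10 records: 2 empty-text, 1 disallowed country, 2 short, 5 passing."""
    passing = [
        make_record(f"p{i}", text=f"this statement number {i} is long enough")
        for i in range(5)
    ]
    empties = [make_record("e1", text=""), make_record("e2", text="   \t ")]
    foreign = [make_record("f1", country="FRANCE", text="une phrase assez longue ici")]
    short = [make_record("s1", text="Too loud"), make_record("s2", text="short text here")]
    return empties[:1] + passing[:2] + foreign + short[:1] + empties[1:] + passing[2:] + short[1:]


class TestFilterCorpus:
    def test_cascade_counts_on_mixed_fixture(self):
        records = _cascade_fixture()
        kept, report = filter_corpus(records)
        assert report.counts == (10, 8, 7, 5, 5)
        assert len(kept) == 5
        assert sorted(r.record_id for r in kept) == [f"p{i}" for i in range(5)]

    def test_text_shorter_than_20_characters_removed(self):
        record = make_record("s", text="Too loud")  # 8 characters
        kept, report = filter_corpus([record])
        assert kept == [] and report.removed["too_short"] == ["s"]

    def test_exactly_20_characters_is_kept(self):
        record = make_record("s", text="abcde fghij klmno pq")  # 20 chars normalized
        assert len(normalize_whitespace(record.text)) == 20
        kept, _ = filter_corpus([record])
        assert [r.record_id for r in kept] == ["s"]

    def test_disallowed_country_removed_case_insensitively(self):
        record = make_record("f", country="France", text="a sufficiently long sentence")
        kept, report = filter_corpus([record])
        assert kept == [] and report.removed["country"] == ["f"]

    def test_country_aliases_accepted(self):
        for country in ("US", "usa", "United_States", "new zealand"):
            kept, _ = filter_corpus([make_record("r", country=country)])
            assert len(kept) == 1, country

    def test_cleaning_drops_low_alpha_and_repeated_runs(self):
        numeric = make_record("n", text="1234567890 1234567890 123")
        run = make_record("rr", text="aaaaaaaaaaaaaaaaaaaaaaaa")
        kept, report = filter_corpus([numeric, run])
        assert kept == []
        assert sorted(report.removed["cleaning"]) == ["n", "rr"]

    def test_replacement_dictionary_fixes_spelling_without_dropping(self):
        record = make_record("r", text="i cannot haer the telivision at all")
        config = FilterConfig(replacements={"haer": "hear", "telivision": "television"})
        kept, _ = filter_corpus([record], config)
        assert kept[0].text == "i cannot hear the television at all"

    def test_cascade_is_idempotent(self):
        kept, _ = filter_corpus(_cascade_fixture())
        again, report = filter_corpus(kept)
        assert again == kept
        assert all(not ids for ids in report.removed.values())

    def test_every_removed_id_appears_in_exactly_one_stage(self):
        records = _cascade_fixture()
        kept, report = filter_corpus(records)
        removed = [rid for ids in report.removed.values() for rid in ids]
        assert len(removed) == len(set(removed)) == len(records) - len(kept)
        assert set(removed) | {r.record_id for r in kept} == {r.record_id for r in records}

    def test_language_filter_hook(self):
        record = make_record("r", text="ein ziemlich langer deutscher satz")
        config = FilterConfig(language_filter=lambda text: "deutscher" not in text)
        kept, report = filter_corpus([record], config)
        assert kept == [] and report.removed["cleaning"] == ["r"]


class TestIramuteqExport:
    def test_single_record_header_format(self, tmp_path):
        record = make_record("r1", country="US", satisfaction="positive", tech_level=1,
                             text="I can hear the tv better")
        path = export_iramuteq_corpus([record], path=tmp_path / "c.txt")
        lines = path.read_text().splitlines()
        assert lines[0] == "**** *country_us *sat_pos *tech_1"
        assert lines[1] == "I can hear the tv better"

    def test_zero_records_gives_empty_file(self, tmp_path):
        path = export_iramuteq_corpus([], path=tmp_path / "c.txt")
        assert path.read_text() == ""

    def test_each_block_has_header_with_sat_token(self, tmp_path):
        records = [make_record(f"r{i}") for i in range(3)]
        path = export_iramuteq_corpus(records, path=tmp_path / "c.txt")
        headers = [l for l in path.read_text().splitlines() if l.startswith("**** ")]
        assert len(headers) == 3
        assert all(" *sat_" in h for h in headers)

    def test_whitespace_in_variable_name_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_iramuteq_corpus([make_record()], variables=["tech level"], path=tmp_path / "c.txt")

    def test_export_parse_round_trip_preserves_normalized_text(self, tmp_path):
        records = [
            make_record("r1", text="spaced   out\ttext with  gaps here"),
            make_record("r2", satisfaction="negative", text="another statement entirely"),
        ]
        path = export_iramuteq_corpus(records, path=tmp_path / "c.txt")
        blocks = read_iramuteq_corpus(path)
        assert [text for _, text in blocks] == [
            normalize_whitespace(r.text) for r in records
        ]
        assert blocks[0][0]["sat"] == "pos" and blocks[1][0]["sat"] == "neg"


class TestEMARecord:
    def test_tech_level_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="tech_level"):
            make_record(tech_level=6)

    def test_satisfaction_normalized(self):
        assert make_record(satisfaction="POS").satisfaction == "positive"
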