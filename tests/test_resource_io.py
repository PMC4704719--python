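"""Flat-file parsing and compiled-resource round trips."""

import gzip

import pytest

from rstrack import resource_io
from rstrack.resource_io import (
    CompiledResource,
    HistoryRecord,
    MergeEvent,
    PositionRecord,
    parse_rs,
)


@pytest.mark.parametrize(
    "token,value",
    [("rs123", 123), ("RS123", 123), ("123", 123), (" rs7 ", 7)],
)
def test_parse_rs_normalizes(token, value):
    assert parse_rs(token) == value


@pytest.mark.parametrize("token", ["", "rs", "rs0", "0", "-5", "exm-551", "chr1:100"])
def test_parse_rs_rejects(token):
    with pytest.raises(ValueError):
        parse_rs(token)


def test_read_merge_arch_takes_high_low_current_columns(tmp_path):
    p = tmp_path / "merge.tsv"
    p.write_text("1002\t1001\t142\t0\t2013-01-01\t2014-01-01\t1001\n")
    assert resource_io.read_merge_arch(p) == [
        MergeEvent(rs_high=1002, rs_low=1001, rs_current=1001)
    ]


def test_read_merge_arch_empty_file(tmp_path):
    p = tmp_path / "merge.tsv"
    p.write_text("")
    assert resource_io.read_merge_arch(p) == []


def test_read_merge_arch_skips_and_counts_malformed(tmp_path):
    p = tmp_path / "merge.tsv"
    p.write_text(
        "1002\t1001\t142\t0\ta\tb\t1001\n"
        "garbage\tline\n"
        "2002\tnotanint\t142\t0\ta\tb\t2001\n"
        "2002\t2001\t142\t0\ta\tb\t2001\n"
    )
    events = resource_io.read_merge_arch(p)
    # record count == data lines minus skipped lines
    assert len(events) == 4 - 2
    assert [e.rs_high for e in events] == [1002, 2002]


def test_gzip_detected_by_magic_bytes_not_extension(tmp_path):
    content = "1002\t1001\t142\t0\ta\tb\t1001\n"
    plain = tmp_path / "m.tsv"
    plain.write_text(content)
    gz = tmp_path / "m.tsv.txt"  # deliberately misleading extension
    with gzip.open(gz, "wt") as fh:
        fh.write(content)
    assert resource_io.read_merge_arch(plain) == resource_io.read_merge_arch(gz)


@pytest.mark.parametrize(
    "comment,expected",
    [("", False), ("Re-activation needed", True), ("REACTIVATED", True), ("withdrawn", False)],
)
def test_history_reactivation_marker(tmp_path, comment, expected):
    p = tmp_path / "hist.tsv"
    p.write_text(f"4000\t2013-01-01\t137\t137\t{comment}\n")
    assert resource_io.read_snp_history(p) == [HistoryRecord(4000, expected)]


def test_history_one_record_per_id_any_marker_wins(tmp_path):
    p = tmp_path / "hist.tsv"
    p.write_text(
        "5000\t2013-01-01\t137\t137\t\n"
        "5000\t2014-01-01\t140\t140\tre-activated\n"
    )
    assert resource_io.read_snp_history(p) == [HistoryRecord(5000, True)]


@pytest.mark.parametrize(
    "line,expected",
    [
        ("1000\t1\t999", PositionRecord(1000, "1", 999)),
        ("6000\tMulti\t", PositionRecord(6000, "Multi", None)),
        ("7000\tNotOn\t", PositionRecord(7000, "NotOn", None)),
        ("8000\tchrX\t5", PositionRecord(8000, "X", 5)),
    ],
)
def test_read_chr_pos_rows(tmp_path, line, expected):
    p = tmp_path / "pos.tsv"
    p.write_text(line + "\n")
    assert resource_io.read_chr_pos(p) == [expected]


def test_parsing_is_order_preserving(tmp_path):
    p = tmp_path / "pos.tsv"
    rows = [f"{rs}\t1\t{rs}" for rs in (30, 10, 20)]
    p.write_text("\n".join(rows) + "\n")
    assert [r.rs_id for r in resource_io.read_chr_pos(p)] == [30, 10, 20]


class TestCompiledRoundTrip:
    def test_empty_resource(self, tmp_path):
        path = tmp_path / "c.gz"
        resource_io.write_compiled(CompiledResource(build_tag="b142"), path)
        back = resource_io.read_compiled(path)
        assert back.build_tag == "b142"
        assert not back.current_of and not back.deleted and not back.positions

    def test_full_round_trip(self, tmp_path, toya):
        path = tmp_path / "c.gz"
        resource_io.write_compiled(toya, path)
        back = resource_io.read_compiled(path)
        assert back.current_of == toya.current_of
        assert back.deleted == toya.deleted
        assert back.reactivated == toya.reactivated
        assert back.positions == toya.positions
        assert back.build_tag == toya.build_tag

    def test_round_trip_bit_identical(self, tmp_path, toya):
        p1, p2 = tmp_path / "a.gz", tmp_path / "b.gz"
        resource_io.write_compiled(toya, p1)
        resource_io.write_compiled(resource_io.read_compiled(p1), p2)
        with gzip.open(p1, "rb") as a, gzip.open(p2, "rb") as b:
            assert a.read() == b.read()

    def test_corrupted_header_is_fatal(self, tmp_path):
        path = tmp_path / "c.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("#something-else v9\n1\t2\t\t\t\n")
        with pytest.raises(resource_io.CompiledFormatError, match="rstrack-compiled"):
            resource_io.read_compiled(path)
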