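"""Parsing of GAF tables, BLAST tabular output and key resolution."""

import gzip
import io
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from goloc import (
    AnnotationTable,
    HomologHit,
    HomologList,
    ProteinRecord,
    first_annotated_key,
    load_blast_tabular,
    load_gaf,
    load_homolog_map,
    parse_blast_tabular,
    resolve_keys,
    write_homolog_map,
)

from conftest import blast_row, blast_stream, gaf_stream


class TestLoadGaf:
    def test_duplicate_rows_accumulate_counts(self):
        table = load_gaf(gaf_stream(
            [("P1", "GO:0000001"), ("P1", "GO:0000001"), ("P1", "GO:0000002")]))
        assert table.terms("P1") == Counter(
            {"GO:0000001": 2, "GO:0000002": 1})

    def test_comment_only_stream_gives_empty_table(self):
        table = load_gaf(io.StringIO("!gaf-version: 2.2\n!generated-by: x\n"))
        assert len(table) == 0

    def test_absent_accession_yields_empty_multiset(self, small_table):
        assert small_table.terms("Q_absent") == Counter()
        assert not small_table.has_annotation("Q_absent")

    def test_malformed_rows_skipped_and_counted(self):
        good = gaf_stream([("P1", "GO:0000001")]).getvalue()
        bad = "too\tfew\tcolumns\n" + "\t".join(
            ["DB", "P2", "P2", "", "GO:12", "R", "IEA", "", "C", "", "",
             "protein", "taxon:1", "20110308", "DB"]) + "\n"
        table = load_gaf(io.StringIO(good + bad))
        assert table.terms("P1")["GO:0000001"] == 1
        assert "P2" not in table
        assert table.skipped_rows == 2

    def test_exclude_not_qualifier_flag(self):
        rows = gaf_stream([("P1", "GO:0000001")]).getvalue()
        not_row = rows.splitlines()[1].split("\t")
        not_row[3] = "NOT|located_in"
        not_row[4] = "GO:0000002"
        stream = rows + "\t".join(not_row) + "\n"
        default = load_gaf(io.StringIO(stream))
        assert default.terms("P1")["GO:0000002"] == 1
        filtered = load_gaf(io.StringIO(stream), exclude_not=True)
        assert "GO:0000002" not in filtered.terms("P1")

    def test_gzip_stream_supported(self, tmp_path):
        path = tmp_path / "anno.gaf.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(gaf_stream([("P1", "GO:0000007")]).getvalue())
        assert load_gaf(path).terms("P1")["GO:0000007"] == 1

    @given(st.lists(st.tuples(
        st.sampled_from(["P1", "P2", "P3"]),
        st.integers(1, 5).map(lambda i: f"GO:{i:07d}")), max_size=30))
    def test_counting_conservation(self, rows):
        """Total occurrences equal the number of accepted GAF rows."""
        table = load_gaf(gaf_stream(rows))
        assert table.total_occurrences() == len(rows)

    def test_table_rejects_bad_go_id_and_count(self):
        table = AnnotationTable()
        with pytest.raises(ValueError):
            table.add("P1", "GO:123")
        with pytest.raises(ValueError):
            table.add("P1", "GO:0000001", 0)


class TestBlastParsing:
    def test_hits_sorted_by_descending_bitscore(self):
        stream = blast_stream(
            [("Q1", "H2", 1e-10, 90), ("Q1", "H1", 1e-50, 200)])
        hl = parse_blast_tabular(stream, "Q1")
        assert [h.subject for h in hl] == ["H1", "H2"]

    def test_self_hit_only_gives_empty_list(self):
        stream = blast_stream([("Q1", "Q1", 0.0, 500)])
        hl = parse_blast_tabular(stream, "Q1", self_accession="Q1")
        assert len(hl) == 0 and not hl

    def test_duplicate_subject_keeps_best_bitscore(self):
        stream = blast_stream(
            [("Q1", "H1", 1e-5, 90), ("Q1", "H1", 1e-40, 200)])
        hl = parse_blast_tabular(stream, "Q1")
        assert len(hl) == 1
        assert hl.hits[0] == HomologHit("H1", 1e-40, 200)

    def test_non_numeric_row_skipped(self):
        text = blast_row("Q1", "H1", 1e-5, 90) + "\n" + \
            blast_row("Q1", "H2", "bad", 50).replace("bad", "notanumber") + "\n"
        hl = parse_blast_tabular(io.StringIO(text), "Q1")
        assert [h.subject for h in hl] == ["H1"]

    def test_tie_break_chain(self):
        stream = blast_stream(
            [("Q1", "HB", 1e-10, 100), ("Q1", "HA", 1e-10, 100),
             ("Q1", "HC", 1e-20, 100)])
        hl = parse_blast_tabular(stream, "Q1")
        assert [h.subject for h in hl] == ["HC", "HA", "HB"]

    def test_load_blast_tabular_groups_queries(self):
        stream = blast_stream(
            [("Q1", "H1", 1e-10, 90), ("Q2", "Q2", 0.0, 500),
             ("Q2", "H2", 1e-20, 120)])
        per_query = load_blast_tabular(stream, self_accessions={"Q2": "Q2"})
        assert per_query["Q1"].top(5) == ["H1"]
        assert per_query["Q2"].top(5) == ["H2"]

    @given(hits=st.lists(st.tuples(
        st.sampled_from(["HA", "HB", "HC", "HD"]),
        st.floats(1e-60, 1.0), st.floats(10, 300)),
        max_size=8, unique_by=lambda t: t[0]))
    def test_homolog_map_round_trip(self, tmp_path_factory, hits):
        """Serialize -> parse is the identity on (subject, evalue, bitscore)."""
        path = tmp_path_factory.mktemp("hm") / "map.tsv"
        original = {"Q1": HomologList(
            "Q1", [HomologHit(s, e, b) for s, e, b in hits])}
        write_homolog_map(original, path)
        loaded = load_homolog_map(path)
        if not hits:
            assert loaded == {}
        else:
            assert loaded["Q1"].hits == original["Q1"].hits


class TestResolveKeys:
    def _protein(self):
        return ProteinRecord("P1", accession="P1", sequence="MKV",
                             labels=frozenset({1}))

    def _homologs(self):
        return HomologList("P1", [
            HomologHit("H1", 1e-50, 200), HomologHit("H2", 1e-30, 150),
            HomologHit("H3", 1e-10, 90)])

    @pytest.mark.parametrize("mode,n,expected", [
        ("ac", 1, ["P1"]),
        ("seq", 2, ["H1", "H2"]),
        ("ac+seq", 2, ["P1", "H1", "H2"]),
        ("ac+seq", 8, ["P1", "H1", "H2", "H3"]),
    ])
    def test_key_resolution_cases(self, mode, n, expected):
        assert resolve_keys(self._protein(), self._homologs(), mode, n) == expected

    def test_seq_mode_without_homologs_gives_empty_keys(self):
        assert resolve_keys(self._protein(), HomologList("P1"), "seq", 1) == []

    @given(st.integers(0, 10))
    def test_never_more_than_n_plus_one_keys(self, n):
        keys = resolve_keys(self._protein(), self._homologs(), "ac+seq", n)
        assert len(keys) <= n + 1
        assert len([k for k in keys if k != "P1"]) == min(n, 3)

    def test_record_requires_accession_or_sequence(self):
        with pytest.raises(ValueError):
            ProteinRecord("P1")


class TestFirstAnnotatedKey:
    def test_skips_unannotated_top_homolog(self, small_table):
        homologs = HomologList("Q", [
            HomologHit("UNANNOTATED", 1e-60, 300), HomologHit("H1", 1e-30, 150)])
        assert first_annotated_key(homologs, small_table) == "H1"

    def test_annotated_top_homolog_wins(self, small_table):
        homologs = HomologList("Q", [HomologHit("H1", 1e-30, 150)])
        assert first_annotated_key(homologs, small_table) == "H1"

    def test_all_unannotated_gives_none(self, small_table):
        homologs = HomologList("Q", [HomologHit("X1", 1e-30, 150)])
        assert first_annotated_key(homologs, small_table) is None
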