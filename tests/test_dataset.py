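"""Pair-table loading, curation rules, and splitting."""

import pytest

from textmol.chem import parse_molecule
from textmol.data import (CurationReport, PairTable, SchemaError, curate,
                          filter_by_word_count, load_pairs, remove_one_to_many,
                          remove_overlap, save_pairs, split)


def _pair(pid: str, description: str, smiles: str):
    from textmol.data import DescriptionPair

    return DescriptionPair(pid, description, parse_molecule(smiles))


def _table(rows):
    return PairTable([_pair(*row) for row in rows])


def _write_table(path, rows, header="id,description,smiles"):
    lines = [header] + [",".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadPairs:
    def test_three_row_fixture(self, tmp_path):
        path = _write_table(tmp_path / "t.csv", [
            ("a", "ethanol molecule", "CCO"),
            ("b", "acetic acid", "CC(=O)O"),
            ("c", "benzene ring", "c1ccccc1"),
        ])
        assert len(load_pairs(path)) == 3

    def test_invalid_smiles_dropped_and_counted(self, tmp_path):
        path = _write_table(tmp_path / "t.csv", [
            ("a", "fine", "CCO"),
            ("b", "broken", "C("),
        ])
        report = CurationReport()
        table = load_pairs(path, report=report)
        assert len(table) == 1
        assert report.dropped_invalid == 1

    def test_duplicate_id_is_schema_error(self, tmp_path):
        path = _write_table(tmp_path / "t.csv", [
            ("a", "one", "CCO"),
            ("a", "two", "CCN"),
        ])
        with pytest.raises(SchemaError, match="duplicate"):
            load_pairs(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = _write_table(tmp_path / "t.csv", [("a", "x")],
                            header="id,description")
        with pytest.raises(SchemaError, match="smiles"):
            load_pairs(path)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,description,smiles\n")
        with pytest.raises(SchemaError, match="empty"):
            load_pairs(path)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            load_pairs(tmp_path / "nope.csv")

    def test_chebi20_preset_and_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "chebi.tsv"
        path.write_text("CID\tSMILES\tdescription\n10\tCCO\tan alcohol\n")
        table = load_pairs(path, "chebi20")
        assert table.pairs[0].id == "10"
        out = tmp_path / "out.tsv"
        save_pairs(table, out, "chebi20")
        assert len(load_pairs(out, "chebi20")) == 1


class TestWordCountFilter:
    def test_exactly_threshold_words_dropped(self):
        table = _table([("a", " ".join(["w"] * 30), "CCO")])
        assert len(filter_by_word_count(table, 30)) == 0

    def test_threshold_plus_one_kept(self):
        table = _table([("a", " ".join(["w"] * 31), "CCO")])
        assert len(filter_by_word_count(table, 30)) == 1

    def test_thresholds_are_nested(self):
        rows = [(f"r{i}", " ".join(["w"] * n), "CCO")
                for i, n in enumerate([5, 15, 21, 25, 31, 40])]
        table = _table(rows)
        at_20 = {p.id for p in filter_by_word_count(table, 20)}
        at_30 = {p.id for p in filter_by_word_count(table, 30)}
        assert at_30 <= at_20

    def test_whitespace_runs_count_once(self):
        table = _table([("a", "two   words", "CCO")])
        assert len(filter_by_word_count(table, 1)) == 1
        assert len(filter_by_word_count(table, 2)) == 0


class TestOneToMany:
    def test_forced_example(self):
        table = _table([
            ("1", "D1", "CCO"),
            ("2", "D1", "CCN"),
            ("3", "D2", "CCS"),
        ])
        kept = remove_one_to_many(table)
        assert [p.id for p in kept] == ["3"]

    def test_one_to_one_table_unchanged(self):
        table = _table([("1", "D1", "CCO"), ("2", "D2", "CCN")])
        assert len(remove_one_to_many(table)) == 2

    def test_same_canonical_molecule_twice_collapses_and_keeps(self):
        table = _table([
            ("1", "D1", "OC1=CC=C(C)C=C1"),
            ("2", "D1", "Cc1ccc(O)cc1"),
        ])
        kept = remove_one_to_many(table)
        assert len(kept) == 1

    def test_many_to_one_is_retained(self):
        table = _table([("1", "D1", "CCO"), ("2", "D2", "CCO")])
        assert len(remove_one_to_many(table)) == 2


class TestOverlap:
    def test_overlap_of_one_molecule(self):
        table = _table([("1", "a", "CCO"), ("2", "b", "CCN"),
                        ("3", "c", "CCS")])
        reference = _table([("r", "x", "CCN")])
        assert len(remove_overlap(table, reference)) == 2

    def test_disjoint_tables_unchanged(self):
        table = _table([("1", "a", "CCO")])
        reference = _table([("r", "x", "CCN")])
        assert len(remove_overlap(table, reference)) == 1

    def test_overlap_is_canonical_form_based(self):
        table = _table([("1", "a", "OC1=CC=C(C)C=C1")])
        reference = _table([("r", "x", "Cc1ccc(O)cc1")])
        assert len(remove_overlap(table, reference)) == 0


class TestSplit:
    def _table10(self):
        return _table([(f"r{i}", f"desc {i}", "C" * (i + 1))
                       for i in range(10)])

    def test_sizes_within_rounding(self):
        train, valid, test = split(self._table10(), (0.8, 0.1, 0.1), seed=0)
        assert (len(train), len(valid), len(test)) == (8, 1, 1)

    def test_disjoint_union(self):
        table = self._table10()
        parts = split(table, (0.8, 0.1, 0.1), seed=3)
        ids = [p.id for part in parts for p in part]
        assert sorted(ids) == sorted(x.id for x in table)

    def test_same_seed_reproducible(self):
        a = split(self._table10(), seed=5)
        b = split(self._table10(), seed=5)
        assert all([p.id for p in x] == [p.id for p in y]
                   for x, y in zip(a, b))

    def test_different_seeds_differ(self):
        table = _table([(f"r{i}", f"d {i}", "CCO" if i % 2 else "CCN")
                        for i in range(100)])
        # unique ids, shared molecules: assignment should shuffle
        a = split(table, seed=1)
        b = split(table, seed=2)
        assert [p.id for p in a[0]] != [p.id for p in b[0]]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split(self._table10(), (0.5, 0.2, 0.2), seed=0)


class TestCurationPipeline:
    def test_all_retained_rows_satisfy_rules(self):
        long = " ".join(["word"] * 25)
        table = _table([
            ("1", long + " alpha", "CCO"),
            ("2", long + " beta", "CCN"),
            ("3", "short text", "CCS"),          # dropped: word count
            ("4", long + " gamma", "CCBr"),      # dropped: overlap
            ("5", long + " delta", "CCCl"),
            ("6", long + " delta", "CCI"),       # one-to-many with 5
        ])
        reference = _table([("r", "x", "CCBr")])
        report = CurationReport()
        out = curate(table, 20, reference, report)
        assert {p.id for p in out} == {"1", "2"}
        assert report.rows_out == 2
        assert report.dropped_short == 1
        assert report.dropped_one_to_many == 2
        assert report.dropped_overlap == 1
        total_dropped = (report.dropped_invalid + report.dropped_short
                         + report.dropped_duplicate
                         + report.dropped_one_to_many
                         + report.dropped_overlap)
        assert report.rows_in - total_dropped == report.rows_out
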