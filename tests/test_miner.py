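import io
import random

import pytest

from gapminer.index import build_index
from gapminer.miner import (
    CountingMatrix,
    GappedPattern,
    MiningParams,
    extend_matrix,
    extend_matrix_min_only,
    initial_matrix,
    mine,
    resolve_threshold,
    support_of,
    write_motifs_tsv,
)
from gapminer.seqdb import Alphabet, Sequence, SequenceDatabase

from conftest import random_db


def lines_db(*residues: str) -> SequenceDatabase:
    return SequenceDatabase(
        Alphabet.dna(), [Sequence(f"s{i}", r) for i, r in enumerate(residues, start=1)]
    )


def as_pairs(records):
    return {(str(r.pattern), r.support) for r in records}


class TestGappedPattern:
    def test_string_form(self):
        assert str(GappedPattern(("C", "A"), gap=3)) == "C*A"
        assert str(GappedPattern(("A",), gap=3)) == "A"

    def test_invalid(self):
        with pytest.raises(ValueError):
            GappedPattern((), gap=3)
        with pytest.raises(ValueError):
            GappedPattern(("A",), gap=0)


class TestResolveThreshold:
    def test_absolute(self):
        assert resolve_threshold(MiningParams(gap=3, min_support=3), N=3) == 3

    def test_fraction_rounds_up(self):
        assert resolve_threshold(MiningParams(gap=3, min_support_frac=0.9), N=3000) == 2700
        assert resolve_threshold(MiningParams(gap=3, min_support_frac=0.9), N=3001) == 2701

    def test_full_fraction(self):
        assert resolve_threshold(MiningParams(gap=3, min_support_frac=1.0), N=5) == 5

    def test_unreachable_threshold_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert resolve_threshold(MiningParams(gap=3, min_support=9), N=3) == 9
        assert "no pattern can qualify" in caplog.text

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            MiningParams(gap=3, min_support_frac=0.0)
        with pytest.raises(ValueError):
            MiningParams(gap=3, min_support_frac=1.5)

    def test_exactly_one_threshold_kind(self):
        with pytest.raises(ValueError):
            MiningParams(gap=3)
        with pytest.raises(ValueError):
            MiningParams(gap=3, min_support=2, min_support_frac=0.5)


class TestCountingMatrices:
    def test_initial_matrix_c(self, worked_index):
        assert initial_matrix(worked_index, "C").rows == [[4], [3, 5], [4, 6]]

    def test_initial_matrix_t(self, worked_index):
        # frozen from a linear scan of the three strings
        assert initial_matrix(worked_index, "T").rows == [[2, 7], [2], [1]]

    def test_initial_matrix_empty_row(self):
        idx = build_index(lines_db("", "AC"))
        assert initial_matrix(idx, "G").rows == [[], []]

    def test_extend_c_by_a(self, worked_index):
        parent = initial_matrix(worked_index, "C")
        child = extend_matrix(worked_index, parent, "A", G=3)
        assert child.rows == [[6], [4, 7], [7]]

    def test_extend_a_by_t(self, worked_index):
        parent = initial_matrix(worked_index, "A")
        child = extend_matrix(worked_index, parent, "T", G=3)
        assert child.rows == [[2, 7], [2], []]

    def test_extension_keeps_all_window_positions(self):
        # both C positions reachable from A@1 must be retained
        idx = build_index(lines_db("ACCGT"))
        parent = initial_matrix(idx, "A")
        assert parent.rows == [[1]]
        child = extend_matrix(idx, parent, "C", G=3)
        assert child.rows == [[2, 3]]

    def test_min_only_variant_keeps_single_successor(self):
        idx = build_index(lines_db("ACCGT"))
        parent = initial_matrix(idx, "A")
        child = extend_matrix_min_only(idx, parent, "C", G=3)
        assert child.rows == [[2]]

    def test_rows_stay_sorted_and_unique(self):
        idx = build_index(lines_db("AAACCC"))
        parent = initial_matrix(idx, "A")  # (1,2,3): overlapping windows onto C
        child = extend_matrix(idx, parent, "C", G=4)
        assert child.rows == [[4, 5, 6]]

    def test_matrix_rendering(self):
        m = CountingMatrix([[2, 7], [2], []])
        assert str(m) == "{(2,7),(2),(-)}"


class TestSupportOf:
    def test_full_support(self):
        assert support_of(CountingMatrix([[6], [4, 7], [7]])) == 3

    def test_partial_support(self):
        assert support_of(CountingMatrix([[2, 7], [2], []])) == 2

    def test_zero_support(self):
        assert support_of(CountingMatrix([[], [], []])) == 0

    def test_multiple_positions_count_once(self):
        assert support_of(CountingMatrix([[1, 2, 3, 4]])) == 1


class TestMine:
    def test_worked_example_motifs(self, worked_db):
        records = mine(worked_db, MiningParams(gap=3, min_support=3))
        pairs = as_pairs(records)
        assert ("C*A", 3) in pairs
        assert all(not p.startswith("A*T") for p, _ in pairs)
        assert "A*T" not in {p for p, _ in pairs}

    def test_small_db_exact_output(self):
        db = lines_db("AC", "AC", "AG")
        records = mine(db, MiningParams(gap=2, min_support=2))
        # frozen from brute-force enumeration of all patterns of length <= 2
        assert as_pairs(records) == {("A", 3), ("C", 2), ("A*C", 2)}

    def test_unreachable_threshold_returns_empty(self, worked_db):
        assert mine(worked_db, MiningParams(gap=3, min_support=4)) == []

    def test_dfs_preorder(self, worked_db):
        records = mine(worked_db, MiningParams(gap=3, min_support=3))
        patterns = [str(r.pattern) for r in records]
        # every pattern appears once, immediately after its prefix chain start
        assert len(patterns) == len(set(patterns))
        for i, pat in enumerate(patterns):
            items = pat.split("*")
            if len(items) > 1:
                prefix = "*".join(items[:-1])
                assert prefix in patterns[:i]

    def test_anti_monotonicity(self):
        rng = random.Random(7)
        for _ in range(20):
            db = random_db(rng)
            records = mine(db, MiningParams(gap=rng.choice([2, 3, 4]), min_support=rng.randint(1, db.N)))
            by_pattern = {str(r.pattern): r.support for r in records}
            for pat, support in by_pattern.items():
                items = pat.split("*")
                if len(items) > 1:
                    prefix = "*".join(items[:-1])
                    assert by_pattern[prefix] >= support

    def test_length1_support_counts_containing_sequences(self):
        rng = random.Random(11)
        for _ in range(20):
            db = random_db(rng)
            records = mine(db, MiningParams(gap=3, min_support=1, max_length=1))
            expected = {
                item: sum(1 for s in db if item in s.residues) for item in db.alphabet
            }
            got = {str(r.pattern): r.support for r in records}
            assert got == {k: v for k, v in expected.items() if v >= 1}

    def test_min_length_suppresses_short_patterns(self, worked_db):
        records = mine(worked_db, MiningParams(gap=3, min_support=3, min_length=2))
        assert all(r.pattern.length >= 2 for r in records)
        assert ("C*A", 3) in as_pairs(records)

    def test_max_length_caps_depth(self, worked_db):
        records = mine(worked_db, MiningParams(gap=3, min_support=3, max_length=2))
        assert records and max(r.pattern.length for r in records) == 2

    def test_report_positions_snapshot(self, worked_db):
        records = mine(worked_db, MiningParams(gap=3, min_support=3, report_positions=True))
        rec = next(r for r in records if str(r.pattern) == "C*A")
        assert rec.supporting_ids == ["X", "Y", "Z"]
        assert rec.end_positions.rows == [[6], [4, 7], [7]]
        assert rec.support == sum(1 for row in rec.end_positions.rows if row)

    def test_min_only_regression(self):
        db = lines_db("ACCGT")
        params = MiningParams(gap=3, min_support=1)
        full = {str(r.pattern) for r in mine(db, params)}
        crippled = {str(r.pattern) for r in mine(db, params, _extend=extend_matrix_min_only)}
        assert "A*C*T" in full
        assert "A*C*T" not in crippled
        assert crippled <= full

    def test_determinism(self, worked_db):
        params = MiningParams(gap=3, min_support=2, report_positions=True)
        out1, out2 = io.StringIO(), io.StringIO()
        for out in (out1, out2):
            write_motifs_tsv(mine(worked_db, params), out, worked_db.N)
        assert out1.getvalue() == out2.getvalue()

    def test_sorted_output(self, worked_db):
        records = mine(worked_db, MiningParams(gap=3, min_support=3), sort=True)
        patterns = [str(r.pattern) for r in records]
        assert patterns == sorted(patterns)

    def test_empty_db_rejected(self):
        db = SequenceDatabase(Alphabet.dna(), [])
        with pytest.raises(ValueError):
            mine(db, MiningParams(gap=3, min_support=1))


class TestMotifTsv:
    def test_columns_and_fraction(self, worked_db):
        out = io.StringIO()
        records = mine(worked_db, MiningParams(gap=3, min_support=3))
        write_motifs_tsv(records, out, worked_db.N)
        lines = out.getvalue().splitlines()
        assert lines[0] == "pattern\tlength\tsupport\tsupport_fraction"
        assert "C*A\t2\t3\t1.000000" in lines

    def test_positions_file(self, worked_db, tmp_path):
        records = mine(worked_db, MiningParams(gap=3, min_support=3, report_positions=True))
        out = tmp_path / "motifs.tsv"
        pos_out = tmp_path / "motifs.positions.tsv"
        write_motifs_tsv(records, out, worked_db.N, positions_path=pos_out)
        lines = pos_out.read_text().splitlines()
        assert lines[0] == "pattern\tsequence_id\tend_positions"
        assert "C*A\tY\t4,7" in lines
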