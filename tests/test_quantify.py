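"""Priority counting rules, nested subtraction, count/abundance tables."""

import numpy as np
import pandas as pd
import pytest

from mirsexdiff.mapping import ReadAligner, map_unique_reads
from mirsexdiff.quantify import (
    CountTable,
    assign_counts,
    build_count_table,
    cpm_normalize,
    filter_highly_expressed,
    nested_subtraction,
    pooling_correlation,
)
from mirsexdiff.readproc import UniqueRead
from mirsexdiff.reference import NestedPair, Reference, ReferenceTarget


@pytest.fixture
def nested_reference():
    short = "ACCCGTAGATCCGAACTT"
    long_ = short + "G"
    targets = [
        ReferenceTarget("short", short, "mature", ("short",)),
        ReferenceTarget("long", long_, "mature", ("long",)),
        ReferenceTarget("other", "TGAGGTAGTAGGTTGTATAGTT", "mature", ("other",)),
        ReferenceTarget("prec", "AACCGG" + "N" * 22 + "TTGGCCAAGGTTCCAATG", "precursor", ("prec",)),
    ]
    return Reference(targets=targets, nested_pairs=[NestedPair("short", "long")])


def _count(reference, unique_reads):
    aligner = ReadAligner(reference)
    hits = map_unique_reads(unique_reads, aligner)
    return assign_counts(unique_reads, hits, reference)


class TestPriorityRules:
    def test_perfect_beats_one_mismatch(self):
        # read matches X perfectly and Y with one mismatch
        x = "TGAGGTAGTAGGTTGTATAGTT"
        y = x[:-1] + "A"
        ref = Reference(
            targets=[
                ReferenceTarget("X", x, "mature", ("X",)),
                ReferenceTarget("Y", y, "mature", ("Y",)),
            ],
            nested_pairs=[],
        )
        lc = _count(ref, [UniqueRead(x, 5)])
        assert lc.totals == {"X": 5}
        assert lc.mismatch == {}

    def test_mismatch_counted_in_subcounts(self):
        x = "TGAGGTAGTAGGTTGTATAGTT"
        ref = Reference(
            targets=[ReferenceTarget("X", x, "mature", ("X",))], nested_pairs=[]
        )
        lc = _count(ref, [UniqueRead(x[:-1] + "A", 3)])
        assert lc.totals == {"X": 3} and lc.mismatch == {"X": 3}

    def test_precursor_exclusive_counting(self, nested_reference):
        # a read from the unmasked precursor flank maps only to the precursor
        read = nested_reference.get("prec").sequence[28:46]
        assert "N" not in read and len(read) == 18
        lc = _count(nested_reference, [UniqueRead(read, 2)])
        assert lc.totals == {"prec": 2}

    def test_mature_hit_suppresses_precursor(self):
        mature = "TGAGGTAGTAGGTTGTATAGTT"
        prec = "AAAA" + mature + "CCCC"  # deliberately unmasked precursor
        ref = Reference(
            targets=[
                ReferenceTarget("mat", mature, "mature", ("mat",)),
                ReferenceTarget("prec", prec, "precursor", ("prec",)),
            ],
            nested_pairs=[],
        )
        lc = _count(ref, [UniqueRead(mature, 4)])
        assert lc.totals == {"mat": 4}

    def test_two_unrelated_perfect_hits_are_ambiguous(self):
        seq = "TGAGGTAGTAGGTTGTATAGTT"
        ref = Reference(
            targets=[
                ReferenceTarget("A", "AAAA" + seq, "mature", ("A",)),
                ReferenceTarget("B", seq + "CCCC", "mature", ("B",)),
            ],
            nested_pairs=[],
        )
        lc = _count(ref, [UniqueRead(seq, 7)])
        assert lc.totals == {} and lc.ambiguous == 7 and lc.mapped_total == 7

    def test_unmapped_reads_tracked(self, nested_reference):
        lc = _count(nested_reference, [UniqueRead("C" * 22, 9)])
        assert lc.unmapped == 9 and lc.mapped_total == 0

    def test_conservation(self, nested_reference):
        reads = [
            UniqueRead(nested_reference.get("other").sequence, 10),
            UniqueRead(nested_reference.get("short").sequence, 6),
            UniqueRead("G" * 25, 3),
        ]
        lc = _count(nested_reference, reads)
        assert lc.assigned + lc.ambiguous + lc.unmapped == 19


class TestNestedSubtraction:
    def test_shared_reads_move_to_short(self, nested_reference):
        short = nested_reference.get("short").sequence
        long_ = nested_reference.get("long").sequence
        reads = [UniqueRead(short, 10), UniqueRead(long_, 5)]
        lc = _count(nested_reference, reads)
        # before subtraction all 15 sit on the long target, 10 flagged shared
        assert lc.totals == {"long": 15}
        adj = nested_subtraction(lc, nested_reference.nested_pairs)
        assert adj.totals == {"long": 5, "short": 10}
        assert adj.assigned == lc.assigned  # pair total conserved

    def test_no_shared_reads_identity(self, nested_reference):
        long_ = nested_reference.get("long").sequence
        lc = _count(nested_reference, [UniqueRead(long_, 5)])
        adj = nested_subtraction(lc, nested_reference.nested_pairs)
        assert adj.totals == {"long": 5}

    def test_all_shared_empties_long(self, nested_reference):
        short = nested_reference.get("short").sequence
        lc = _count(nested_reference, [UniqueRead(short, 8)])
        adj = nested_subtraction(lc, nested_reference.nested_pairs)
        assert adj.totals == {"long": 0, "short": 8}

    def test_double_subtraction_rejected(self, nested_reference):
        lc = _count(nested_reference, [UniqueRead(nested_reference.get("short").sequence, 1)])
        adj = nested_subtraction(lc, nested_reference.nested_pairs)
        with pytest.raises(ValueError, match="already"):
            nested_subtraction(adj, nested_reference.nested_pairs)


class TestTables:
    def _table(self):
        from mirsexdiff.quantify import LibraryCounts

        per_lib = {
            "lib1": LibraryCounts(totals={"a": 50, "b": 50}, mapped_total=110),
            "lib2": LibraryCounts(totals={"a": 10, "c": 90}, mismatch={"a": 2}, mapped_total=100),
        }
        return build_count_table(per_lib)

    def test_union_of_targets_with_zeros(self):
        table = self._table()
        assert table.targets == ["a", "b", "c"]
        assert table.total.loc["b", "lib2"] == 0
        assert table.mismatch.loc["a", "lib2"] == 2

    def test_tsv_roundtrip(self, tmp_path):
        table = self._table()
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = CountTable.from_tsv(path)
        assert back.equals(table)

    def test_cpm_and_percent_sums(self):
        table = self._table()
        ab = cpm_normalize(table)
        assert np.allclose(ab.cpm.sum(axis=0), 1e6)
        assert np.allclose(ab.percent.sum(axis=0), 100.0)
        assert ab.cpm.loc["a", "lib1"] == pytest.approx(5e5)
        assert ab.percent.loc["a", "lib1"] == pytest.approx(50.0)

    def test_cpm_invariant_to_uniform_scaling(self):
        table = self._table()
        scaled = CountTable(
            total=table.total * 10,
            mismatch=table.mismatch * 10,
            mapped_total=table.mapped_total * 10,
        )
        assert np.allclose(
            cpm_normalize(table).cpm.values, cpm_normalize(scaled).cpm.values
        )

    def test_zero_count_library_rejected(self):
        from mirsexdiff.quantify import LibraryCounts

        table = build_count_table({"lib1": LibraryCounts(totals={"a": 0})})
        with pytest.raises(ValueError, match="zero-count"):
            cpm_normalize(table)


class TestHighlyExpressedFilter:
    def _abundance(self, cpms):
        total = pd.DataFrame(cpms, dtype=int)
        table = CountTable(
            total=total,
            mismatch=total * 0,
            mapped_total=total.sum(axis=0),
        )
        return cpm_normalize(table)

    def test_strictly_above_threshold_in_one_library_kept(self):
        # target 'hi' at 101 CPM in lib1 only
        ab = self._abundance({"lib1": {"hi": 101, "rest": 999_899}, "lib2": {"hi": 0, "rest": 1000}})
        assert "hi" in filter_highly_expressed(ab, threshold=100)

    def test_exactly_threshold_dropped(self):
        ab = self._abundance({"lib1": {"edge": 100, "rest": 999_900}})
        assert filter_highly_expressed(ab, threshold=100) == ["rest"]

    def test_min_libraries(self):
        ab = self._abundance(
            {"lib1": {"x": 200, "rest": 999_800}, "lib2": {"x": 50, "rest": 999_950}}
        )
        assert filter_highly_expressed(ab, 100, min_libraries=2) == ["rest"]


class TestPoolingCorrelation:
    def _single(self, counts):
        from mirsexdiff.quantify import LibraryCounts

        return build_count_table({"lib": LibraryCounts(totals=counts, mapped_total=sum(counts.values()))})

    def test_pooled_equal_to_mean_gives_r2_one(self):
        a = self._single({"x": 10, "y": 30, "z": 60})
        b = self._single({"x": 20, "y": 50, "z": 80})
        pooled = self._single({"x": 15, "y": 40, "z": 70})
        r2, p = pooling_correlation([a, b], pooled, ["x", "y", "z"])
        assert r2 == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_vector_rejected(self):
        a = self._single({"x": 10, "y": 10})
        b = self._single({"x": 10, "y": 10})
        pooled = self._single({"x": 5, "y": 9})
        with pytest.raises(ValueError, match="constant"):
            pooling_correlation([a, b], pooled, ["x", "y"])

    def test_needs_two_individuals(self):
        a = self._single({"x": 1, "y": 2})
        with pytest.raises(ValueError, match="two individual"):
            pooling_correlation([a], a, ["x", "y"])
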