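"""Sequence primitives: normalization, hamming, k-mers, constructs, I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promscreen.sequence import (
    ConstructLayout,
    PromoterRecord,
    assemble_construct,
    hamming_distance,
    kmer_count_matrix,
    kmer_count_vector,
    kmer_index,
    normalize_sequence,
    read_expression_table,
    read_fasta,
    write_expression_table,
    write_fasta,
)

dna = st.text(alphabet="ACGTacgt", min_size=1, max_size=30)


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [("acgt", "ACGT"), ("TTTT", "TTTT"), ("AcGt", "ACGT")])
    def test_uppercases(self, raw, expected):
        assert normalize_sequence(raw) == expected

    @pytest.mark.parametrize("bad", ["ACGN", "ACG-", "acgu", "", "AC GT"])
    def test_rejects_non_acgt(self, bad):
        with pytest.raises((ValueError, TypeError)):
            normalize_sequence(bad)

    @given(dna)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_length_preserving(self, raw):
        norm = normalize_sequence(raw)
        assert normalize_sequence(norm) == norm
        assert len(norm) == len(raw)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)]
    )
    def test_examples(self, a, b, d):
        assert hamming_distance(a, b) == d

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_distance("ACG", "ACGT")

    @given(dna)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetric_and_zero_on_self(self, s):
        s = normalize_sequence(s)
        assert hamming_distance(s, s) == 0


class TestKmerCounts:
    def test_single_base_counts(self):
        vec = kmer_count_vector("AAAA", 1)
        assert vec.tolist() == [4, 0, 0, 0]

    def test_single_window(self):
        vec = kmer_count_vector("ACGT", 4)
        assert vec.sum() == 1
        assert vec[kmer_index("ACGT")] == 1

    def test_window_count_by_enumeration(self):
        # "ACGTACGT": windows ACGT, CGTA, GTAC, TACG, ACGT
        vec = kmer_count_vector("ACGTACGT", 4)
        assert vec.sum() == 5
        assert vec[kmer_index("ACGT")] == 2
        assert vec[kmer_index("CGTA")] == 1

    def test_k_larger_than_sequence(self):
        with pytest.raises(ValueError):
            kmer_count_vector("ACG", 4)

    def test_brute_force_small_sequences(self):
        # exhaustive check of counts against a naive window scan
        for length in (4, 6):
            for seq_tuple in itertools.islice(itertools.product("ACGT", repeat=length), 0, 256, 7):
                seq = "".join(seq_tuple)
                for k in (1, 2, 3):
                    vec = kmer_count_vector(seq, k)
                    naive = {}
                    for i in range(length - k + 1):
                        naive[seq[i : i + k]] = naive.get(seq[i : i + k], 0) + 1
                    assert vec.sum() == length - k + 1
                    for kmer, count in naive.items():
                        assert vec[kmer_index(kmer)] == count

    @given(dna, st.integers(min_value=1, max_value=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_counts_sum_to_window_count(self, seq, k):
        seq = normalize_sequence(seq)
        if k > len(seq):
            return
        assert kmer_count_vector(seq, k).sum() == len(seq) - k + 1

    def test_matrix_matches_vectors(self):
        seqs = ["ACGTACGT", "TTTTAAAA", "GGGGCCCC"]
        mat = kmer_count_matrix(seqs, 3)
        for row, seq in zip(mat, seqs):
            assert np.array_equal(row, kmer_count_vector(seq, 3))


class TestConstruct:
    def test_minimal_concatenation(self):
        layout = ConstructLayout(
            pt_element="TTT", pa_element="AAA", insert_slot_length=4,
            insert_start_relative_to_tss=-170, insert_end_relative_to_tss=-166,
        )
        assert assemble_construct(layout, "ACGT") == "TTTACGTAAA"

    def test_wrong_insert_length(self):
        layout = ConstructLayout(
            pt_element="TTT", pa_element="AAA", insert_slot_length=4,
            insert_start_relative_to_tss=-170, insert_end_relative_to_tss=-166,
        )
        with pytest.raises(ValueError):
            assemble_construct(layout, "ACG")

    def test_scaffold_arithmetic_and_insert_recovery(self, rng):
        up = "".join(rng.choice(list("ACGT"), size=50))
        down = "".join(rng.choice(list("ACGT"), size=60))
        layout = ConstructLayout(
            upstream_scaffold=up, pt_element="TTTTT", pa_element="AAAAA",
            downstream_scaffold=down, insert_slot_length=80,
        )
        insert = "".join(rng.choice(list("ACGT"), size=80))
        construct = assemble_construct(layout, insert)
        assert len(construct) == layout.total_length == 50 + 5 + 80 + 5 + 60
        off = layout.insert_offset
        assert construct[off : off + 80] == insert

    def test_constructs_differ_only_on_insert_window(self):
        layout = ConstructLayout(
            upstream_scaffold="GG", pt_element="TTT", pa_element="AAA",
            insert_slot_length=4,
            insert_start_relative_to_tss=-170, insert_end_relative_to_tss=-166,
        )
        a = assemble_construct(layout, "ACGT")
        b = assemble_construct(layout, "TGCA")
        diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        off = layout.insert_offset
        assert set(diff) <= set(range(off, off + 4))

    def test_inconsistent_tss_labels(self):
        with pytest.raises(ValueError):
            ConstructLayout(insert_slot_length=80, insert_start_relative_to_tss=-170,
                            insert_end_relative_to_tss=-100)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        records = [("p1", "ACGTACGTAA"), ("p2", "TTTTCCCCGG"), ("p3", "A" * 100)]
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == records

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_lowercase_normalized(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">s\nacgt\n")
        assert read_fasta(path) == [("s", "ACGT")]

    def test_line_wrapping(self, tmp_path):
        path = tmp_path / "x.fasta"
        write_fasta([("s", "A" * 130)], path, width=60)
        lines = path.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 60, 10]


class TestExpressionTableIO:
    def test_round_trip_full_precision(self, tmp_path):
        records = [PromoterRecord("ACGT", 3.14159), PromoterRecord("TTTT", -2.0),
                   PromoterRecord("GGCC", 0.1234567890123456)]
        path = tmp_path / "t.tsv"
        write_expression_table(records, path)
        back = read_expression_table(path)
        assert back == records

    def test_two_rows(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("ACGT\t1.5\nTTTT\t2.5\n")
        recs = read_expression_table(path)
        assert len(recs) == 2 and recs[0].sequence == "ACGT"

    def test_non_numeric_expression(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("ACGT\tabc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression_table(path)

    def test_ragged_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("ACGT\t1.0\textra\n")
        with pytest.raises(ValueError, match="2 tab-separated"):
            read_expression_table(path)

    def test_header_autodetection(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sequence\texpression\nACGT\t1.0\n")
        recs = read_expression_table(path)
        assert len(recs) == 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            PromoterRecord("ACGT", float("nan"))
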