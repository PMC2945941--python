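import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctxbias.align_io import (
    AlignmentBlock,
    AlignmentError,
    apply_bed_mask,
    filter_blocks,
    filter_blocks_with_stats,
    iter_windows,
    read_blocks,
    read_blocks_with_stats,
    read_paired_fasta_with_stats,
    write_maf,
    write_paired_fasta,
)

block_strategy = st.integers(5, 40).flatmap(
    lambda n: st.tuples(
        st.text("ACGTN-", min_size=n, max_size=n),
        st.text("ACGTN-", min_size=n, max_size=n),
    )
).map(lambda pair: _make_block(*pair)).filter(lambda b: b is not None)


def _make_block(anc, desc):
    cols = [(a, d) for a, d in zip(anc, desc) if not (a == "-" and d == "-")]
    if not cols:
        return None
    return AlignmentBlock("hb", "".join(c[0] for c in cols), "".join(c[1] for c in cols))


class TestAlignmentBlock:
    def test_basic(self):
        b = AlignmentBlock("b", "ACGT", "ACAT")
        assert b.n_columns == 4

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            AlignmentBlock("b", "ACGT", "ACG")

    def test_illegal_character_names_offset(self):
        with pytest.raises(AlignmentError, match="offset 2"):
            AlignmentBlock("b", "ACGGT", "AC GT")

    def test_dual_gap_column_rejected(self):
        with pytest.raises(AlignmentError, match="gap in both"):
            AlignmentBlock("b", "A-T", "A-T")


class TestPairedFasta:
    def test_identity_plumbing(self, tmp_path):
        p = tmp_path / "pairs.fa"
        p.write_text(">b1|ancestor\nACGT\n>b1|descendant\nACAT\n")
        blocks = read_blocks(p, "paired_fasta")
        assert len(blocks) == 1
        assert blocks[0].n_columns == 4
        assert blocks[0].ancestor == "ACGT"

    def test_illegal_char_error_names_offset(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">b1|anc\nACG-T\n>b1|desc\nACXGT\n")
        with pytest.raises(AlignmentError, match="offset 2"):
            read_blocks(p, "paired_fasta")

    def test_unequal_lengths_hard_error(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">b1|anc\nACGT\n>b1|desc\nACG\n")
        with pytest.raises(AlignmentError, match="b1"):
            read_blocks(p, "paired_fasta")

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "pairs.fa"
        p.write_text(">x|anc\nacgt\n>x|desc\nacat\n")
        assert read_blocks(p, "paired_fasta")[0].descendant == "ACAT"

    def test_dual_gap_columns_dropped_and_counted(self, tmp_path):
        p = tmp_path / "pairs.fa"
        p.write_text(">x|anc\nAC-GT\n>x|desc\nAC-AT\n")
        blocks, stats = read_paired_fasta_with_stats(p)
        assert blocks[0].ancestor == "ACGT"
        assert stats.n_dual_gap_columns_dropped == 1

    def test_roundtrip(self, tmp_path):
        blocks = [
            AlignmentBlock("a0", "ACGT-A", "ACATTA"),
            AlignmentBlock("a1", "GGNGG", "GG-GG"),
        ]
        p = tmp_path / "out.fa"
        write_paired_fasta(blocks, p)
        back = read_blocks(p, "paired_fasta")
        assert [(b.ancestor, b.descendant) for b in back] == [
            (b.ancestor, b.descendant) for b in blocks
        ]


MAF_TEXT = """##maf version=1

a score=0
s anc.chr1 0 6 + 100 CACGCA
s desc.chr1 0 6 + 100 CATGCA

a score=0
s anc.chr1 6 4 + 100 ACGT
s other.chr1 0 4 + 100 ACGT

a score=0
s anc.chr1 10 4 + 100 AC-T
s desc.chr1 10 4 + 100 ACGT
"""


class TestMaf:
    def test_skip_count(self, tmp_path):
        p = tmp_path / "in.maf"
        p.write_text(MAF_TEXT)
        blocks, stats = read_blocks_with_stats(p, "maf", "anc", "desc")
        assert len(blocks) == 2
        assert stats.n_skipped_missing_label == 1
        assert blocks[0].ancestor == "CACGCA"
        assert blocks[0].source_coords == ("anc.chr1", 0, 6, "+")

    def test_missing_labels_raise(self, tmp_path):
        p = tmp_path / "in.maf"
        p.write_text(MAF_TEXT)
        with pytest.raises(ValueError):
            read_blocks(p, "maf")

    def test_write_read_roundtrip(self, tmp_path):
        blocks = [AlignmentBlock("x", "ACGTAC", "ACATAC")]
        p = tmp_path / "out.maf"
        write_maf(blocks, p, "anc", "desc")
        back = read_blocks(p, "maf", "anc", "desc")
        assert back[0].ancestor == "ACGTAC"
        assert back[0].descendant == "ACATAC"


class TestFilterBlocks:
    def test_nine_contiguous_removed(self):
        b = AlignmentBlock("b", "AAAAAAAAA-AAAAAAAAA", "AAAAAAAAATAAAAAAAAA")
        assert filter_blocks([b], min_contiguous_nongap=10) == []

    def test_ten_gap_free_retained(self):
        b = AlignmentBlock("b", "A" * 10, "A" * 10)
        assert filter_blocks([b], min_contiguous_nongap=10) == [b]

    def test_more_gaps_than_aligned_removed(self):
        # 6 gapped vs 5 aligned columns
        b = AlignmentBlock("b", "AAAAAAAAAAA", "AAAAA------")
        survivors, stats = filter_blocks_with_stats(b and [b], min_contiguous_nongap=1)
        assert survivors == []
        assert stats.n_removed_gappy == 1

    def test_equal_gaps_and_aligned_retained(self):
        b = AlignmentBlock("b", "AAAAAAAAAA", "AAAAA-----")
        assert filter_blocks([b], min_contiguous_nongap=1) == [b]

    def test_order_preserved_and_counts(self):
        keep1 = AlignmentBlock("k1", "A" * 12, "A" * 12)
        short = AlignmentBlock("s", "AAAA-AAAA", "AAAAAAAAA")
        keep2 = AlignmentBlock("k2", "C" * 15, "C" * 15)
        survivors, stats = filter_blocks_with_stats([keep1, short, keep2])
        assert [b.block_id for b in survivors] == ["k1", "k2"]
        assert stats.n_removed_short_run == 1

    def test_precondition(self):
        with pytest.raises(ValueError):
            filter_blocks([], min_contiguous_nongap=0)

    @given(st.lists(block_strategy, max_size=6))
    def test_idempotent(self, blocks):
        once = filter_blocks(blocks, 3)
        twice = filter_blocks(once, 3)
        assert once == twice


class TestIterWindows:
    def test_hand_enumeration(self, hand_block):
        got = list(iter_windows(hand_block, 2))
        assert got == [("CA", "CA"), ("AC", "AT"), ("CG", "TG"), ("GC", "GC"), ("CA", "CA")]

    def test_cpg_exclusion(self, hand_block):
        got = list(iter_windows(hand_block, 2, exclude_ancestral_cpg=True))
        assert got == [("CA", "CA"), ("CA", "CA")]

    def test_gap_splits_runs(self):
        b = AlignmentBlock("b", "AC-GT", "ACAGT")
        assert list(iter_windows(b, 3)) == []
        assert list(iter_windows(b, 2)) == [("AC", "AC"), ("GT", "GT")]

    def test_n_breaks_run_like_gap(self):
        b = AlignmentBlock("b", "ACNGT", "ACAGT")
        assert list(iter_windows(b, 3)) == []

    @given(st.integers(1, 4), st.text("ACGT", min_size=4, max_size=30))
    def test_window_count_gap_free(self, L, seq):
        b = AlignmentBlock("b", seq, seq)
        assert len(list(iter_windows(b, L))) == max(0, len(seq) - L + 1)

    @given(block_strategy, st.integers(1, 3))
    def test_length_consistency(self, block, L):
        longer = list(iter_windows(block, L + 1))
        shorter = set(iter_windows(block, L))
        for anc, desc in longer:
            assert (anc[:-1], desc[:-1]) in shorter
            assert (anc[1:], desc[1:]) in shorter


class TestBedMask:
    def test_clipping(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t2\t6\n")
        b = AlignmentBlock("b", "ACGTACGT", "ACGTACGT", ("chr1", 0, 8, "+"))
        out = apply_bed_mask([b], bed)
        assert len(out) == 1
        assert out[0].ancestor == "GTAC"

    def test_no_coords_dropped(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t0\t100\n")
        b = AlignmentBlock("b", "ACGT", "ACGT")
        assert apply_bed_mask([b], bed) == []
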