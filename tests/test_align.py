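import numpy as np
import pytest

from mtdel import (
    align_read,
    build_seed_index,
    classify_reads,
    infer_junction,
    parse_last_tab,
    revcomp,
)
from mtdel.align import AMBIGUOUS, NON_SPLIT, SPLIT, UNALIGNED, ReadAlignment
from mtdel.io import FormatError, ReferenceGenome


class TestSeedIndex:
    def test_doubled_reference_kmer_count(self):
        ref = ReferenceGenome("m", "ACGTACGT")
        idx = build_seed_index(ref, k=8)
        assert sum(len(v) for v in idx.table.values()) == 9

    @pytest.mark.parametrize("k", [7, 32])
    def test_k_out_of_range(self, small_ref, k):
        with pytest.raises(ValueError):
            build_seed_index(small_ref, k=k)

    def test_k_longer_than_reference(self):
        with pytest.raises(ValueError):
            build_seed_index(ReferenceGenome("m", "ACGTACGTAC"), k=12)

    def test_n_kmers_skipped(self):
        ref = ReferenceGenome("m", "ACGTNCGTACGTAAAA")
        idx = build_seed_index(ref, k=8)
        assert not any("N" in kmer for kmer in idx.table)


class TestAlignRead:
    def test_exact_substring_single_block(self, small_ref, small_index):
        read = small_ref.sequence[150:250]
        aln = align_read(small_index, read, "r")
        assert aln.classification == NON_SPLIT
        blk = aln.blocks[0]
        assert (blk.ref_start, blk.ref_end) == (150, 250)

    def test_split_read_two_blocks(self, small_ref, small_index, placements_oracle):
        read = small_ref.sequence[150:200] + small_ref.sequence[600:650]
        aln = align_read(small_index, read, "r")
        assert aln.classification == SPLIT
        b1, b2 = aln.blocks
        # the exact cut may shift within junction micro-homology; any
        # brute-force-valid decomposition is correct
        _, splits = placements_oracle(small_ref.sequence, read)
        assert (b1.read_end, b1.ref_start, b2.ref_start) in splits
        # every valid decomposition implies the same deleted interval length
        assert (b2.ref_start - b1.ref_end) % small_ref.length == 400

    def test_random_read_unaligned(self, small_index):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), 100))
        assert align_read(small_index, read, "r").classification == UNALIGNED

    def test_small_gap_reclassified_non_split(self, small_ref, small_index):
        # gap of 10 < min_del_len
        read = small_ref.sequence[150:200] + small_ref.sequence[210:260]
        aln = align_read(small_index, read, "r")
        assert aln.classification == NON_SPLIT

    def test_read_with_errors_still_aligns(self, small_ref, small_index):
        read = list(small_ref.sequence[300:400])
        read[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[50]]
        aln = align_read(small_index, "".join(read), "r")
        assert aln.classification == NON_SPLIT
        assert aln.blocks[0].ref_start == 300

    def test_origin_spanning_block(self, small_ref, small_index):
        L = small_ref.length
        read = small_ref.sequence[L - 50 :] + small_ref.sequence[:50]
        aln = align_read(small_index, read, "r")
        assert aln.classification == NON_SPLIT
        s, e = aln.blocks[0].ref_interval_mod(L)
        assert s == L - 50 and e == L + 50


class TestAlignerOracle:
    """Seed-and-extend results must agree with brute-force exact search."""

    def test_single_segment_reads(self, small_ref, small_index, placements_oracle):
        rng = np.random.default_rng(1)
        for _ in range(30):
            start = int(rng.integers(0, small_ref.length))
            length = int(rng.integers(40, 120))
            read = (small_ref.sequence * 2)[start : start + length]
            singles, _ = placements_oracle(small_ref.sequence, read)
            aln = align_read(small_index, read, "r")
            assert aln.classification == NON_SPLIT
            assert aln.blocks[0].ref_start in singles
            assert aln.blocks[0].ref_start == min(singles)

    def test_two_segment_reads(self, small_ref, small_index, placements_oracle):
        rng = np.random.default_rng(2)
        L = small_ref.length
        doubled = small_ref.sequence * 2
        for _ in range(30):
            a = int(rng.integers(0, L))
            la = int(rng.integers(25, 60))
            gap = int(rng.integers(30, 400))
            lb = int(rng.integers(25, 60))
            b = (a + la + gap) % L
            read = doubled[a : a + la] + doubled[b : b + lb]
            singles, splits = placements_oracle(small_ref.sequence, read)
            aln = align_read(small_index, read, "r")
            if singles:  # the concatenation happens to exist contiguously
                assert aln.classification == NON_SPLIT
                continue
            assert aln.classification == SPLIT
            b1, b2 = aln.blocks
            cut = b1.read_end
            assert (cut, b1.ref_start, b2.ref_start) in splits

    def test_strand_symmetry(self, small_ref, small_index):
        rng = np.random.default_rng(3)
        for _ in range(10):
            start = int(rng.integers(0, small_ref.length - 120))
            read = small_ref.sequence[start : start + 100]
            fwd = align_read(small_index, read, "r")
            rev = align_read(small_index, revcomp(read), "r")
            assert [b.ref_start for b in fwd.blocks] == [b.ref_start for b in rev.blocks]
            assert fwd.strand == "+" and rev.strand == "-"

    def test_rotation_shifts_coordinates(self, small_ref):
        r = 137
        rotated = ReferenceGenome(
            "rot", small_ref.sequence[r:] + small_ref.sequence[:r]
        )
        idx0 = build_seed_index(small_ref)
        idx1 = build_seed_index(rotated)
        L = small_ref.length
        rng = np.random.default_rng(4)
        for _ in range(10):
            start = int(rng.integers(0, L))
            read = (small_ref.sequence * 2)[start : start + 100]
            a0 = align_read(idx0, read, "r")
            a1 = align_read(idx1, read, "r")
            assert a1.classification == a0.classification == NON_SPLIT
            assert a1.blocks[0].ref_start == (a0.blocks[0].ref_start - r) % L


class TestSplitJunctionRoundTrip:
    def test_plus_and_minus_strand_agree(self, small_ref, small_index):
        from mtdel.simulate import make_deletion_genome

        g = make_deletion_genome(small_ref, 501, 900)
        read = g[450:550]  # spans the junction at index 500
        fwd = align_read(small_index, read, "r")
        rev = align_read(small_index, revcomp(read), "r")
        L = small_ref.length
        jf = infer_junction(fwd, L)
        jr = infer_junction(rev, L)
        assert jf == jr
        ds, de, wraps = jf
        # breakpoints may shift within junction micro-homology but the
        # deleted interval length is invariant
        assert not wraps
        assert de - ds + 1 == 400
        assert abs(ds - 501) <= 3


class TestParseLastTab:
    def _write(self, tmp_path, lines):
        p = tmp_path / "a.tab"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_single_line_non_split(self, tmp_path):
        p = self._write(
            tmp_path, ["100\tchrM\t100\t100\t+\t16300\tr1\t0\t100\t+\t100\t100"]
        )
        alns = parse_last_tab(p)
        assert len(alns) == 1
        assert alns[0].classification == NON_SPLIT
        assert alns[0].blocks[0].ref_start == 100
        assert alns[0].blocks[0].ref_end == 200

    def test_two_lines_split(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                "50\tchrM\t100\t50\t+\t16300\tr1\t0\t50\t+\t100\t50",
                "50\tchrM\t600\t50\t+\t16300\tr1\t50\t50\t+\t100\t50",
            ],
        )
        (aln,) = parse_last_tab(p)
        assert aln.classification == SPLIT
        assert [b.ref_start for b in aln.blocks] == [100, 600]

    def test_three_lines_ambiguous(self, tmp_path):
        lines = [
            f"50\tchrM\t{s}\t30\t+\t16300\tr1\t{q}\t30\t+\t100\t30"
            for s, q in ((100, 0), (600, 30), (900, 60))
        ]
        (aln,) = parse_last_tab(self._write(tmp_path, lines))
        assert aln.classification == AMBIGUOUS

    def test_minus_strand_converted_to_forward_read_coords(self, tmp_path):
        # 40 bases aligned starting at RC-coordinate 10 on a 100-base read
        p = self._write(
            tmp_path, ["40\tchrM\t500\t40\t+\t16300\tr1\t10\t40\t-\t100\t40"]
        )
        (aln,) = parse_last_tab(p)
        blk = aln.blocks[0]
        assert (blk.read_start, blk.read_end) == (50, 90)
        assert blk.strand == "-"

    @pytest.mark.parametrize(
        "line",
        [
            "100\tchrM\t100\t100\t+\t16300\tr1\t0\t100\t+",  # too few fields
            "x\tchrM\t100\t100\t+\t16300\tr1\t0\t100\t+\t100\t100",  # non-numeric
        ],
    )
    def test_malformed_lines_rejected(self, tmp_path, line):
        with pytest.raises(FormatError):
            parse_last_tab(self._write(tmp_path, [line]))

    def test_wrong_reference_rejected(self, tmp_path):
        p = self._write(
            tmp_path, ["100\tchr1\t100\t100\t+\t16300\tr1\t0\t100\t+\t100\t100"]
        )
        with pytest.raises(FormatError, match="chr1"):
            parse_last_tab(p, ref_name="chrM")


class TestClassifyReads:
    def test_tallies_sum_to_distinct_reads(self):
        alns = [
            ReadAlignment("a", [], UNALIGNED),
            ReadAlignment("b", [], NON_SPLIT),
            ReadAlignment("c", [], SPLIT),
        ]
        assert classify_reads(alns) == {
            NON_SPLIT: 1, SPLIT: 1, UNALIGNED: 1, AMBIGUOUS: 0,
        }

    def test_empty_input(self):
        assert sum(classify_reads([]).values()) == 0

    def test_conflicting_duplicates_ambiguous(self):
        from mtdel.align import AlignmentBlock

        b1 = AlignmentBlock("a", 0, 50, 0, 50)
        b2 = AlignmentBlock("a", 500, 550, 0, 50)
        tallies = classify_reads(
            [ReadAlignment("a", [b1], NON_SPLIT), ReadAlignment("a", [b2], NON_SPLIT)]
        )
        assert tallies[AMBIGUOUS] == 1
        assert sum(tallies.values()) == 1
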