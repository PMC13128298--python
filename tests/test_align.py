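"""Native aligner: threshold, scoring-oracle equivalence, ties, SAM output."""

import numpy as np
import pysam
import pytest

from conftest import mref_from_seqs, processed
from msrseq.align import (
    AlignmentError,
    AlignParams,
    align_read,
    run_alignment,
    score_threshold,
)

NEG = float("-inf")


def oracle_penalties(seq, qual, mn=2, mx=5):
    """Scaled (x40) per-base mismatch penalty, interpolated by quality."""
    pens = []
    for base, qc in zip(seq, qual):
        if base == "N":
            pens.append(mn * 40)
        else:
            q = min(ord(qc) - 33, 40)
            pens.append(mn * 40 + ((mx - mn) * 40 * q) // 40)
    return pens


def oracle_glocal_score(seq, qual, ref, mn=2, mx=5, gap_open=5, gap_extend=3):
    """Independent full-matrix affine DP: full read vs any reference substring.

    Returns the best scaled (x40) score.  Written as plain dict-of-dicts
    dynamic programming with no shared code with the package kernels.
    """
    pen = oracle_penalties(seq, qual, mn, mx)
    go, ge = gap_open * 40, gap_extend * 40
    n, m = len(seq), len(ref)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            I[i][j] = max(M[i - 1][j] - go - ge, I[i - 1][j] - ge)
            if j > 0:
                sub = 0 if (seq[i - 1] == ref[j - 1] and seq[i - 1] != "N") else -pen[i - 1]
                M[i][j] = max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1]) + sub
                D[i][j] = max(M[i][j - 1] - go - ge, D[i][j - 1] - ge)
    return int(max(max(M[n]), max(I[n])))


def cigar_score(rec, ref_seq, mn=2, mx=5, gap_open=5, gap_extend=3):
    """Recompute the scaled score implied by a record's cigar path."""
    pen = oracle_penalties(rec.sequence, rec.quality, mn, mx)
    score = 0
    ri, qi = rec.ref_start, 0
    for op, length in rec.cigar:
        if op == "M":
            for k in range(length):
                if rec.sequence[qi + k] != ref_seq[ri + k] or rec.sequence[qi + k] == "N":
                    score -= pen[qi + k]
            ri += length
            qi += length
        else:
            score -= gap_open * 40 + gap_extend * 40 * length
            if op == "I":
                qi += length
            else:
                ri += length
    return score


def random_pair(rng, min_len=20, max_len=80, error=0.15):
    bases = "ACGT"
    ref_len = int(rng.integers(40, max_len + 21))
    ref = "".join(bases[i] for i in rng.integers(0, 4, ref_len))
    rl = int(rng.integers(min_len, min(max_len, ref_len) + 1))
    start = int(rng.integers(0, ref_len - rl + 1))
    read = list(ref[start : start + rl])
    for i in range(len(read)):
        if rng.random() < error:
            r = rng.random()
            if r < 0.6:  # substitution
                read[i] = bases[int(rng.integers(0, 4))]
            elif r < 0.8 and len(read) > min_len:  # deletion
                read[i] = ""
            else:  # insertion
                read[i] += bases[int(rng.integers(0, 4))]
    return "".join(read), ref


class TestScoreThreshold:
    def test_linear_formula(self):
        assert score_threshold(70) == pytest.approx(-0.7 - 0.7 * 70)  # -49.7
        assert score_threshold(1) == pytest.approx(-1.4)

    def test_zero_length_invalid(self):
        with pytest.raises(AlignmentError):
            score_threshold(0)

    def test_zero_slope_zero_intercept_admits_only_perfect(self):
        p = AlignParams(score_min_intercept=0.0, score_min_slope=0.0)
        mref = mref_from_seqs({"a": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTCCA"})
        perfect = processed("ACGTACGTACGTACGT")
        assert align_read(perfect, mref, p) is not None
        imperfect = processed("ACGTACGTACGTACGA")
        assert align_read(imperfect, mref, p) is None


class TestAlignRead:
    def test_perfect_read_scores_zero(self, refset10, mref10):
        e = refset10.entries[0]
        rec = align_read(processed(e.gene_sequence + "CCA"), mref10)
        assert rec.score == 0
        assert rec.n_mismatches == 0
        assert rec.tie_ids == {e.id}
        assert (rec.ref_start, rec.ref_end) == (0, len(e.gene_sequence) + 3)

    def test_identical_references_tie(self):
        seq = "ACGGTTCAAGGCCATTGGACCATGCCATTGGAAGCTTGACCA"
        mref = mref_from_seqs({"b": seq, "a": seq})
        rec = align_read(processed(seq[:30]), mref)
        assert rec.tie_ids == {"a", "b"}
        assert rec.ref_id == "a"  # lexicographically smallest primary

    def test_mismatch_penalty_quality_scaled(self):
        ref = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTCCA"
        mref = mref_from_seqs({"a": ref})
        read = "T" + ref[1:20]
        hi = align_read(processed(read, quality="I" * 20), mref)  # Q40
        lo = align_read(processed(read, quality="#" * 20), mref)  # Q2
        assert hi.score == -5.0
        assert lo.score == pytest.approx(-(2 + 3 * 2 / 40))
        assert hi.n_mismatches == lo.n_mismatches == 1

    def test_n_base_scores_minimum_penalty(self):
        ref = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTCCA"
        mref = mref_from_seqs({"a": ref})
        read = "N" + ref[1:20]
        rec = align_read(processed(read, quality="I" * 20), mref)
        assert rec.score == -2.0

    def test_non_acgtn_is_hard_error(self, mref10):
        with pytest.raises(AlignmentError, match="non-ACGTN"):
            align_read(processed("ACGTX" + "ACGT" * 5), mref10)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            read, ref = random_pair(rng)
            mref = mref_from_seqs({"a": ref})
            p = AlignParams(score_min_intercept=-10_000, score_min_slope=0)
            rec = align_read(processed(read), mref, p)
            expected = oracle_glocal_score(read, "?" * len(read), ref)
            assert rec is not None
            assert int(round(rec.score * 40)) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_traceback_path_reproduces_score(self, seed):
        # the cigar-implied score must equal the reported DP score
        rng = np.random.default_rng(100 + seed)
        for _ in range(10):
            read, ref = random_pair(rng, error=0.1)
            mref = mref_from_seqs({"a": ref})
            p = AlignParams(score_min_intercept=-10_000, score_min_slope=0)
            rec = align_read(processed(read), mref, p)
            assert cigar_score(rec, ref) == int(round(rec.score * 40))
            # end-to-end: the read is fully consumed by the cigar
            consumed = sum(n for op, n in rec.cigar if op in "MI")
            assert consumed == len(read)

    def test_threshold_relaxation_never_unmaps(self):
        rng = np.random.default_rng(7)
        strict = AlignParams()
        loose = AlignParams(score_min_slope=-1.0)
        mapped_strict, mapped_loose = 0, 0
        for _ in range(50):
            read, ref = random_pair(rng, error=0.25)
            mref = mref_from_seqs({"a": ref})
            rs = align_read(processed(read), mref, strict)
            rl = align_read(processed(read), mref, loose)
            if rs is not None:
                assert rl is not None  # relaxing cannot unmap
                mapped_strict += 1
            if rl is not None:
                mapped_loose += 1
        assert mapped_loose >= mapped_strict


class TestRunAlignment:
    def test_sam_parses_and_roundtrips(self, refset10, mref10, tmp_path):
        reads = [
            processed(e.gene_sequence + "CCA", read_id=f"read{i}")
            for i, e in enumerate(refset10.entries[:5])
        ]
        reads.append(processed("GGGTTTAAACCCGGGTTTAAA", read_id="junk"))
        sam_path = tmp_path / "out.sam"
        records, table = run_alignment(reads, mref10, sam_path=sam_path)
        with pysam.AlignmentFile(sam_path, "r") as fh:
            segs = list(fh)
        assert len(segs) == 6
        mapped = [s for s in segs if not s.is_unmapped]
        assert len(mapped) == len(records)
        for seg, rec in zip(mapped, records):
            assert seg.query_name == rec.read_id
            assert seg.reference_name == rec.ref_id
            assert seg.reference_start == rec.ref_start
            assert seg.get_tag("NH") == len(rec.tie_ids)

    def test_empty_input_header_only(self, mref10, tmp_path):
        sam_path = tmp_path / "empty.sam"
        records, table = run_alignment([], mref10, sam_path=sam_path)
        assert records == [] and table.empty
        with pysam.AlignmentFile(sam_path, "r") as fh:
            assert len(fh.header["SQ"]) == len(mref10)
            assert list(fh) == []

    def test_deterministic_sam_bytes(self, refset10, mref10, tmp_path):
        reads = [
            processed(e.gene_sequence[5:] + "CCA", read_id=f"read{i}")
            for i, e in enumerate(refset10.entries)
        ]
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        run_alignment(reads, mref10, sam_path=p1)
        run_alignment(reads, mref10, sam_path=p2)
        assert p1.read_bytes() == p2.read_bytes()
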