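"""Read cleanup: merging, adapter removal, 5' extension trimming."""

import numpy as np
import pytest

from conftest import mref_from_seqs, processed
from msrseq.io import FastqRead, revcomp
from msrseq.preprocess import (
    AdapterParams,
    FivePrimeTrimmer,
    MergeParams,
    merge_pair,
    process_pairs,
    trim_cho_adapter,
)
from msrseq.refdb import build_mapping_reference
from msrseq.simulate import (
    LibraryConfig,
    ReferenceProfile,
    SimProfile,
    simulate_library,
    synthetic_reference_set,
)

ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


def fq(seq, read_id="r", qual=None):
    return FastqRead(read_id, seq, qual if qual is not None else "?" * len(seq))


def oracle_merge(seq1, seq2_rc, min_overlap, max_rate):
    """Brute-force overlap scan: lowest mismatch rate, ties to longest."""
    best = None
    for L in range(min_overlap, min(len(seq1), len(seq2_rc)) + 1):
        mm = sum(a != b for a, b in zip(seq1[-L:], seq2_rc[:L]))
        rate = mm / L
        if rate <= max_rate and (
            best is None or rate < best[0] or (rate == best[0] and L > best[1])
        ):
            best = (rate, L, mm)
    return best


class TestMergePair:
    def test_short_overlap_example(self):
        # suffix "CGTAC" of r1 matches prefix of rc(r2) exactly
        r1 = fq("ACGTACGTAC")
        r2 = fq(revcomp("CGTACGGGGG"))
        m = merge_pair(r1, r2, MergeParams(min_overlap=5))
        assert m.sequence == "ACGTACGTACGGGGG"
        assert m.overlap_length == 5
        assert m.mismatches_in_overlap == 0

    def test_identical_reads_merge_to_themselves(self):
        seq = "ACGTACGGTTCA" * 12 + "ACGTAC"  # 150-mer
        m = merge_pair(fq(seq), fq(revcomp(seq)))
        assert m.sequence == seq
        assert m.overlap_length == len(seq)

    def test_disjoint_sequences_rejected(self):
        assert merge_pair(fq("A" * 60), fq("A" * 60)) is None  # rc gives T*60

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            FastqRead("r", "ACGT", "???")

    def test_disagreement_resolved_by_higher_quality(self):
        seq = "ACGTAACCGGTTACGTACGT"
        other = "T" + seq[1:]
        r1 = fq(seq, qual="I" * len(seq))  # Q40 everywhere
        r2 = FastqRead("r", revcomp(other), "#" * len(other))  # Q2 everywhere
        m = merge_pair(r1, r2, MergeParams(min_overlap=10, max_mismatch_rate=0.2))
        assert m.sequence == seq  # r1's high-quality base wins
        assert m.mismatches_in_overlap == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        construct = "".join(bases[i] for i in rng.integers(0, 4, 90))
        r1_seq = construct[:70]
        r2_seq = revcomp(construct[30:])
        # sprinkle errors on r2
        arr = list(r2_seq)
        for i in rng.integers(0, len(arr), 3):
            arr[i] = bases[(bases.index(arr[i]) + 1) % 4]
        r2_seq = "".join(arr)
        params = MergeParams(min_overlap=10, max_mismatch_rate=0.15)
        expected = oracle_merge(r1_seq, revcomp(r2_seq), 10, 0.15)
        m = merge_pair(fq(r1_seq), fq(r2_seq), params)
        if expected is None:
            assert m is None
        else:
            assert (m.overlap_length, m.mismatches_in_overlap) == (
                expected[1],
                expected[2],
            )


class TestAdapterTrim:
    def test_exact_adapter_removed(self):
        trna = "GGGTCGTTAGCTCAGTTGGTAGAGCAGTTGACT"
        m = merge_pair(fq(trna + ADAPTER), fq(revcomp(trna + ADAPTER)))
        p = trim_cho_adapter(m, ADAPTER)
        assert p.sequence == trna

    def test_adapter_with_one_mismatch_tolerated(self):
        trna = "GGGTCGTTAGCTCAGTTGGTAGAGCAGTTGACT"
        mutated = "C" + ADAPTER[1:]
        m = merge_pair(fq(trna + mutated), fq(revcomp(trna + mutated)))
        p = trim_cho_adapter(m, ADAPTER, AdapterParams(max_adapter_mismatches=2))
        assert p is not None and p.sequence == trna

    def test_missing_adapter_rejected(self):
        trna = "GGGTCGTTAGCTCAGTTGGTAGAGCAGTTGACTAAACCGGTT"
        m = merge_pair(fq(trna), fq(revcomp(trna)))
        assert trim_cho_adapter(m, ADAPTER) is None

    def test_short_remainder_rejected(self):
        m = merge_pair(fq("ACGTACGTAC" + ADAPTER), fq(revcomp("ACGTACGTAC" + ADAPTER)))
        assert trim_cho_adapter(m, ADAPTER, AdapterParams(min_remaining=15)) is None


class TestFivePrimeTrim:
    def test_extension_removed_exactly(self, refset10, mref10):
        gene = refset10.entries[0].gene_sequence
        ext = "TTGACGCAATCG"  # 12 nt of junk
        trimmer = FivePrimeTrimmer(mref10)
        out = trimmer.trim(processed(ext + gene + "CCA"))
        assert out.five_prime_trimmed_bases == 12
        assert out.sequence == gene + "CCA"

    def test_read_without_extension_unchanged(self, refset10, mref10):
        gene = refset10.entries[0].gene_sequence
        out = FivePrimeTrimmer(mref10).trim(processed(gene + "CCA"))
        assert out.five_prime_trimmed_bases == 0
        assert out.sequence == gene + "CCA"

    def test_internal_fragment_unchanged(self, refset10, mref10):
        # a tRNA-derived fragment aligns internally; nothing projects
        # beyond the reference start
        gene = refset10.entries[0].gene_sequence
        frag = gene[20:60]
        out = FivePrimeTrimmer(mref10).trim(processed(frag))
        assert out.sequence == frag

    def test_never_removes_aligned_bases(self, refset10, mref10):
        trimmer = FivePrimeTrimmer(mref10)
        for e in refset10.entries[:5]:
            read = e.gene_sequence + "CCA"
            for ext_len in (0, 1, 5, 12):
                out = trimmer.trim(processed("G" * 0 + "ATCGTCAGGTCA"[:ext_len] + read))
                assert out.sequence.endswith(read)
                assert len(out.sequence) >= len(read)


class TestAccounting:
    def test_every_pair_classified_once(self):
        refset = synthetic_reference_set(3, seed=5)
        mref = build_mapping_reference(refset)
        prof = SimProfile({e.id: ReferenceProfile() for e in refset})
        cfg = LibraryConfig(n_read_pairs=400, seed=6, error_rate=0.01)
        lib = simulate_library(refset, prof, cfg)
        # add pairs that cannot merge and pairs without adapter
        r1s = lib.r1 + [fq("A" * 80, "nomerge"), fq("ACGT" * 20, "noadapter")]
        r2s = lib.r2 + [fq("A" * 80, "nomerge"), fq(revcomp("ACGT" * 20), "noadapter")]
        out, stats = process_pairs(zip(r1s, r2s), cfg.adapter_seq, mref)
        assert stats.input_pairs == 402
        assert (
            stats.processed
            + stats.rejected_no_merge
            + stats.rejected_no_adapter
            + stats.rejected_too_short
            == stats.input_pairs
        )
        assert stats.rejected_no_merge >= 1
        assert stats.rejected_no_adapter >= 1

    def test_zero_error_full_recovery(self):
        # with no sequencing error every non-truncated read is processed and
        # equals the truth molecule
        refset = synthetic_reference_set(3, seed=9)
        mref = build_mapping_reference(refset)
        prof = SimProfile(
            {
                e.id: ReferenceProfile(
                    tail_distribution={"CCA": 0.7, "CC": 0.3}, five_prime_extension_prob=0.2
                )
                for e in refset
            }
        )
        cfg = LibraryConfig(n_read_pairs=300, seed=7)
        lib = simulate_library(refset, prof, cfg)
        out, stats = process_pairs(zip(lib.r1, lib.r2), cfg.adapter_seq, mref)
        assert stats.processed == 300
        for p in out:
            truth = lib.truth.reads[p.id]
            gene = refset.entry(truth.ref_id).gene_sequence
            drop = {"CCA": 0, "CC": 1, "C": 2}[truth.tail_state]
            molecule = (gene + "CCA")[: len(gene) + 3 - drop]
            assert p.sequence == molecule
            assert p.five_prime_trimmed_bases == truth.extension_length
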