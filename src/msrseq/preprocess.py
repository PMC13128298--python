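"""Read cleanup: pair merging, CHO-adapter removal, 5' extension trimming.

Every input pair is classified into exactly one of {processed,
rejected_no_merge, rejected_no_adapter, rejected_too_short}; the stage
counts always sum to the number of input pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from ._dp import local_align
from .io import FastqRead, revcomp
from .refdb import MappingReference

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string onto uint8 codes (A=0 C=1 G=2 T=3, other=N=4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class MergeParams:
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1


@dataclass
class AdapterParams:
    max_adapter_mismatches: int = 2
    min_remaining: int = 15


@dataclass
class LocalTrimParams:
    min_local_score: int = 20
    word_size: int = 11


@dataclass
class MergedRead:
    id: str
    sequence: str
    quality: str
    overlap_length: int
    mismatches_in_overlap: int


@dataclass
class ProcessedRead:
    id: str
    sequence: str
    quality: str
    merged_ok: bool = True
    adapter_found: bool = True
    five_prime_trimmed_bases: int = 0


@dataclass
class PreprocessStats:
    input_pairs: int = 0
    processed: int = 0
    rejected_no_merge: int = 0
    rejected_no_adapter: int = 0
    rejected_too_short: int = 0

    def check(self) -> None:
        total = (
            self.processed
            + self.rejected_no_merge
            + self.rejected_no_adapter
            + self.rejected_too_short
        )
        if total != self.input_pairs:
            raise AssertionError("preprocess accounting does not sum to input pairs")


def merge_pair(r1: FastqRead, r2: FastqRead, params: MergeParams | None = None) -> MergedRead | None:
    """Merge a read pair via the best suffix(r1)/prefix(rc(r2)) overlap.

    Among overlaps with mismatch rate <= max_mismatch_rate, the lowest
    mismatch rate wins; ties go to the longer overlap.  Disagreeing
    overlap bases are resolved by the higher-quality call.  Returns None
    (REJECT) when no qualifying overlap exists.
    """
    params = params or MergeParams()
    seq1, qual1 = r1.sequence, r1.quality
    seq2 = revcomp(r2.sequence)
    qual2 = r2.quality[::-1]
    n1, n2 = len(seq1), len(seq2)
    max_len = min(n1, n2)
    if max_len < params.min_overlap:
        return None

    # Fast path: perfect overlap at the maximal length (the common case
    # for short constructs fully covered by both reads).
    best_len = 0
    best_mm = 0
    if seq1[n1 - max_len :] == seq2[:max_len]:
        best_len, best_mm = max_len, 0
    else:
        a = encode(seq1)
        b = encode(seq2)
        best_rate = params.max_mismatch_rate + 1e-12
        for L in range(max_len, params.min_overlap - 1, -1):
            mm = int((a[n1 - L :] != b[:L]).sum())
            rate = mm / L
            if rate < best_rate - 1e-12:
                best_rate = rate
                best_len, best_mm = L, mm
        if best_len == 0:
            return None

    L = best_len
    over1, over2 = seq1[n1 - L :], seq2[:L]
    q1, q2 = qual1[n1 - L :], qual2[:L]
    if best_mm == 0:
        overlap_seq = over1
        overlap_qual = "".join(max(x, y) for x, y in zip(q1, q2))
    else:
        bases = []
        quals = []
        for x, y, qx, qy in zip(over1, over2, q1, q2):
            if x == y:
                bases.append(x)
                quals.append(max(qx, qy))
            elif qx >= qy:
                bases.append(x)
                quals.append(qx)
            else:
                bases.append(y)
                quals.append(qy)
        overlap_seq = "".join(bases)
        overlap_qual = "".join(quals)

    merged_seq = seq1[: n1 - L] + overlap_seq + seq2[L:]
    merged_qual = qual1[: n1 - L] + overlap_qual + qual2[L:]
    return MergedRead(r1.id, merged_seq, merged_qual, L, best_mm)


def trim_cho_adapter(
    m: MergedRead, adapter: str, params: AdapterParams | None = None
) -> ProcessedRead | None:
    """Locate the CHO adapter near the merged 3' end and cut it off.

    The best full-length adapter window (fewest mismatches, ties toward
    the 3'-most position) is removed together with everything 3' of it.
    Returns None when no window has <= max_adapter_mismatches mismatches
    or when the remaining 5' part is shorter than min_remaining.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    params = params or AdapterParams()
    seq = m.sequence
    alen = len(adapter)
    if len(seq) < alen:
        return None

    pos = seq.rfind(adapter)
    if pos < 0:
        a = encode(seq)
        ad = encode(adapter)
        best_mm = params.max_adapter_mismatches + 1
        for s in range(len(seq) - alen, -1, -1):
            mm = int((a[s : s + alen] != ad).sum())
            if mm < best_mm:
                best_mm = mm
                pos = s
                if mm == 0:
                    break
        if best_mm > params.max_adapter_mismatches:
            return None
    if pos < params.min_remaining:
        return None
    return ProcessedRead(m.id, seq[:pos], m.quality[:pos])


class FivePrimeTrimmer:
    """Seeded local aligner that removes 5' overhang beyond reference start.

    Candidate references are found by exact word seeding; the best local
    alignment (match +1, mismatch -2, affine gaps) then tells how many
    read bases project 5' of reference position 0.  Reads with no seeded
    hit or with a sub-threshold local score pass through unchanged.
    """

    def __init__(self, mref: MappingReference, params: LocalTrimParams | None = None):
        self.params = params or LocalTrimParams()
        self.mref = mref
        self._seqs = {e.ref_id: e.mapping_sequence for e in mref}
        self._codes = {rid: encode(s) for rid, s in self._seqs.items()}
        k = self.params.word_size
        index: dict[str, set[str]] = {}
        for rid, s in self._seqs.items():
            for i in range(len(s) - k + 1):
                index.setdefault(s[i : i + k], set()).add(rid)
        self._index = index

    def _candidates(self, seq: str) -> list[str]:
        k = self.params.word_size
        hits: set[str] = set()
        for i in range(len(seq) - k + 1):
            hits.update(self._index.get(seq[i : i + k], ()))
        return sorted(hits)

    def trim(self, p: ProcessedRead) -> ProcessedRead:
        seq = p.sequence
        # Exact-substring fast path: the whole read lies inside a
        # reference, so nothing projects past position 0.
        for s in self._seqs.values():
            if seq in s:
                return p
        best = None  # (score, ref_id, read_start, ref_start)
        read_codes = encode(seq)
        for rid in self._candidates(seq):
            # match +1, mismatch -2; gap open/extend are magnitudes
            score, qs, rs, _qe, _re = local_align(
                read_codes, self._codes[rid], 1, -2, 5, 2
            )
            if best is None or score > best[0]:
                best = (score, rid, qs, rs)
        if best is None or best[0] < self.params.min_local_score:
            return p
        _score, _rid, qs, rs = best
        overhang = qs - rs
        if overhang <= 0:
            return p
        return replace(
            p,
            sequence=seq[overhang:],
            quality=p.quality[overhang:],
            five_prime_trimmed_bases=p.five_prime_trimmed_bases + overhang,
        )


def trim_five_prime_extension(
    p: ProcessedRead, mref: MappingReference, params: LocalTrimParams | None = None
) -> ProcessedRead:
    """Convenience wrapper constructing a fresh :class:`FivePrimeTrimmer`.

    Build the trimmer once via the class when processing many reads.
    """
    return FivePrimeTrimmer(mref, params).trim(p)


def process_pairs(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    adapter: str,
    mref: MappingReference | None = None,
    merge_params: MergeParams | None = None,
    adapter_params: AdapterParams | None = None,
    trim_params: LocalTrimParams | None = None,
) -> tuple[list[ProcessedRead], PreprocessStats]:
    """Run all cleanup stages over read pairs with full accounting."""
    merge_params = merge_params or MergeParams()
    adapter_params = adapter_params or AdapterParams()
    trimmer = FivePrimeTrimmer(mref, trim_params) if mref is not None else None
    stats = PreprocessStats()
    out: list[ProcessedRead] = []
    for r1, r2 in pairs:
        stats.input_pairs += 1
        merged = merge_pair(r1, r2, merge_params)
        if merged is None:
            stats.rejected_no_merge += 1
            continue
        trimmed = trim_cho_adapter(merged, adapter, adapter_params)
        if trimmed is None:
            # distinguish "no adapter window" from "window found but the
            # remainder is too short"
            probe = trim_cho_adapter(
                merged, adapter, replace(adapter_params, min_remaining=0)
            )
            if probe is None:
                stats.rejected_no_adapter += 1
            else:
                stats.rejected_too_short += 1
            continue
        if len(trimmed.sequence) < adapter_params.min_remaining:
            stats.rejected_too_short += 1
            continue
        if trimmer is not None:
            trimmed = trimmer.trim(trimmed)
        stats.processed += 1
        out.append(trimmed)
    stats.check()
    return out, stats
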