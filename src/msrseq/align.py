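"""Sensitive end-to-end read mapping against the tRNA mapping reference.

The scoring contract mirrors a sensitive short-read mapper configuration:
match bonus 0, quality-interpolated mismatch penalty between 2 and 5,
affine gaps (open 5, extend 3), and an acceptance threshold that is
linear in read length (-0.7 - 0.7 * L by default).  The full read must be
consumed (end-to-end in the read); the reference is local.  All
references achieving the exact best score form the tie set, which drives
multimapping-aware attribution downstream.

Scores are computed on an integer scale (x40) so quality interpolation
stays exact and ties are unambiguous; reported scores are on the
conventional scale (<= 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from . import _dp
from .preprocess import ProcessedRead, encode
from .refdb import MappingReference

SCALE = 40


class AlignmentError(ValueError):
    pass


@dataclass
class AlignParams:
    """Native aligner scoring parameters (magnitudes of penalties)."""

    mismatch_penalty_max: float = 5.0
    mismatch_penalty_min: float = 2.0
    gap_open: float = 5.0
    gap_extend: float = 3.0
    match_bonus: float = 0.0
    score_min_intercept: float = -0.7
    score_min_slope: float = -0.7
    seed_length: int = 10  # retained for config parity; native mode is full DP

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty_max, self.mismatch_penalty_min, self.gap_open, self.gap_extend) < 0:
            raise AlignmentError("penalties must be non-negative magnitudes")
        if self.score_min_slope > 0:
            raise AlignmentError("score_min_slope must be <= 0")


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment plus its equal-best tie set."""

    read_id: str
    ref_id: str
    score: float  # <= 0 under end-to-end scoring
    ref_start: int  # 0-based half-open mapping coordinates
    ref_end: int
    cigar: tuple[tuple[str, int], ...]  # ('M'|'I'|'D', length)
    n_mismatches: int
    tie_ids: frozenset[str]
    sequence: str
    quality: str

    @property
    def unique(self) -> bool:
        return len(self.tie_ids) == 1


def score_threshold(read_length: int, p: AlignParams | None = None) -> float:
    """Minimum acceptable score for a read of the given length."""
    p = p or AlignParams()
    if read_length <= 0:
        raise AlignmentError("read_length must be positive")
    return p.score_min_intercept + p.score_min_slope * read_length


def _penalties(sequence: str, quality: str, p: AlignParams) -> np.ndarray:
    """Per-base scaled mismatch penalties, interpolated by base quality.

    penalty(Q) = MN + (MX - MN) * min(Q, 40) / 40; N bases always score
    the minimum penalty.
    """
    q = np.frombuffer(quality.encode(), dtype=np.uint8).astype(np.int64) - 33
    q = np.minimum(q, 40)
    mn = int(round(p.mismatch_penalty_min * SCALE))
    mx = int(round(p.mismatch_penalty_max * SCALE))
    pen = mn + ((mx - mn) * q) // 40
    is_n = encode(sequence) == 4
    pen[is_n] = mn
    return pen.astype(np.int64)


def _scaled_gap(p: AlignParams) -> tuple[int, int]:
    return int(round(p.gap_open * SCALE)), int(round(p.gap_extend * SCALE))


def _cigar_from_ops(ops: np.ndarray) -> tuple[tuple[str, int], ...]:
    letters = {_dp.OP_M: "M", _dp.OP_I: "I", _dp.OP_D: "D"}
    out: list[tuple[str, int]] = []
    for op in ops:
        c = letters[int(op)]
        if out and out[-1][0] == c:
            out[-1] = (c, out[-1][1] + 1)
        else:
            out.append((c, 1))
    return tuple(out)


def _count_mismatches(seq: str, ref: str, ref_start: int, cigar) -> int:
    mm = 0
    ri, qi = ref_start, 0
    for op, length in cigar:
        if op == "M":
            for k in range(length):
                if seq[qi + k] != ref[ri + k]:
                    mm += 1
            ri += length
            qi += length
        elif op == "I":
            qi += length
        else:
            ri += length
    return mm


def align_read(
    r: ProcessedRead, mref: MappingReference, p: AlignParams | None = None
) -> AlignmentRecord | None:
    """Map one processed read; returns None when unmapped.

    The best score over all references is found by exact dynamic
    programming; tie_ids collects every reference achieving it.  The
    lexicographically smallest tied reference becomes the primary record
    (deterministic stand-in for a mapper's arbitrary tie choice).
    """
    p = p or AlignParams()
    if len(mref) == 0:
        raise AlignmentError("mapping reference is empty")
    seq = r.sequence
    if not seq:
        return None
    if set(seq) - set("ACGTN"):
        raise AlignmentError(f"read {r.id}: non-ACGTN characters")

    thr_scaled = (score_threshold(len(seq), p)) * SCALE

    # Exact-substring fast path: a full-length gapless perfect match has
    # score 0, which no alignment can beat; the tie set is exactly the
    # set of references containing the read.
    if "N" not in seq:
        containing = sorted(
            e.ref_id for e in mref if seq in e.mapping_sequence
        )
        if containing:
            if 0 < thr_scaled - 1e-9:
                return None
            primary = containing[0]
            ref_seq = mref.entry(primary).mapping_sequence
            start = ref_seq.find(seq)
            return AlignmentRecord(
                read_id=r.id,
                ref_id=primary,
                score=0.0,
                ref_start=start,
                ref_end=start + len(seq),
                cigar=(("M", len(seq)),),
                n_mismatches=0,
                tie_ids=frozenset(containing),
                sequence=seq,
                quality=r.quality,
            )

    read_codes = encode(seq)
    pen = _penalties(seq, r.quality, p)
    go, ge = _scaled_gap(p)
    scores: dict[str, int] = {}
    for e in mref:
        scores[e.ref_id] = int(
            _dp.glocal_score(read_codes, pen, encode(e.mapping_sequence), go, ge)
        )
    best = max(scores.values())
    if best < thr_scaled - 1e-9:
        return None
    ties = sorted(rid for rid, s in scores.items() if s == best)
    primary = ties[0]
    ref_seq = mref.entry(primary).mapping_sequence
    score, ref_start, ref_end, ops, n_ops = _dp.glocal_align(
        read_codes, pen, encode(ref_seq), go, ge
    )
    cigar = _cigar_from_ops(ops[:n_ops])
    return AlignmentRecord(
        read_id=r.id,
        ref_id=primary,
        score=best / SCALE,
        ref_start=ref_start,
        ref_end=ref_end,
        cigar=cigar,
        n_mismatches=_count_mismatches(seq, ref_seq, ref_start, cigar),
        tie_ids=frozenset(ties),
        sequence=seq,
        quality=r.quality,
    )


_SAM_OPS = {"M": 0, "I": 1, "D": 2}


def _sam_header(mref: MappingReference) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": e.ref_id, "LN": len(e.mapping_sequence)} for e in mref
            ],
        }
    )


def run_alignment(
    reads: Sequence[ProcessedRead],
    mref: MappingReference,
    p: AlignParams | None = None,
    sam_path: str | Path | None = None,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Map reads in input order; optionally emit a SAM file.

    The SAM contains one primary record per mapped read (tie set in the
    ZT tag, tie count in NH) and an unmapped record for each rejected
    read.  Output is deterministic for identical inputs.
    """
    p = p or AlignParams()
    header = _sam_header(mref)
    records: list[AlignmentRecord] = []
    sam_out = (
        pysam.AlignmentFile(str(sam_path), "w", header=header)
        if sam_path is not None
        else None
    )
    ref_index = {rid: i for i, rid in enumerate(mref.ids())}
    rows = []
    try:
        for r in reads:
            rec = align_read(r, mref, p)
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.id
            seg.query_sequence = r.sequence
            seg.query_qualities = pysam.qualitystring_to_array(r.quality)
            if rec is None:
                seg.flag = 4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            else:
                records.append(rec)
                seg.flag = 0
                seg.reference_id = ref_index[rec.ref_id]
                seg.reference_start = rec.ref_start
                seg.mapping_quality = 255
                seg.cigartuples = [(_SAM_OPS[op], n) for op, n in rec.cigar]
                seg.set_tags(
                    [
                        ("NM", rec.n_mismatches, "i"),
                        ("NH", len(rec.tie_ids), "i"),
                        ("ZS", float(rec.score), "f"),
                        ("ZT", ",".join(sorted(rec.tie_ids)), "Z"),
                    ]
                )
                rows.append(
                    {
                        "read_id": rec.read_id,
                        "ref_id": rec.ref_id,
                        "score": rec.score,
                        "ref_start": rec.ref_start,
                        "ref_end": rec.ref_end,
                        "n_mismatches": rec.n_mismatches,
                        "n_ties": len(rec.tie_ids),
                        "tie_ids": ",".join(sorted(rec.tie_ids)),
                        "cigar": "".join(f"{n}{op}" for op, n in rec.cigar),
                    }
                )
            if sam_out is not None:
                sam_out.write(seg)
    finally:
        if sam_out is not None:
            sam_out.close()
    table = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "ref_id",
            "score",
            "ref_start",
            "ref_end",
            "n_mismatches",
            "n_ties",
            "tie_ids",
            "cigar",
        ],
    )
    return records, table
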