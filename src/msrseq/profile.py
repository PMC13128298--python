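"""Per-reference pileup analysis: tail status, misincorporation and
hard-stop profiles, and modification calls.

Tail classification exploits the mapping-reference construction: every
mapping sequence ends in CCA, so maturation status reduces to which of
the three terminal tail positions a read covers with matching bases.  A
hard stop at position p truncates cDNA synthesis so the read's 5'-most
aligned base piles up at p+1; the stop score therefore reads the start
pile at p+1 against the depth there, which captures both the start pile
and the coverage drop in one statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .align import AlignmentRecord
from .refdb import MappingEntry

TAIL_CATEGORIES = ("CCA", "CC", "C", "NONE", "NOT_3PRIME")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class TailCall:
    category: str  # CCA / CC / C / NONE / NOT_3PRIME
    informative: bool  # False when genomic CCA or the read stops short
    extra_3prime_bases: int = 0


@dataclass
class ModificationParams:
    tau_mis: float = 0.10
    tau_stop: float = 0.30
    min_depth: int = 20
    mask_5prime: int = 2
    mask_3prime: int = 5


@dataclass(frozen=True)
class ModificationCall:
    position: int  # gene coordinates
    evidence: frozenset[str]  # subset of {"misincorporation", "hard_stop"}
    misincorporation_rate: float
    stop_score: float
    depth: int
    passed: bool


@dataclass
class PositionProfile:
    """Per-mapping-position pileup for one reference."""

    ref_id: str
    length: int
    depth: np.ndarray
    mismatch: np.ndarray  # shape (4, length): counts by substituted base
    insertion: np.ndarray
    deletion: np.ndarray
    read_start: np.ndarray
    n_reads: int = 0

    @classmethod
    def empty(cls, ref_id: str, length: int) -> "PositionProfile":
        return cls(
            ref_id=ref_id,
            length=length,
            depth=np.zeros(length, dtype=np.int64),
            mismatch=np.zeros((4, length), dtype=np.int64),
            insertion=np.zeros(length, dtype=np.int64),
            deletion=np.zeros(length, dtype=np.int64),
            read_start=np.zeros(length, dtype=np.int64),
        )

    def misincorporation_rate(self) -> np.ndarray:
        errors = self.mismatch.sum(axis=0) + self.insertion + self.deletion
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(self.depth > 0, errors / np.maximum(self.depth, 1), 0.0)
        return rate

    def stop_score(self) -> np.ndarray:
        """stop_score(p) = read_start(p+1) / depth(p+1); 0 at the last position."""
        score = np.zeros(self.length, dtype=float)
        nxt = slice(1, self.length)
        denom = np.maximum(self.depth[nxt], 1)
        score[: self.length - 1] = np.where(
            self.depth[nxt] > 0, self.read_start[nxt] / denom, 0.0
        )
        return score


def _aligned_pairs(a: AlignmentRecord):
    """Yield (ref_pos, read_pos | None, op) walking the cigar."""
    ri, qi = a.ref_start, 0
    for op, length in a.cigar:
        if op == "M":
            for k in range(length):
                yield ri + k, qi + k, "M"
            ri += length
            qi += length
        elif op == "D":
            for k in range(length):
                yield ri + k, None, "D"
            ri += length
        else:  # I — consumes read only; reported at the following ref position
            yield ri, qi, "I"
            qi += length


def classify_tail(a: AlignmentRecord, mentry: MappingEntry) -> TailCall:
    """Classify the 3' maturation state of one aligned read.

    NOT_3PRIME when the alignment ends before the last gene-body base;
    otherwise the number of tail positions covered with matching bases
    maps 3/2/1/0 onto CCA/CC/C/NONE.  Mismatched tail bases count as
    absent.  Calls on genomically CCA-encoded references are flagged
    non-informative.
    """
    if a.ref_id != mentry.ref_id:
        raise ProfileError(
            f"alignment is to {a.ref_id!r}, mapping entry is {mentry.ref_id!r}"
        )
    if a.ref_end > len(mentry.mapping_sequence) or a.ref_start < 0:
        raise ProfileError(f"{a.read_id}: alignment coordinates outside reference")
    gene_end = mentry.gene_end
    if a.ref_end < gene_end:
        return TailCall(category="NOT_3PRIME", informative=False)

    matched = 0
    ref_seq = mentry.mapping_sequence
    tail_positions = range(gene_end, gene_end + 3)
    covered = {}
    for rp, qp, op in _aligned_pairs(a):
        if op == "M" and rp in tail_positions:
            covered[rp] = a.sequence[qp] == ref_seq[rp]
    matched = sum(1 for v in covered.values() if v)
    category = {3: "CCA", 2: "CC", 1: "C", 0: "NONE"}[matched]

    extra = 0
    if a.cigar and a.cigar[-1][0] == "I" and a.ref_end >= len(ref_seq):
        extra = a.cigar[-1][1]
    return TailCall(
        category=category,
        informative=not mentry.genomic_cca,
        extra_3prime_bases=extra,
    )


def accumulate_pileup(
    records: Iterable[AlignmentRecord], mentry: MappingEntry
) -> PositionProfile:
    """Build the per-position pileup for one reference.

    Depth counts reads spanning a position (deleted positions included);
    an insertion is counted at the reference position that follows it;
    the read-start counter marks each read's 5'-most aligned position.
    """
    prof = PositionProfile.empty(mentry.ref_id, len(mentry.mapping_sequence))
    ref_seq = mentry.mapping_sequence
    for a in records:
        if a.ref_id != mentry.ref_id:
            raise ProfileError(
                f"record {a.read_id} maps to {a.ref_id!r}, expected {mentry.ref_id!r}"
            )
        prof.n_reads += 1
        prof.read_start[a.ref_start] += 1
        for rp, qp, op in _aligned_pairs(a):
            if op == "M":
                prof.depth[rp] += 1
                base = a.sequence[qp]
                if base != ref_seq[rp] and base in _BASE_INDEX:
                    prof.mismatch[_BASE_INDEX[base], rp] += 1
            elif op == "D":
                prof.depth[rp] += 1
                prof.deletion[rp] += 1
            else:  # I
                if rp < prof.length:
                    prof.insertion[rp] += 1
    return prof


def call_modifications(
    prof: PositionProfile,
    mentry: MappingEntry,
    params: ModificationParams | None = None,
) -> list[ModificationCall]:
    """Call modified positions from misincorporation and stop signals.

    Terminal windows of the gene body (mask_5prime at the 5' end,
    mask_3prime before the tail) are excluded as adapter/tail-adjacent
    artifacts.  Positions are reported in gene coordinates.
    """
    params = params or ModificationParams()
    rates = prof.misincorporation_rate()
    stops = prof.stop_score()
    calls: list[ModificationCall] = []
    lo = params.mask_5prime
    hi = mentry.gene_end - params.mask_3prime
    for p in range(lo, max(lo, hi)):
        evidence = set()
        if prof.depth[p] >= params.min_depth and rates[p] >= params.tau_mis:
            evidence.add("misincorporation")
        if (
            p + 1 < prof.length
            and prof.depth[p + 1] >= params.min_depth
            and stops[p] >= params.tau_stop
        ):
            evidence.add("hard_stop")
        if evidence:
            calls.append(
                ModificationCall(
                    position=p,
                    evidence=frozenset(evidence),
                    misincorporation_rate=float(rates[p]),
                    stop_score=float(stops[p]),
                    depth=int(prof.depth[p]),
                    passed=True,
                )
            )
    return calls
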