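"""Per-read anticodon extraction and variant assessment.

Used to detect suppressor-tRNA candidates: reads from an isotype of
interest are inspected at the annotated anticodon span, observed 3-mers
are tallied, and a candidate variant is supported only when its read
count and its enrichment over a standard-genetic-code control library
both clear thresholds.  The comparison is deliberately simple (count +
fold enrichment); a one-sided binomial p-value is reported as auxiliary
output only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binomtest

from .align import AlignmentRecord
from .refdb import ReferenceEntry


class AnticodonError(ValueError):
    pass


@dataclass
class AnticodonExtraction:
    seqs: list[str]
    excluded_indel_reads: int
    n_reads_spanning: int


@dataclass
class AnticodonTally:
    group: str  # reference id or isotype group label
    counts: Counter
    n_reads_spanning: int
    excluded_indel_reads: int

    @property
    def n_counted(self) -> int:
        return sum(self.counts.values())


@dataclass
class VariantParams:
    k: int = 20  # minimum supporting read count
    f: float = 5.0  # minimum fold enrichment over control


@dataclass(frozen=True)
class VariantAssessment:
    variant: str
    test_count: int
    test_fraction: float
    control_fraction: float
    fold_enrichment: float
    min_count_ok: bool
    supported: bool
    p_value: float  # auxiliary one-sided binomial p-value


def extract_anticodon_sequences(
    records: Iterable[AlignmentRecord], e: ReferenceEntry
) -> AnticodonExtraction:
    """Read bases across the anticodon span, for reads spanning it cleanly.

    A read contributes a 3-mer when its alignment covers the whole span
    with M operations only; reads with an indel across the span are
    excluded and counted.  Reads not spanning the full anticodon are
    ignored.
    """
    s, span_end = e.anticodon_span
    if span_end > len(e.gene_sequence):
        raise AnticodonError(f"{e.id}: anticodon span outside reference")
    seqs: list[str] = []
    excluded = 0
    spanning = 0
    for a in records:
        if not (a.ref_start <= s and a.ref_end >= span_end):
            continue
        spanning += 1
        # walk the cigar; collect read offsets for each span position
        ri, qi = a.ref_start, 0
        offsets: dict[int, int] = {}
        clean = True
        for op, length in a.cigar:
            if op == "M":
                for k in range(length):
                    if s <= ri + k < span_end:
                        offsets[ri + k] = qi + k
                ri += length
                qi += length
            elif op == "D":
                if any(s <= ri + k < span_end for k in range(length)):
                    clean = False
                ri += length
            else:  # I
                if s < ri < span_end:
                    clean = False
                qi += length
        if not clean or len(offsets) != span_end - s:
            excluded += 1
            continue
        seqs.append("".join(a.sequence[offsets[p]] for p in range(s, span_end)))
    return AnticodonExtraction(
        seqs=seqs, excluded_indel_reads=excluded, n_reads_spanning=spanning
    )


def tally_anticodon_variants(
    seqs: Sequence[str] | AnticodonExtraction, group: str = ""
) -> AnticodonTally:
    """Exact 3-mer counting; invariant to read order."""
    if isinstance(seqs, AnticodonExtraction):
        return AnticodonTally(
            group=group,
            counts=Counter(seqs.seqs),
            n_reads_spanning=seqs.n_reads_spanning,
            excluded_indel_reads=seqs.excluded_indel_reads,
        )
    return AnticodonTally(
        group=group,
        counts=Counter(seqs),
        n_reads_spanning=len(seqs),
        excluded_indel_reads=0,
    )


def compare_to_control(
    test: AnticodonTally,
    control: AnticodonTally,
    variant: str,
    params: VariantParams | None = None,
) -> VariantAssessment:
    """Assess a candidate anticodon variant against a control library.

    Supported iff the test count reaches k AND the test fraction is at
    least f times the control fraction, with the control fraction floored
    at 1 / n_control so an all-zero control cannot divide out.
    """
    params = params or VariantParams()
    n_test = test.n_counted
    if n_test == 0:
        raise AnticodonError("empty test tally")
    n_control = max(control.n_counted, 1)
    test_count = test.counts.get(variant, 0)
    test_frac = test_count / n_test
    control_frac = control.counts.get(variant, 0) / n_control
    floor = max(control_frac, 1.0 / n_control)
    fold = test_frac / floor
    min_count_ok = test_count >= params.k
    supported = min_count_ok and test_frac >= params.f * floor
    p_value = binomtest(test_count, n_test, min(floor, 1.0), alternative="greater").pvalue
    return VariantAssessment(
        variant=variant,
        test_count=test_count,
        test_fraction=test_frac,
        control_fraction=control_frac,
        fold_enrichment=fold,
        min_count_ok=min_count_ok,
        supported=supported,
        p_value=float(p_value),
    )
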