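"""Per-reference counting, multimapping resolution, background thresholds
from no-template controls, and expressed/pseudogene calls.

A read "maps to" every reference in its equal-best tie set, so per-
reference totals are tie-inclusive; unique counts require a singleton tie
set.  Expression calls demand *unique* reads above the background
threshold — reads that map equally well elsewhere can only ever support
an "ambiguous_only" (likely pseudogene) verdict.  Compartment rollups and
tail tallies use primary attribution so they sum over mapped reads
without double counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentRecord
from .profile import TAIL_CATEGORIES, ModificationCall, TailCall
from .refdb import ReferenceSet

EXPRESSION_STATUSES = ("expressed", "not_expressed", "ambiguous_only")


class AttributionError(ValueError):
    pass


@dataclass
class CountRecord:
    ref_id: str
    compartment: str
    total_mapped: int = 0  # reads whose tie set includes this reference
    unique_mapped: int = 0  # tie set == {this reference}
    ambiguous_mapped: int = 0
    primary_mapped: int = 0  # reads attributed here as primary
    cca_count: int = 0
    cc_count: int = 0
    c_count: int = 0
    none_count: int = 0
    not_3prime_count: int = 0

    def tail_total(self) -> int:
        return (
            self.cca_count
            + self.cc_count
            + self.c_count
            + self.none_count
            + self.not_3prime_count
        )


@dataclass
class CountTable:
    records: list[CountRecord]
    compartment_fractions: dict[str, float]
    mapped_reads: int
    # sequencing depth (input read pairs) of the library; equals
    # mapped_reads when the caller does not supply it
    total_reads: int = 0

    def record(self, ref_id: str) -> CountRecord:
        for r in self.records:
            if r.ref_id == ref_id:
                return r
        raise KeyError(ref_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_id": r.ref_id,
                    "compartment": r.compartment,
                    "total_mapped": r.total_mapped,
                    "unique_mapped": r.unique_mapped,
                    "ambiguous_mapped": r.ambiguous_mapped,
                    "primary_mapped": r.primary_mapped,
                    "CCA": r.cca_count,
                    "CC": r.cc_count,
                    "C": r.c_count,
                    "NONE": r.none_count,
                    "NOT_3PRIME": r.not_3prime_count,
                }
                for r in self.records
            ]
        )


@dataclass
class BackgroundParams:
    k_min: int = 10
    multiplier: float = 2.0


@dataclass(frozen=True)
class ExpressionCall:
    ref_id: str
    status: str  # expressed / not_expressed / ambiguous_only
    background_threshold: float
    rationale: str


def tally_counts(
    records: Sequence[AlignmentRecord],
    tails: Mapping[str, TailCall],
    refset: ReferenceSet,
    input_reads: int | None = None,
) -> CountTable:
    """Aggregate alignment records into per-reference count records.

    ``tails`` maps read id to that read's tail call (computed against its
    primary reference); a mapped read without a tail call is a hard
    error, because the tail accounting identity could otherwise silently
    break.
    """
    by_ref = {
        e.id: CountRecord(ref_id=e.id, compartment=e.compartment) for e in refset
    }
    compartment_counts: dict[str, int] = {}
    for a in records:
        tail = tails.get(a.read_id)
        if tail is None:
            raise AttributionError(f"no tail call for mapped read {a.read_id!r}")
        unique = len(a.tie_ids) == 1
        for rid in a.tie_ids:
            rec = by_ref[rid]
            rec.total_mapped += 1
            if unique:
                rec.unique_mapped += 1
            else:
                rec.ambiguous_mapped += 1
        primary = by_ref[a.ref_id]
        primary.primary_mapped += 1
        if tail.category == "CCA":
            primary.cca_count += 1
        elif tail.category == "CC":
            primary.cc_count += 1
        elif tail.category == "C":
            primary.c_count += 1
        elif tail.category == "NONE":
            primary.none_count += 1
        else:
            primary.not_3prime_count += 1
        comp = primary.compartment
        compartment_counts[comp] = compartment_counts.get(comp, 0) + 1

    mapped = len(records)
    fractions = {
        comp: n / mapped for comp, n in sorted(compartment_counts.items())
    } if mapped else {}
    return CountTable(
        records=[by_ref[e.id] for e in refset],
        compartment_fractions=fractions,
        mapped_reads=mapped,
        total_reads=input_reads if input_reads is not None else mapped,
    )


def background_threshold(
    ntc_counts: CountTable,
    library_mappable: int,
    params: BackgroundParams | None = None,
) -> dict[str, float]:
    """Per-reference background threshold from no-template controls.

    threshold(ref) = max(k_min, multiplier * ntc_rate(ref) * library_mappable),
    where ntc_rate is the reference's NTC read count over the NTC
    library's sequencing depth (input reads).  Scaling that per-read
    contamination rate by the sample's mappable depth predicts the
    background count the sample would accrue from index hopping and
    cross-contamination alone.  The NTC libraries must have been
    processed through the identical pipeline.
    """
    params = params or BackgroundParams()
    if library_mappable <= 0:
        raise AttributionError("library has zero mappable reads")
    ntc_depth = ntc_counts.total_reads or ntc_counts.mapped_reads
    thresholds = {}
    for rec in ntc_counts.records:
        rate = rec.total_mapped / ntc_depth if ntc_depth > 0 else 0.0
        thresholds[rec.ref_id] = max(
            float(params.k_min), params.multiplier * rate * library_mappable
        )
    return thresholds


def call_expression(
    c: CountRecord,
    threshold: float,
    mods: Sequence[ModificationCall] = (),
) -> ExpressionCall:
    """Expressed / not expressed / ambiguous-only verdict for one reference.

    Expression requires uniquely attributed reads above background; a
    reference whose total exceeds background purely through multimapping
    reads carries the pseudogene signature (ambiguous_only).  CCA-tail
    and modification support are recorded as corroborating evidence in
    the rationale.
    """
    if c.unique_mapped > threshold:
        status = "expressed"
    elif c.total_mapped > threshold:
        status = "ambiguous_only"
    else:
        status = "not_expressed"
    rationale = (
        f"unique={c.unique_mapped}, total={c.total_mapped} vs "
        f"background threshold {threshold:g}; CCA-tailed reads={c.cca_count}; "
        f"modification sites called={len(mods)}"
    )
    if status == "ambiguous_only":
        rationale += "; reads map equally well to other references (likely not expressed)"
    return ExpressionCall(
        ref_id=c.ref_id,
        status=status,
        background_threshold=float(threshold),
        rationale=rationale,
    )


def write_expression_report(calls: Sequence[ExpressionCall], path: str | Path) -> None:
    payload = [
        {
            "ref_id": c.ref_id,
            "status": c.status,
            "background_threshold": c.background_threshold,
            "rationale": c.rationale,
        }
        for c in calls
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
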