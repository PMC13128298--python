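"""tRNA reference set: loading, validation, and mapping-reference construction.

A reference entry stores the *gene body* of a tRNA (without the
post-transcriptionally added CCA) together with the metadata needed
downstream: genomic compartment, isotype, anticodon and its coordinates,
and whether the CCA tail is genomically encoded.  The mapping reference
appends CCA to every entry that lacks a genomic tail so that 3'-maturation
status is decidable directly from alignment end coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

COMPARTMENTS = frozenset({"nuclear", "plastid", "mitochondrial", "spike_in"})
ORIGINS = frozenset({"native", "foreign", "MTPT", "unknown"})
_VALID_BASES = frozenset("ACGT")

MIN_GENE_LENGTH = 50
MAX_GENE_LENGTH = 120

METADATA_COLUMNS = [
    "id",
    "compartment",
    "species",
    "isotype",
    "anticodon",
    "anticodon_start",
    "anticodon_end",
    "genomic_cca",
    "origin",
    "spike_in",
]


class ReferenceValidationError(ValueError):
    """Raised when a reference entry or set violates an invariant."""


@dataclass(frozen=True)
class ReferenceEntry:
    """One tRNA reference gene with its annotation.

    ``anticodon_span`` is a 0-based half-open interval of length 3 in gene
    coordinates; the gene-strand bases at that span must equal
    ``anticodon``.  ``genomic_cca`` marks genes whose 3' CCA is encoded in
    the genome rather than added post-transcriptionally.
    """

    id: str
    gene_sequence: str
    compartment: str
    species: str
    isotype: str
    anticodon: str
    anticodon_span: tuple[int, int]
    genomic_cca: bool
    origin: str = "native"
    spike_in: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ReferenceValidationError("reference id must be non-empty")
        seq = self.gene_sequence
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ReferenceValidationError(
                f"{self.id}: non-ACGT characters in sequence: {sorted(bad)}"
            )
        if not (MIN_GENE_LENGTH <= len(seq) <= MAX_GENE_LENGTH):
            raise ReferenceValidationError(
                f"{self.id}: gene length {len(seq)} outside "
                f"[{MIN_GENE_LENGTH}, {MAX_GENE_LENGTH}]"
            )
        if self.compartment not in COMPARTMENTS:
            raise ReferenceValidationError(
                f"{self.id}: unknown compartment {self.compartment!r}"
            )
        if self.origin not in ORIGINS:
            raise ReferenceValidationError(f"{self.id}: unknown origin {self.origin!r}")
        s, e = self.anticodon_span
        if not (0 <= s < e <= len(seq)) or e - s != 3:
            raise ReferenceValidationError(
                f"{self.id}: anticodon_span {self.anticodon_span} invalid for "
                f"length-{len(seq)} gene"
            )
        if len(self.anticodon) != 3 or set(self.anticodon) - _VALID_BASES:
            raise ReferenceValidationError(
                f"{self.id}: anticodon {self.anticodon!r} is not a 3-nt DNA string"
            )
        if seq[s:e] != self.anticodon:
            raise ReferenceValidationError(
                f"{self.id}: sequence at anticodon_span is {seq[s:e]!r}, "
                f"metadata says {self.anticodon!r}"
            )
        if self.genomic_cca and not seq.endswith("CCA"):
            raise ReferenceValidationError(
                f"{self.id}: genomic_cca set but gene does not end in CCA"
            )


@dataclass
class ReferenceSet:
    """Ordered collection of reference entries with unique ids."""

    entries: list[ReferenceEntry]
    provenance: str = ""
    _by_id: dict[str, ReferenceEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, ReferenceEntry] = {}
        for e in self.entries:
            if e.id in by_id:
                raise ReferenceValidationError(f"duplicate reference id {e.id!r}")
            by_id[e.id] = e
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def entry(self, ref_id: str) -> ReferenceEntry:
        return self._by_id[ref_id]

    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id


@dataclass(frozen=True)
class MappingEntry:
    """One reference as used for read mapping: gene body plus CCA tail.

    ``gene_end`` is the exclusive end of the gene body in mapping
    coordinates (equivalently, the index of the first tail position), so
    that ``gene_end + 3 == len(mapping_sequence)`` always holds and the
    tail span is the terminal CCA trinucleotide.
    """

    ref_id: str
    mapping_sequence: str
    gene_end: int
    tail_span: tuple[int, int]
    genomic_cca: bool


@dataclass
class MappingReference:
    """Mapping sequences for a reference set, keyed by reference id."""

    entries: dict[str, MappingEntry]
    refset: ReferenceSet

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def entry(self, ref_id: str) -> MappingEntry:
        return self.entries[ref_id]

    def ids(self) -> list[str]:
        return list(self.entries)


def build_mapping_reference(refset: ReferenceSet) -> MappingReference:
    """Append CCA to every entry without a genomically encoded tail.

    Idempotent on genomic_cca entries (their sequence is left unchanged;
    the tail span is their terminal, genomically encoded CCA, which makes
    them non-informative for maturation calls downstream).
    """
    entries: dict[str, MappingEntry] = {}
    for e in refset:
        seq = e.gene_sequence if e.genomic_cca else e.gene_sequence + "CCA"
        gene_end = len(seq) - 3
        entries[e.id] = MappingEntry(
            ref_id=e.id,
            mapping_sequence=seq,
            gene_end=gene_end,
            tail_span=(gene_end, gene_end + 3),
            genomic_cca=e.genomic_cca,
        )
    return MappingReference(entries=entries, refset=refset)


def _parse_bool(value, ref_id: str, column: str) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ReferenceValidationError(f"{ref_id}: cannot parse {column}={value!r} as boolean")


def load_reference_set(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceSet:
    """Load references from FASTA plus a TSV metadata table.

    FASTA ids and metadata rows must match one-to-one; entries are returned
    in FASTA file order.  Every entry invariant is validated on load.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ReferenceValidationError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ReferenceValidationError(f"metadata missing columns: {sorted(missing_cols)}")
    meta_by_id = {}
    for _, row in meta.iterrows():
        rid = row["id"]
        if rid in meta_by_id:
            raise ReferenceValidationError(f"duplicate metadata row for id {rid!r}")
        meta_by_id[rid] = row

    fasta_only = set(seqs) - set(meta_by_id)
    meta_only = set(meta_by_id) - set(seqs)
    if fasta_only:
        raise ReferenceValidationError(
            f"missing metadata row for FASTA ids: {sorted(fasta_only)}"
        )
    if meta_only:
        raise ReferenceValidationError(
            f"metadata rows without FASTA sequence: {sorted(meta_only)}"
        )

    entries = []
    for rid, seq in seqs.items():
        row = meta_by_id[rid]
        entries.append(
            ReferenceEntry(
                id=rid,
                gene_sequence=seq,
                compartment=row["compartment"],
                species=row["species"],
                isotype=row["isotype"],
                anticodon=row["anticodon"].upper(),
                anticodon_span=(int(row["anticodon_start"]), int(row["anticodon_end"])),
                genomic_cca=_parse_bool(row["genomic_cca"], rid, "genomic_cca"),
                origin=row["origin"] or "unknown",
                spike_in=_parse_bool(row["spike_in"] or "false", rid, "spike_in"),
            )
        )
    return ReferenceSet(entries=entries, provenance=f"{fasta_path} + {metadata_path}")


def write_reference_report(refset: ReferenceSet, path: str | Path) -> None:
    """One TSV row per entry with all metadata plus the gene sequence.

    The report round-trips through :func:`load_reference_report`.
    """
    rows = []
    for e in refset:
        rows.append(
            {
                "id": e.id,
                "compartment": e.compartment,
                "species": e.species,
                "isotype": e.isotype,
                "anticodon": e.anticodon,
                "anticodon_start": e.anticodon_span[0],
                "anticodon_end": e.anticodon_span[1],
                "genomic_cca": e.genomic_cca,
                "origin": e.origin,
                "spike_in": e.spike_in,
                "gene_sequence": e.gene_sequence,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS + ["gene_sequence"]).to_csv(
        path, sep="\t", index=False
    )


def load_reference_report(path: str | Path) -> ReferenceSet:
    """Inverse of :func:`write_reference_report`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ReferenceEntry(
                id=row["id"],
                gene_sequence=row["gene_sequence"].upper(),
                compartment=row["compartment"],
                species=row["species"],
                isotype=row["isotype"],
                anticodon=row["anticodon"].upper(),
                anticodon_span=(int(row["anticodon_start"]), int(row["anticodon_end"])),
                genomic_cca=_parse_bool(row["genomic_cca"], row["id"], "genomic_cca"),
                origin=row["origin"] or "unknown",
                spike_in=_parse_bool(row["spike_in"] or "false", row["id"], "spike_in"),
            )
        )
    return ReferenceSet(entries=entries, provenance=str(path))


def write_reference_fasta(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in refset:
            fh.write(f">{e.id}\n{e.gene_sequence}\n")
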