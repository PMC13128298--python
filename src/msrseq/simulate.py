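"""Synthetic MSR-seq library generator with per-read ground truth.

The generative model per read pair:

1. draw a source reference proportional to its abundance weight;
2. draw a 3' tail state: the mature molecule is the gene body plus CCA
   (or the gene body alone when the CCA is genomically encoded), and the
   tail state removes 0 (CCA), 1 (CC), 2 (C), or 3+k (TRUNC_k, k >= 2
   missing gene-body bases) terminal bases;
3. emulate reverse transcription 3'->5': at each modified position the RT
   either stops (the read's 5' terminus becomes the next position toward
   3') or, independently, misincorporates a wrong base — stop and misread
   are mutually exclusive per read per site;
4. optionally prepend a random 5' extension;
5. append the capture-hairpin-oligo adapter at the molecule 3' end;
6. emit R1/R2 as the two ends of the construct with iid sequencing errors.

Everything is deterministic given the master seed; per-library random
streams are derived by stable hashing of the library name.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import FastqRead, revcomp
from .refdb import ReferenceEntry, ReferenceSet

# Surrogate for the MSR-seq capture hairpin oligo adapter (the real CHO
# sequence lives in the wet-lab protocol and is a required config input
# when processing real libraries).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = "ACGT"
# TRUNC with no explicit k removes between 2 and 8 gene-body bases,
# drawn uniformly — emulating heterogeneous 3' degradation / tRFs.
_TRUNC_K_RANGE = (2, 8)


class SimulationError(ValueError):
    """Raised on inconsistent simulation profiles or configs."""


@dataclass(frozen=True)
class Modification:
    """A modified base position and its RT-signature probabilities.

    ``position`` is in gene coordinates.  ``misincorp_base_weights`` maps
    substituted bases to weights; by default the three non-reference bases
    are equally likely.
    """

    position: int
    stop_prob: float = 0.0
    misincorp_prob: float = 0.0
    misincorp_base_weights: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.stop_prob <= 1.0 and 0.0 <= self.misincorp_prob <= 1.0):
            raise SimulationError(f"modification at {self.position}: probabilities outside [0,1]")


@dataclass
class ReferenceProfile:
    """Per-reference generative parameters."""

    abundance_weight: float = 1.0
    tail_distribution: dict[str, float] = field(
        default_factory=lambda: {"CCA": 0.65, "CC": 0.25, "C": 0.05, "TRUNC": 0.05}
    )
    modifications: tuple[Modification, ...] = ()
    five_prime_extension_prob: float = 0.1
    extension_lengths: tuple[int, int] = (1, 12)

    def validate(self, entry: ReferenceEntry) -> None:
        if self.abundance_weight < 0:
            raise SimulationError(f"{entry.id}: negative abundance weight")
        total = sum(self.tail_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"{entry.id}: tail_distribution sums to {total}, expected 1"
            )
        for state, p in self.tail_distribution.items():
            if p < 0:
                raise SimulationError(f"{entry.id}: negative tail probability for {state}")
            if state not in ("CCA", "CC", "C", "TRUNC") and not (
                state.startswith("TRUNC_") and state[6:].isdigit() and int(state[6:]) >= 2
            ):
                raise SimulationError(f"{entry.id}: unknown tail state {state!r}")
        for mod in self.modifications:
            if not (0 <= mod.position < len(entry.gene_sequence)):
                raise SimulationError(
                    f"{entry.id}: modification position {mod.position} outside gene body"
                )


@dataclass
class SimProfile:
    """Generative profile for a whole library: one entry per reference id."""

    per_ref: dict[str, ReferenceProfile]

    def validate(self, refset: ReferenceSet) -> None:
        for ref_id, prof in self.per_ref.items():
            if ref_id not in refset:
                raise SimulationError(f"profile references unknown id {ref_id!r}")
            prof.validate(refset.entry(ref_id))

    @classmethod
    def uniform(cls, refset: ReferenceSet, **kwargs) -> "SimProfile":
        return cls({e.id: ReferenceProfile(**kwargs) for e in refset})


@dataclass
class LibraryConfig:
    n_read_pairs: int
    read_length: int = 150
    adapter_seq: str = DEFAULT_ADAPTER
    error_rate: float = 0.0
    quality_model: str = "constant"  # "constant" (Q30) or "two_state"
    seed: int = 0
    library_name: str = "lib"

    def validate(self) -> None:
        if self.n_read_pairs < 0:
            raise SimulationError("n_read_pairs must be >= 0")
        if not self.adapter_seq:
            raise SimulationError("adapter_seq must be non-empty")
        if not (0.0 <= self.error_rate < 1.0):
            raise SimulationError("error_rate must be in [0, 1)")
        if self.quality_model not in ("constant", "two_state"):
            raise SimulationError(f"unknown quality model {self.quality_model!r}")


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    ref_id: str
    tail_state: str  # CCA / CC / C / TRUNC
    trunc_k: int  # missing gene-body bases (0 unless TRUNC)
    stop_position: int | None  # gene coordinate of the stop-causing site
    misincorporations: tuple[tuple[int, str], ...]  # (gene position, substituted base)
    extension_length: int


@dataclass
class TruthTable:
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    tail_counts: dict[str, Counter] = field(default_factory=dict)

    def add(self, truth: ReadTruth) -> None:
        if truth.read_id in self.reads:
            raise SimulationError(f"duplicate read id {truth.read_id!r}")
        self.reads[truth.read_id] = truth
        self.tail_counts.setdefault(truth.ref_id, Counter())[truth.tail_state] += 1

    def total_counts(self) -> Counter:
        return Counter(t.ref_id for t in self.reads.values())


@dataclass
class SimulatedLibrary:
    r1: list[FastqRead]
    r2: list[FastqRead]
    truth: TruthTable


def _library_rng(seed: int, library_name: str) -> np.random.Generator:
    """Per-library stream derived from the master seed by stable name hashing."""
    return np.random.default_rng((seed, zlib.crc32(library_name.encode())))


def _draw_tail(rng: np.random.Generator, dist: Mapping[str, float]) -> tuple[str, int]:
    """Return (tail label, missing gene-body bases)."""
    states = sorted(dist)
    probs = np.array([dist[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    state = states[rng.choice(len(states), p=probs)]
    if state == "TRUNC":
        lo, hi = _TRUNC_K_RANGE
        return "TRUNC", int(rng.integers(lo, hi + 1))
    if state.startswith("TRUNC_"):
        return "TRUNC", int(state[6:])
    return state, 0


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _substitute(rng: np.random.Generator, base: str, weights=None) -> str:
    if weights is None:
        choices = [b for b in _BASES if b != base]
        return choices[rng.integers(0, len(choices))]
    items = [(b, w) for b, w in weights if w > 0]
    probs = np.array([w for _, w in items], dtype=float)
    probs /= probs.sum()
    return items[rng.choice(len(items), p=probs)][0]


def _apply_sequencing_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _substitute(rng, arr[i])
    return "".join(arr)


def _quality_string(rng: np.random.Generator, n: int, model: str) -> str:
    if model == "constant":
        return "?" * n  # Q30
    # Two-state Markov model: long high-quality (Q37) stretches with
    # occasional low-quality (Q12) runs.
    quals = []
    low = False
    for _ in range(n):
        if low:
            low = rng.random() >= 0.3
        else:
            low = rng.random() < 0.02
        quals.append("-" if low else "F")  # Q12 / Q37
    return "".join(quals)


def _simulate_molecule_read(
    rng: np.random.Generator,
    entry: ReferenceEntry,
    prof: ReferenceProfile,
    cfg: LibraryConfig,
    read_id: str,
) -> tuple[FastqRead, FastqRead, ReadTruth]:
    """Draw one molecule from a reference and emit its read pair + truth."""
    gene = entry.gene_sequence
    tail_state, trunc_k = _draw_tail(rng, prof.tail_distribution)
    mature = gene if entry.genomic_cca else gene + "CCA"
    drop = {"CCA": 0, "CC": 1, "C": 2, "TRUNC": 3 + trunc_k}[tail_state]
    molecule = mature[: len(mature) - drop] if drop else mature
    gene_bases_kept = min(len(molecule), len(gene))

    # Reverse transcription runs 3'->5'; visit modified sites from the 3' end.
    stop_position: int | None = None
    misincorps: list[tuple[int, str]] = []
    frag = list(molecule)
    frag_start = 0
    for mod in sorted(prof.modifications, key=lambda m: -m.position):
        if mod.position >= gene_bases_kept:
            continue  # truncated away before RT
        if rng.random() < mod.stop_prob:
            stop_position = mod.position
            frag_start = mod.position + 1
            break
        if rng.random() < mod.misincorp_prob:
            new = _substitute(rng, frag[mod.position], mod.misincorp_base_weights)
            frag[mod.position] = new
            misincorps.append((mod.position, new))
    fragment = "".join(frag[frag_start:])
    misincorps = [(p, b) for p, b in misincorps if p >= frag_start]

    # A 5' extension is part of the RNA template, so an RT that stopped
    # mid-molecule never reads through to it.
    ext_len = 0
    extension = ""
    if stop_position is None and rng.random() < prof.five_prime_extension_prob:
        lo, hi = prof.extension_lengths
        ext_len = int(rng.integers(lo, hi + 1))
        extension = _random_bases(rng, ext_len)

    construct = extension + fragment + cfg.adapter_seq
    r1_seq = construct[: cfg.read_length]
    r2_seq = revcomp(construct)[: cfg.read_length]
    r1_seq = _apply_sequencing_errors(rng, r1_seq, cfg.error_rate)
    r2_seq = _apply_sequencing_errors(rng, r2_seq, cfg.error_rate)
    r1 = FastqRead(read_id, r1_seq, _quality_string(rng, len(r1_seq), cfg.quality_model))
    r2 = FastqRead(read_id, r2_seq, _quality_string(rng, len(r2_seq), cfg.quality_model))
    truth = ReadTruth(
        read_id=read_id,
        ref_id=entry.id,
        tail_state=tail_state,
        trunc_k=trunc_k,
        stop_position=stop_position,
        misincorporations=tuple(sorted(misincorps)),
        extension_length=ext_len,
    )
    return r1, r2, truth


def simulate_library(
    refset: ReferenceSet, profile: SimProfile, cfg: LibraryConfig
) -> SimulatedLibrary:
    """Simulate one MSR-seq library; deterministic given cfg.seed and name."""
    cfg.validate()
    profile.validate(refset)
    rng = _library_rng(cfg.seed, cfg.library_name)

    ids = sorted(profile.per_ref)
    weights = np.array([profile.per_ref[i].abundance_weight for i in ids], dtype=float)
    if weights.sum() <= 0:
        raise SimulationError("all abundance weights are zero")
    probs = weights / weights.sum()

    lib = SimulatedLibrary(r1=[], r2=[], truth=TruthTable())
    for i in range(cfg.n_read_pairs):
        ref_id = ids[rng.choice(len(ids), p=probs)]
        read_id = f"{cfg.library_name}.{i}"
        r1, r2, truth = _simulate_molecule_read(
            rng, refset.entry(ref_id), profile.per_ref[ref_id], cfg, read_id
        )
        lib.r1.append(r1)
        lib.r2.append(r2)
        lib.truth.add(truth)
    return lib


def simulate_ntc(
    refset: ReferenceSet,
    cfg: LibraryConfig,
    contamination_rate: float,
    donor_profile: SimProfile,
) -> SimulatedLibrary:
    """No-template control: cross-contamination reads plus adapter-dimer junk.

    Each pair is, with probability ``contamination_rate``, a genuine
    tRNA-derived read drawn from ``donor_profile`` (modelling index hopping
    and cross-contamination); otherwise an adapter-dimer construct that is
    rejected during preprocessing.
    """
    if not (0.0 <= contamination_rate < 1.0):
        raise SimulationError("contamination_rate must be in [0, 1)")
    cfg.validate()
    donor_profile.validate(refset)
    rng = _library_rng(cfg.seed, cfg.library_name + ".ntc")

    ids = sorted(donor_profile.per_ref)
    weights = np.array(
        [donor_profile.per_ref[i].abundance_weight for i in ids], dtype=float
    )
    donor_ok = weights.sum() > 0
    probs = weights / weights.sum() if donor_ok else None

    lib = SimulatedLibrary(r1=[], r2=[], truth=TruthTable())
    for i in range(cfg.n_read_pairs):
        read_id = f"{cfg.library_name}.ntc.{i}"
        if donor_ok and rng.random() < contamination_rate:
            ref_id = ids[rng.choice(len(ids), p=probs)]
            r1, r2, truth = _simulate_molecule_read(
                rng, refset.entry(ref_id), donor_profile.per_ref[ref_id], cfg, read_id
            )
            lib.truth.add(truth)
        else:
            construct = cfg.adapter_seq + cfg.adapter_seq
            r1_seq = _apply_sequencing_errors(
                rng, construct[: cfg.read_length], cfg.error_rate
            )
            r2_seq = _apply_sequencing_errors(
                rng, revcomp(construct)[: cfg.read_length], cfg.error_rate
            )
            r1 = FastqRead(read_id, r1_seq, _quality_string(rng, len(r1_seq), cfg.quality_model))
            r2 = FastqRead(read_id, r2_seq, _quality_string(rng, len(r2_seq), cfg.quality_model))
        lib.r1.append(r1)
        lib.r2.append(r2)
    return lib


def write_truth(truth: TruthTable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write read-level and reference-level truth tables as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    read_rows = [
        {
            "read_id": t.read_id,
            "ref_id": t.ref_id,
            "tail_state": t.tail_state,
            "trunc_k": t.trunc_k,
            "stop_position": "" if t.stop_position is None else t.stop_position,
            "misincorporations": ";".join(f"{p}:{b}" for p, b in t.misincorporations),
            "extension_length": t.extension_length,
        }
        for t in truth.reads.values()
    ]
    read_path = out_dir / "truth_reads.tsv"
    pd.DataFrame(
        read_rows,
        columns=[
            "read_id",
            "ref_id",
            "tail_state",
            "trunc_k",
            "stop_position",
            "misincorporations",
            "extension_length",
        ],
    ).to_csv(read_path, sep="\t", index=False)

    ref_rows = []
    for ref_id in sorted(truth.tail_counts):
        counts = truth.tail_counts[ref_id]
        ref_rows.append(
            {
                "ref_id": ref_id,
                "total": sum(counts.values()),
                "CCA": counts.get("CCA", 0),
                "CC": counts.get("CC", 0),
                "C": counts.get("C", 0),
                "TRUNC": counts.get("TRUNC", 0),
            }
        )
    ref_path = out_dir / "truth_refs.tsv"
    pd.DataFrame(ref_rows, columns=["ref_id", "total", "CCA", "CC", "C", "TRUNC"]).to_csv(
        ref_path, sep="\t", index=False
    )
    return read_path, ref_path


def synthetic_reference_set(
    n_refs: int,
    seed: int = 0,
    length_range: tuple[int, int] = (72, 90),
    n_duplicate_pairs: int = 0,
    genomic_cca_every: int = 0,
) -> ReferenceSet:
    """Random but structurally valid tRNA-like reference set for studies.

    Sequences are random DNA with an annotated anticodon at position ~32.
    ``n_duplicate_pairs`` appends byte-identical copies of the first
    references under distinct ids (to exercise multimapping ties);
    ``genomic_cca_every`` (if > 0) marks every k-th entry as carrying a
    genomically encoded CCA.
    """
    rng = np.random.default_rng(seed)
    compartments = ["nuclear", "plastid", "mitochondrial"]
    isotypes = ["Ala", "Glu", "Gly", "iMet", "Trp", "Ser", "Lys", "Ile"]
    entries = []
    for i in range(n_refs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        genomic_cca = genomic_cca_every > 0 and (i + 1) % genomic_cca_every == 0
        seq = _random_bases(rng, length - 3) + "CCA" if genomic_cca else _random_bases(rng, length)
        span = (32, 35)
        entries.append(
            ReferenceEntry(
                id=f"ref{i:03d}",
                gene_sequence=seq,
                compartment=compartments[i % len(compartments)],
                species="Synthetica exempli",
                isotype=isotypes[i % len(isotypes)],
                anticodon=seq[span[0] : span[1]],
                anticodon_span=span,
                genomic_cca=genomic_cca,
            )
        )
    for j in range(n_duplicate_pairs):
        src = entries[j]
        entries.append(
            ReferenceEntry(
                id=f"{src.id}_dup",
                gene_sequence=src.gene_sequence,
                compartment=src.compartment,
                species=src.species,
                isotype=src.isotype,
                anticodon=src.anticodon,
                anticodon_span=src.anticodon_span,
                genomic_cca=src.genomic_cca,
            )
        )
    return ReferenceSet(entries=entries, provenance=f"synthetic(seed={seed})")
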