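"""Pipeline orchestration: configuration, staging, and report generation.

The pipeline runs, per library: pair merging -> adapter removal -> 5'
extension trimming -> mapping -> tail classification -> pileup and
modification calling, then pools the no-template-control libraries into
per-reference background thresholds and emits expression calls and
anticodon tallies.  Outputs are plain SAM/TSV/JSON; re-running with an
identical config reproduces them byte-for-byte (the run log carries the
only timestamp).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .align import AlignParams, AlignmentRecord, run_alignment
from .anticodon import (
    VariantParams,
    compare_to_control,
    extract_anticodon_sequences,
    tally_anticodon_variants,
)
from .attribute import (
    BackgroundParams,
    CountTable,
    background_threshold,
    call_expression,
    tally_counts,
    write_expression_report,
)
from .io import read_fastq
from .preprocess import (
    AdapterParams,
    LocalTrimParams,
    MergeParams,
    PreprocessStats,
    process_pairs,
)
from .profile import (
    ModificationParams,
    accumulate_pileup,
    call_modifications,
    classify_tail,
)
from .refdb import MappingReference, ReferenceSet, build_mapping_reference, load_reference_set


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class LibrarySpec:
    name: str
    r1: str
    r2: str


@dataclass
class AnticodonConfig:
    refs: list[str] = field(default_factory=list)
    variants: list[str] = field(default_factory=list)
    control_library: str | None = None
    params: VariantParams = field(default_factory=VariantParams)


@dataclass
class PipelineConfig:
    references_fasta: str
    references_metadata: str
    output_dir: str
    adapter: str
    libraries: list[LibrarySpec] = field(default_factory=list)
    ntc_libraries: list[LibrarySpec] = field(default_factory=list)
    seed: int = 0
    merge: MergeParams = field(default_factory=MergeParams)
    adapter_params: AdapterParams = field(default_factory=AdapterParams)
    trim: LocalTrimParams = field(default_factory=LocalTrimParams)
    align: AlignParams = field(default_factory=AlignParams)
    modifications: ModificationParams = field(default_factory=ModificationParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    anticodon: AnticodonConfig = field(default_factory=AnticodonConfig)

    def validate(self) -> None:
        for path in (self.references_fasta, self.references_metadata):
            if not Path(path).exists():
                raise ConfigError(f"missing input path: {path}")
        for spec in list(self.libraries) + list(self.ntc_libraries):
            for path in (spec.r1, spec.r2):
                if not Path(path).exists():
                    raise ConfigError(f"library {spec.name}: missing FASTQ {path}")
        if not self.adapter:
            raise ConfigError("adapter must be non-empty")


def _build(cls, data: Mapping[str, Any], context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in ("libraries", "ntc_libraries"):
            kwargs[key] = [_build(LibrarySpec, v, f"{key} entry") for v in value]
        elif key == "merge":
            kwargs[key] = _build(MergeParams, value, "merge")
        elif key == "adapter_params":
            kwargs[key] = _build(AdapterParams, value, "adapter_params")
        elif key == "trim":
            kwargs[key] = _build(LocalTrimParams, value, "trim")
        elif key == "align":
            kwargs[key] = _build(AlignParams, value, "align")
        elif key == "modifications":
            kwargs[key] = _build(ModificationParams, value, "modifications")
        elif key == "background":
            kwargs[key] = _build(BackgroundParams, value, "background")
        elif key == "anticodon":
            value = dict(value)
            if "params" in value:
                value["params"] = _build(VariantParams, value["params"], "anticodon.params")
            kwargs[key] = _build(AnticodonConfig, value, "anticodon")
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


@dataclass
class LibraryResult:
    name: str
    stats: PreprocessStats
    records: list[AlignmentRecord]
    tails: dict[str, Any]
    counts: CountTable
    modifications: dict[str, list]


def _process_library(
    spec: LibrarySpec,
    cfg: PipelineConfig,
    mref: MappingReference,
    refset: ReferenceSet,
    out_dir: Path,
) -> LibraryResult:
    try:
        r1 = read_fastq(spec.r1)
        r2 = read_fastq(spec.r2)
        if len(r1) != len(r2):
            raise StageError(f"[read] {spec.name}: R1/R2 pair count mismatch")
        processed, stats = process_pairs(
            zip(r1, r2),
            cfg.adapter,
            mref,
            cfg.merge,
            cfg.adapter_params,
            cfg.trim,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[preprocess] {spec.name}: {exc}") from exc

    try:
        records, table = run_alignment(
            processed, mref, cfg.align, sam_path=out_dir / f"{spec.name}.sam"
        )
        table.to_csv(out_dir / f"{spec.name}.alignments.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(f"[align] {spec.name}: {exc}") from exc

    try:
        tails = {a.read_id: classify_tail(a, mref.entry(a.ref_id)) for a in records}
        counts = tally_counts(records, tails, refset, input_reads=stats.input_pairs)
    except Exception as exc:
        raise StageError(f"[profile] {spec.name}: {exc}") from exc

    try:
        by_ref: dict[str, list[AlignmentRecord]] = {}
        for a in records:
            by_ref.setdefault(a.ref_id, []).append(a)
        modifications = {}
        for rid, recs in sorted(by_ref.items()):
            prof = accumulate_pileup(recs, mref.entry(rid))
            modifications[rid] = call_modifications(prof, mref.entry(rid), cfg.modifications)
    except Exception as exc:
        raise StageError(f"[modifications] {spec.name}: {exc}") from exc

    return LibraryResult(
        name=spec.name,
        stats=stats,
        records=records,
        tails=tails,
        counts=counts,
        modifications=modifications,
    )


def _write_library_reports(res: LibraryResult, out_dir: Path) -> None:
    res.counts.to_frame().to_csv(out_dir / f"{res.name}.counts.tsv", sep="\t", index=False)
    tail_rows = [
        {"read_id": rid, "category": t.category, "informative": t.informative,
         "extra_3prime_bases": t.extra_3prime_bases}
        for rid, t in res.tails.items()
    ]
    pd.DataFrame(
        tail_rows, columns=["read_id", "category", "informative", "extra_3prime_bases"]
    ).to_csv(out_dir / f"{res.name}.tails.tsv", sep="\t", index=False)
    mod_rows = []
    for rid, calls in res.modifications.items():
        for c in calls:
            mod_rows.append(
                {
                    "ref_id": rid,
                    "position": c.position,
                    "evidence": ",".join(sorted(c.evidence)),
                    "misincorporation_rate": round(c.misincorporation_rate, 6),
                    "stop_score": round(c.stop_score, 6),
                    "depth": c.depth,
                }
            )
    pd.DataFrame(
        mod_rows,
        columns=["ref_id", "position", "evidence", "misincorporation_rate", "stop_score", "depth"],
    ).to_csv(out_dir / f"{res.name}.modifications.tsv", sep="\t", index=False)
    stats = res.stats
    pd.DataFrame(
        [
            {
                "input_pairs": stats.input_pairs,
                "processed": stats.processed,
                "rejected_no_merge": stats.rejected_no_merge,
                "rejected_no_adapter": stats.rejected_no_adapter,
                "rejected_too_short": stats.rejected_too_short,
            }
        ]
    ).to_csv(out_dir / f"{res.name}.preprocess.tsv", sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full pipeline; returns the report directory."""
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        refset = load_reference_set(cfg.references_fasta, cfg.references_metadata)
        mref = build_mapping_reference(refset)
    except Exception as exc:
        raise StageError(f"[refdb] {exc}") from exc

    ntc_results = [
        _process_library(spec, cfg, mref, refset, out_dir) for spec in cfg.ntc_libraries
    ]
    results = [
        _process_library(spec, cfg, mref, refset, out_dir) for spec in cfg.libraries
    ]

    # Pool NTC libraries into one background count table.
    ntc_records = [a for res in ntc_results for a in res.records]
    ntc_tails = {k: v for res in ntc_results for k, v in res.tails.items()}
    ntc_depth = sum(res.stats.input_pairs for res in ntc_results)
    ntc_counts = tally_counts(ntc_records, ntc_tails, refset, input_reads=ntc_depth)

    thresholds_rows = []
    for res in ntc_results + results:
        _write_library_reports(res, out_dir)

    for res in results:
        try:
            mappable = res.counts.mapped_reads
            if mappable > 0:
                thresholds = background_threshold(ntc_counts, mappable, cfg.background)
            else:
                thresholds = {e.id: float(cfg.background.k_min) for e in refset}
            calls = [
                call_expression(
                    res.counts.record(e.id),
                    thresholds[e.id],
                    res.modifications.get(e.id, []),
                )
                for e in refset
            ]
            write_expression_report(calls, out_dir / f"{res.name}.expression.json")
            for e in refset:
                thresholds_rows.append(
                    {"library": res.name, "ref_id": e.id, "threshold": thresholds[e.id]}
                )
        except Exception as exc:
            raise StageError(f"[expression] {res.name}: {exc}") from exc

    pd.DataFrame(thresholds_rows, columns=["library", "ref_id", "threshold"]).to_csv(
        out_dir / "background_thresholds.tsv", sep="\t", index=False
    )

    # Anticodon tallies for references of interest.
    ac_rows = []
    for res in results + ntc_results:
        for rid in cfg.anticodon.refs:
            entry = refset.entry(rid)
            recs = [a for a in res.records if a.ref_id == rid]
            tally = tally_anticodon_variants(
                extract_anticodon_sequences(recs, entry), group=rid
            )
            for mer in sorted(tally.counts):
                ac_rows.append(
                    {
                        "library": res.name,
                        "ref_id": rid,
                        "anticodon": mer,
                        "count": tally.counts[mer],
                        "n_spanning": tally.n_reads_spanning,
                        "excluded_indel_reads": tally.excluded_indel_reads,
                    }
                )
    pd.DataFrame(
        ac_rows,
        columns=["library", "ref_id", "anticodon", "count", "n_spanning", "excluded_indel_reads"],
    ).to_csv(out_dir / "anticodon_tallies.tsv", sep="\t", index=False)

    log = {
        "msrseq_version": __version__,
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "adapter": cfg.adapter,
            "merge": dataclasses.asdict(cfg.merge),
            "adapter_params": dataclasses.asdict(cfg.adapter_params),
            "trim": dataclasses.asdict(cfg.trim),
            "align": dataclasses.asdict(cfg.align),
            "modifications": dataclasses.asdict(cfg.modifications),
            "background": dataclasses.asdict(cfg.background),
        },
        "libraries": [s.name for s in cfg.libraries],
        "ntc_libraries": [s.name for s in cfg.ntc_libraries],
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return out_dir
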