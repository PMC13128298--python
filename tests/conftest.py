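import pytest

from msrseq.preprocess import ProcessedRead
from msrseq.refdb import MappingEntry, MappingReference, build_mapping_reference
from msrseq.simulate import synthetic_reference_set


@pytest.fixture(scope="session")
def refset10():
    return synthetic_reference_set(10, seed=42)


@pytest.fixture(scope="session")
def mref10(refset10):
    return build_mapping_reference(refset10)


def mref_from_seqs(seqs: dict[str, str]) -> MappingReference:
    """Mapping reference straight from raw mapping sequences (tests only)."""
    entries = {
        rid: MappingEntry(
            ref_id=rid,
            mapping_sequence=s,
            gene_end=len(s) - 3,
            tail_span=(len(s) - 3, len(s)),
            genomic_cca=False,
        )
        for rid, s in seqs.items()
    }
    return MappingReference(entries=entries, refset=None)


def processed(seq: str, read_id: str = "r", quality: str | None = None) -> ProcessedRead:
    return ProcessedRead(read_id, seq, quality if quality is not None else "?" * len(seq))
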