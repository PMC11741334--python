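import numpy as np
import pandas as pd
import pysam
import pytest

from mosaicall.simulate import write_fasta, write_sam_fixture


@pytest.fixture(scope="session")
def reference():
    """Deterministic 400-bp single-chromosome reference."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return {"ref1": seq}


@pytest.fixture
def fasta_path(tmp_path, reference):
    path = tmp_path / "ref.fa"
    write_fasta(path, reference)
    return path


@pytest.fixture
def make_sam(tmp_path, reference):
    """Factory writing a coordinate-sorted SAM of read specs."""

    def _make(reads, name="reads.sam"):
        path = tmp_path / name
        write_sam_fixture(path, reference, reads)
        return str(path)

    return _make


def make_read(reference, **overrides):
    """An in-memory AlignedSegment with clean proper-pair defaults."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    })
    a = pysam.AlignedSegment(header)
    a.query_name = overrides.get("name", "read1")
    a.flag = overrides.get("flag", 99)
    a.reference_id = 0
    a.reference_start = overrides.get("start", 10)
    a.mapping_quality = overrides.get("mapq", 60)
    length = overrides.get("length", 75)
    a.cigarstring = overrides.get("cigar", f"{length}M")
    chrom = list(reference)[0]
    seq = overrides.get("seq")
    if seq is None:
        seq = reference[chrom][a.reference_start:a.reference_start + length]
        for off, base in overrides.get("mismatches", {}).items():
            seq = seq[:off] + base + seq[off + 1:]
    a.query_sequence = seq
    a.query_qualities = overrides.get("quals", [30] * len(seq))
    if "nm" in overrides:
        a.set_tag("NM", overrides["nm"])
    elif overrides.get("set_nm", True):
        a.set_tag("NM", len(overrides.get("mismatches", {})))
    a.next_reference_id = 0
    a.next_reference_start = a.reference_start
    a.template_length = length
    return a


@pytest.fixture
def clean_read(reference):
    return lambda **kw: make_read(reference, **kw)
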