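"""Shared fixtures: synthetic references and planted-indel read sets."""

from __future__ import annotations

import numpy as np
import pytest

from clipscan.alignment_core import AlignedRead, parse_cigar
from clipscan.realigner import ReferenceIndex
from clipscan.simulator import SimulationConfig, TruthRecord, random_reference


def make_read(
    name="r1",
    seq="A" * 100,
    cigar="100M",
    pos=0,
    chrom="chr1",
    mapq=60,
    quals=None,
    unmapped=False,
    **kw,
) -> AlignedRead:
    if quals is None:
        quals = bytes([63]) * len(seq)  # Q30
    if unmapped:
        return AlignedRead(name=name, seq=seq, quals=quals, is_unmapped=True, **kw)
    return AlignedRead(
        name=name, seq=seq, quals=quals, chrom=chrom, pos=pos, mapq=mapq,
        cigar=parse_cigar(cigar), is_unmapped=False, **kw,
    )


@pytest.fixture(scope="session")
def small_reference():
    return random_reference(20_000, seed=101, name="chr1")


@pytest.fixture(scope="session")
def small_index(small_reference):
    return ReferenceIndex(small_reference, k=16)


def plant_indel(reference: dict[str, str], svtype: str, size: int, start: int, seed=3):
    """Apply one indel to a reference; returns (mutated genome, truth record)."""
    chrom = next(iter(reference))
    seq = reference[chrom]
    rng = np.random.default_rng([seed, 9])
    if svtype == "DEL":
        mutated = seq[:start] + seq[start + size :]
        truth = TruthRecord(chrom=chrom, start=start, type="DEL", size=size)
    else:
        ins = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=size).tobytes().decode()
        mutated = seq[:start] + ins + seq[start:]
        truth = TruthRecord(chrom=chrom, start=start, type="INS", size=size, inserted_seq=ins)
    return {chrom: mutated}, truth


def tiled_reads(genome: dict[str, str], lo: int, hi: int, read_len=100, step=12):
    """Error-free reads tiled over genome[lo:hi] (mutated coordinates)."""
    chrom = next(iter(genome))
    seq = genome[chrom]
    reads = []
    for i, start in enumerate(range(lo, min(hi, len(seq) - read_len), step)):
        reads.append((f"t{i}", seq[start : start + read_len], bytes([63]) * read_len))
    return reads
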