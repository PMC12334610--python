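from __future__ import annotations

import numpy as np
import pysam
import pytest

from allelesplice.genemodels import Gene, GeneModels, Transcript

CHROM = "chr1"
CONTIG_LEN = 100_000


@pytest.fixture(scope="session")
def header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": CHROM, "LN": CONTIG_LEN}],
        }
    )


def build_read(
    header: pysam.AlignmentHeader,
    name: str = "read1",
    ref_start: int = 0,
    cigar: list[tuple[int, int]] | str = "100M",
    seq: str | None = None,
    quals: list[int] | None = None,
    flag: int = 0,
    chrom_id: int = 0,
    tags: dict | None = None,
) -> pysam.AlignedSegment:
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.flag = flag
    read.reference_id = chrom_id
    read.reference_start = ref_start
    read.mapping_quality = 60
    if isinstance(cigar, str):
        read.cigarstring = cigar
    else:
        read.cigartuples = cigar
    qlen = read.infer_query_length() or 0
    read.query_sequence = seq if seq is not None else "A" * qlen
    read.query_qualities = quals if quals is not None else [30] * qlen
    for key, value in (tags or {}).items():
        read.set_tag(key, value)
    return read


@pytest.fixture
def make_read(header):
    def _make(**kw):
        return build_read(header, **kw)

    return _make


@pytest.fixture
def small_gene_models() -> GeneModels:
    """One two-transcript gene: exons at [1000,1200), [1500,1700), [2000,2200);
    the second transcript skips the middle exon."""
    full = Transcript(
        "TX1", CHROM, "+", ((1000, 1200), (1500, 1700), (2000, 2200))
    )
    skip = Transcript("TX2", CHROM, "+", ((1000, 1200), (2000, 2200)))
    gene = Gene("GENE1", CHROM, "+", {"TX1": full, "TX2": skip})
    return GeneModels([gene])


def random_cigar(rng: np.random.Generator) -> tuple[int, list[tuple[int, int]]]:
    """A random valid CIGAR starting and ending with an aligned run."""
    ops = []
    if rng.random() < 0.3:
        ops.append((4, int(rng.integers(1, 20))))  # leading soft clip
    n_blocks = int(rng.integers(1, 6))
    for i in range(n_blocks):
        ops.append((int(rng.choice([0, 7, 8])), int(rng.integers(1, 80))))
        if i < n_blocks - 1:
            gap_op = int(rng.choice([1, 2, 3]))
            ops.append((gap_op, int(rng.integers(1, 60))))
    if rng.random() < 0.3:
        ops.append((4, int(rng.integers(1, 20))))  # trailing soft clip
    ref_start = int(rng.integers(0, 5000))
    return ref_start, ops
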