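"""Read selection and per-base observation extraction from BAM alignments.

Works directly on :class:`pysam.AlignedSegment` records. The CIGAR walk in
:func:`base_at_position` reproduces the per-position base/quality extraction
that tools like sam2tsv provide, without leaving Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam

from .variants import TargetRegion

logger = logging.getLogger(__name__)

# CIGAR operation codes (BAM encoding)
_CONSUMES_QUERY = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X
_MATCH_OPS = {0, 7, 8}  # M, =, X
_OP_LENGTH = "MIDNSHP=X"


@dataclass(frozen=True)
class BaseObservation:
    """One read's base call at a reference position.

    ``base`` is None when the position falls inside a deletion or reference
    skip of the alignment (the read aligns across but carries no base there).
    """

    read_id: str
    base: str | None
    phred_q: int | None

    @property
    def has_base(self) -> bool:
        return self.base is not None and self.base in "ACGT"


def select_spanning_reads(
    bam: pysam.AlignmentFile, chrom: str, pos: int
) -> list[pysam.AlignedSegment]:
    """Primary alignments whose reference interval contains 1-based ``pos``.

    Secondary and supplementary records are excluded; chimeric reads are
    handled separately via their primary record's SA tag.
    """
    if chrom not in bam.references:
        logger.warning("chromosome %s absent from BAM header", chrom)
        return []
    p0 = pos - 1
    out = []
    for read in bam.fetch(chrom, p0, p0 + 1):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        if read.reference_start <= p0 < read.reference_end:
            out.append(read)
    return out


def _sa_segments(read: pysam.AlignedSegment) -> list[tuple[str, int, int]]:
    """Supplementary-segment reference intervals from the SA tag (0-based)."""
    if not read.has_tag("SA"):
        return []
    segments = []
    for entry in str(read.get_tag("SA")).rstrip(";").split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        chrom, pos, cigar = fields[0], int(fields[1]), fields[3]
        ref_len = _cigar_reference_length(cigar)
        segments.append((chrom, pos - 1, pos - 1 + ref_len))
    return segments


def _cigar_reference_length(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                total += int(num)
            num = ""
    return total


def remove_chimeric_reads(
    reads: list[pysam.AlignedSegment], region: TargetRegion
) -> list[pysam.AlignedSegment]:
    """Drop reads with a split segment mapping outside the target region.

    A read is chimeric here when any supplementary segment (SA tag of the
    primary record) lies on another chromosome or outside the region —
    i.e. it maps both within the gene of interest and outside of it.
    """
    kept = []
    for read in reads:
        chimeric = False
        for chrom, start, end in _sa_segments(read):
            if chrom != region.chrom or start < region.start or end > region.end:
                chimeric = True
                break
        if not chimeric:
            kept.append(read)
    return kept


def base_at_position(read: pysam.AlignedSegment, pos: int) -> BaseObservation:
    """Walk the CIGAR to the query base aligned at 0-based reference ``pos``.

    Returns an observation with the base and its Phred quality when the
    position falls in an aligned (M/=/X) run, or with ``base=None`` when it
    falls in a deletion or reference skip. ``pos`` must lie inside the
    read's reference span.
    """
    if not (read.reference_start <= pos < read.reference_end):
        raise ValueError(
            f"position {pos} outside reference span "
            f"[{read.reference_start}, {read.reference_end}) of {read.query_name}"
        )
    ref = read.reference_start
    query = 0
    seq = read.query_sequence
    quals = read.query_qualities
    for op, length in read.cigartuples:
        consumes_ref = op in _CONSUMES_REF
        consumes_query = op in _CONSUMES_QUERY
        if consumes_ref and ref <= pos < ref + length:
            if op in _MATCH_OPS:
                offset = query + (pos - ref)
                if seq is None or quals is None:
                    raise ValueError(
                        f"read {read.query_name} lacks sequence or qualities"
                    )
                return BaseObservation(
                    read.query_name, seq[offset].upper(), int(quals[offset])
                )
            # D or N: aligned across, no base present
            return BaseObservation(read.query_name, None, None)
        if consumes_ref:
            ref += length
        if consumes_query:
            query += length
    raise AssertionError("unreachable: pos inside span but not in any CIGAR run")


def collect_observations(
    reads: list[pysam.AlignedSegment], pos: int
) -> list[BaseObservation]:
    """Base observations at 0-based ``pos`` for every read spanning it.

    Reads not spanning the position, and reads without stored base
    qualities, are skipped (the latter with a counted warning).
    """
    obs = []
    n_no_qual = 0
    for read in reads:
        if not (read.reference_start <= pos < read.reference_end):
            continue
        if read.query_qualities is None or read.query_sequence is None:
            n_no_qual += 1
            continue
        obs.append(base_at_position(read, pos))
    if n_no_qual:
        logger.warning(
            "%d reads without stored base qualities skipped at position %d",
            n_no_qual,
            pos,
        )
    return obs


def phred_reliability(q: int | float) -> float:
    """Percent base-call reliability implied by Phred quality ``q``.

    Q = -10*log10(p_error), so reliability = 100*(1 - 10^(-q/10));
    Q=10 gives 90.0%, Q=20 gives 99.0%.
    """
    if q < 0:
        raise ValueError(f"Phred quality must be non-negative, got {q}")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))
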