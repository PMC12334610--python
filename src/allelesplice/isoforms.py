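"""Junction-chain extraction and isoform collapse.

A read's isoform identity is carried by its splice-junction chain: the
ordered set of intron intervals spliced out of the alignment. Reads sharing
a chain are collapsed into isoform groups (FLAIR-collapse semantics: a
minimum supporting-read count, representative ends never adjusted to the
annotation), matched against annotated transcripts, and counted per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .allelic import HAP1, HAP2, AllelePartition
from .genemodels import Gene

DEFAULT_MIN_INTRON = 20
DEFAULT_MIN_SUPPORT = 4
DEFAULT_SE_OVERLAP = 0.8


@dataclass(frozen=True)
class JunctionChain:
    """Ordered intron intervals of one read or isoform (0-based half-open)."""

    chrom: str
    introns: tuple[tuple[int, int], ...]
    strand: str = "."

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.introns:
            if s >= e:
                raise ValueError(f"empty intron ({s}, {e})")
            if s < prev_end:
                raise ValueError("introns must be sorted and disjoint")
            prev_end = e

    @property
    def is_single_exon(self) -> bool:
        return not self.introns

    def key(self) -> tuple:
        return (self.chrom, self.introns)


@dataclass(frozen=True)
class IsoformGroup:
    """A supported cluster of reads sharing one junction chain."""

    chain: JunctionChain
    rep_start: int
    rep_end: int
    read_ids: tuple[str, ...]
    label: str = ""

    @property
    def n_support(self) -> int:
        return len(self.read_ids)


def extract_junction_chain(
    read: pysam.AlignedSegment, min_intron: int = DEFAULT_MIN_INTRON
) -> JunctionChain:
    """Introns (reference skips >= ``min_intron``) of one aligned read.

    Shorter N runs are ignored as alignment artifacts rather than introns;
    deletions never produce junctions.
    """
    introns = []
    ref = read.reference_start
    for op, length in read.cigartuples:
        if op == 3 and length >= min_intron:  # N
            introns.append((ref, ref + length))
        if op in (0, 2, 3, 7, 8):  # consumes reference
            ref += length
    strand = "-" if read.is_reverse else "+"
    return JunctionChain(read.reference_name, tuple(introns), strand)


def collapse_isoforms(
    reads_with_chains: Iterable[tuple[str, JunctionChain, int, int]],
    min_support: int = DEFAULT_MIN_SUPPORT,
    single_exon_overlap: float = DEFAULT_SE_OVERLAP,
) -> list[IsoformGroup]:
    """Group reads into isoform models by exact junction-chain identity.

    Input tuples are (read_id, chain, alignment start, alignment end).
    Single-exon reads (empty chains) are clustered by reciprocal overlap of
    their aligned spans instead (>= ``single_exon_overlap`` against the
    running cluster span). Groups supported by fewer than ``min_support``
    reads are discarded, leaving their reads unassigned. Representative
    ends are the medians of member starts/ends (never adjusted to the
    annotation). Output is independent of input read order.
    """
    entries = list(reads_with_chains)
    spliced: dict[tuple, list[tuple[str, int, int]]] = {}
    mono: list[tuple[str, int, int, str]] = []  # (read_id, start, end, chrom)
    chains_by_key: dict[tuple, JunctionChain] = {}
    for read_id, chain, start, end in entries:
        if chain.is_single_exon:
            mono.append((read_id, start, end, chain.chrom))
        else:
            spliced.setdefault(chain.key(), []).append((read_id, start, end))
            chains_by_key.setdefault(chain.key(), chain)
    groups: list[IsoformGroup] = []
    for key in sorted(spliced):
        members = sorted(spliced[key])
        if len(members) < min_support:
            continue
        groups.append(_make_group(chains_by_key[key], members))
    # Single-exon reads: deterministic single-pass clustering over the
    # position-sorted list; a read joins the open cluster when it
    # reciprocally overlaps the cluster's current span.
    for chrom in sorted({m[3] for m in mono}):
        spans = sorted(
            ((s, e, rid) for rid, s, e, c in mono if c == chrom),
        )
        clusters: list[list[tuple[str, int, int]]] = []
        cluster_span: tuple[int, int] | None = None
        for s, e, rid in spans:
            if cluster_span is not None and _reciprocal_overlap(
                (s, e), cluster_span
            ) >= single_exon_overlap:
                clusters[-1].append((rid, s, e))
                cluster_span = (min(cluster_span[0], s), max(cluster_span[1], e))
            else:
                clusters.append([(rid, s, e)])
                cluster_span = (s, e)
        for members in clusters:
            if len(members) < min_support:
                continue
            groups.append(
                _make_group(JunctionChain(chrom, ()), sorted(members))
            )
    groups.sort(key=lambda g: (g.chain.chrom, g.rep_start, g.chain.introns))
    return groups


def _make_group(
    chain: JunctionChain, members: list[tuple[str, int, int]]
) -> IsoformGroup:
    starts = [s for _, s, _ in members]
    ends = [e for _, _, e in members]
    return IsoformGroup(
        chain=chain,
        rep_start=int(median(starts)),
        rep_end=int(median(ends)),
        read_ids=tuple(rid for rid, _, _ in members),
    )


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def match_annotation(
    groups: Sequence[IsoformGroup],
    gene: Gene | None,
    fuzz: int = 0,
) -> list[IsoformGroup]:
    """Label each group with the transcript whose intron chain it matches.

    Matching is exact by default (``fuzz`` allows a per-boundary tolerance
    in bp). Empty-chain groups match single-exon transcripts whose span
    contains the representative span. Unmatched groups get deterministic
    "novel-k" ordinals in group sort order.
    """
    labeled = []
    novel_ordinal = 0
    transcripts = list(gene.transcripts.values()) if gene is not None else []
    for group in groups:
        label = None
        for tx in sorted(transcripts, key=lambda t: t.transcript_id):
            if group.chain.is_single_exon:
                if not tx.introns and tx.start <= group.rep_start and group.rep_end <= tx.end:
                    label = tx.transcript_id
                    break
            elif _chains_match(group.chain.introns, tx.introns, fuzz):
                label = tx.transcript_id
                break
        if label is None:
            novel_ordinal += 1
            label = f"novel-{novel_ordinal}"
        labeled.append(replace(group, label=label))
    return labeled


def _chains_match(
    a: tuple[tuple[int, int], ...], b: tuple[tuple[int, int], ...], fuzz: int
) -> bool:
    if len(a) != len(b) or not a:
        return False
    if fuzz == 0:
        return a == b
    return all(
        abs(x[0] - y[0]) <= fuzz and abs(x[1] - y[1]) <= fuzz
        for x, y in zip(a, b)
    )


def quantify_per_allele(
    groups: Sequence[IsoformGroup], partition: AllelePartition
) -> pd.DataFrame:
    """Raw per-allele read counts and usage fractions per isoform group.

    Returns a DataFrame indexed by isoform label with columns
    ``count_allele1``/``count_allele2`` (raw counts of group-assigned reads
    on the ref/alt side of the partition) and ``usage_allele1``/
    ``usage_allele2`` (fractions summing to 1 per allele with >= 1 assigned
    read; NaN for an allele with none).
    """
    rows = []
    for group in groups:
        c1 = sum(1 for rid in group.read_ids if partition.allele_of(rid) == HAP1)
        c2 = sum(1 for rid in group.read_ids if partition.allele_of(rid) == HAP2)
        rows.append((group.label or repr(group.chain.introns), c1, c2))
    df = pd.DataFrame(rows, columns=["isoform", "count_allele1", "count_allele2"])
    df = df.set_index("isoform")
    for allele in ("allele1", "allele2"):
        total = df[f"count_{allele}"].sum()
        df[f"usage_{allele}"] = (
            df[f"count_{allele}"] / total if total > 0 else float("nan")
        )
    return df
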