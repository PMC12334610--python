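"""Splicing-variant and allele-informative-SNV handling.

Parses the two heterozygous variant inputs, computes SpliceAI-style delta
scores, applies the delta-score and splice-region filters, and derives the
per-variant target region to analyse.

Coordinate conventions: VCF positions are 1-based; every internal interval is
0-based half-open. Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from .genemodels import GeneModels

logger = logging.getLogger(__name__)

SPLICEAI_INFO_KEY = "SpliceAI"
_SPLICEAI_TOKENS = 10


class MalformedAnnotationError(ValueError):
    """A SpliceAI annotation field does not follow the 10-token layout."""


@dataclass(frozen=True)
class SpliceAIRecord:
    """One per-transcript SpliceAI score record.

    ``ds_*`` are probabilities of acceptor gain/loss and donor gain/loss in
    [0, 1]; ``dp_*`` are the signed base-pair offsets (relative to the variant
    position) of the most affected positions.
    """

    allele: str
    gene_symbol: str
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int

    @property
    def delta_score(self) -> float:
        """Maximal probability of splicing alteration across the four events."""
        return max(self.ds_ag, self.ds_al, self.ds_dg, self.ds_dl)

    @property
    def offsets(self) -> tuple[int, int, int, int]:
        return (self.dp_ag, self.dp_al, self.dp_dg, self.dp_dl)

    def serialize(self) -> str:
        return "|".join(
            [
                self.allele,
                self.gene_symbol,
                _fmt_ds(self.ds_ag),
                _fmt_ds(self.ds_al),
                _fmt_ds(self.ds_dg),
                _fmt_ds(self.ds_dl),
                str(self.dp_ag),
                str(self.dp_al),
                str(self.dp_dg),
                str(self.dp_dl),
            ]
        )


def _fmt_ds(x: float) -> str:
    return f"{x:.2f}"


@dataclass(frozen=True)
class SplicingVariant:
    """A heterozygous candidate splice-altering variant with SpliceAI scores."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int
    genotype: tuple[int, int] = (0, 1)
    filter_pass: bool = True

    @property
    def delta_score(self) -> float:
        return max(self.ds_ag, self.ds_al, self.ds_dg, self.ds_dl)

    @property
    def offsets(self) -> tuple[int, int, int, int]:
        return (self.dp_ag, self.dp_al, self.dp_dg, self.dp_dl)

    @property
    def is_heterozygous(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class AlleleInformativeSNV:
    """A heterozygous SNV whose base identity assigns a read to an allele."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"informative SNV alleles must be single bases: {self}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical: {self}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class TargetRegion:
    """The genomic interval analysed for one splicing variant."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_symbol: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.start}..{self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def parse_spliceai_annotation(
    raw_field: str, variant_id: str = "?"
) -> list[SpliceAIRecord]:
    """Parse a pipe-delimited SpliceAI INFO field into per-transcript records.

    Layout per record: ``ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|
    DP_DG|DP_DL``; several records may be comma-separated when more than one
    gene/transcript annotates the variant.
    """
    records = []
    for chunk in str(raw_field).split(","):
        tokens = chunk.split("|")
        if len(tokens) != _SPLICEAI_TOKENS:
            raise MalformedAnnotationError(
                f"variant {variant_id}: SpliceAI record has {len(tokens)} tokens, "
                f"expected {_SPLICEAI_TOKENS}: {chunk!r}"
            )
        allele, symbol = tokens[0], tokens[1]
        try:
            ds = tuple(float(t) for t in tokens[2:6])
            dp = tuple(int(t) for t in tokens[6:10])
        except ValueError as exc:
            raise MalformedAnnotationError(
                f"variant {variant_id}: non-numeric SpliceAI token in {chunk!r}"
            ) from exc
        for score in ds:
            if not 0.0 <= score <= 1.0:
                raise MalformedAnnotationError(
                    f"variant {variant_id}: sub-score {score} outside [0, 1]"
                )
        records.append(SpliceAIRecord(allele, symbol, *ds, *dp))
    return records


def best_spliceai_record(records: Sequence[SpliceAIRecord]) -> SpliceAIRecord:
    """Pick the record with maximal delta score (stable on ties)."""
    return max(records, key=lambda r: r.delta_score)


def select_splicing_variants(
    variants: Iterable[SplicingVariant],
    delta_threshold: float = 0.5,
    splice_region_only: bool = False,
    gene_models: GeneModels | None = None,
    branch_window: tuple[int, int] | None = None,
) -> list[SplicingVariant]:
    """Retain heterozygous, PASS variants with delta score >= threshold.

    ``splice_region_only`` additionally restricts to positions inside
    annotated splice regions (see :func:`splice_region_filter`); it requires
    ``gene_models``.
    """
    kept = []
    for v in variants:
        if not v.is_heterozygous or not v.filter_pass:
            continue
        if v.delta_score < delta_threshold:
            continue
        if splice_region_only:
            if gene_models is None:
                raise ValueError("splice_region_only requires gene_models")
            if not splice_region_filter(v, gene_models, branch_window=branch_window):
                continue
        kept.append(v)
    return kept


def splice_region_filter(
    variant: SplicingVariant,
    gene_models: GeneModels,
    exon_window: tuple[int, int] = (1, 3),
    intron_window: tuple[int, int] = (3, 8),
    branch_window: tuple[int, int] | None = None,
) -> bool:
    """True iff the variant sits in a splice region of any annotated transcript.

    A splice region is 1-3 bases into an exon from an exon-intron junction,
    3-8 bases into the intron from the junction, or (when ``branch_window``
    is given, e.g. ``(18, 44)``) within that many bases upstream of an
    acceptor site inside the intron. A variant outside every annotated gene
    is simply not a splice-region variant (returns False).
    """
    p = variant.pos - 1  # 0-based
    for gene in gene_models.overlapping(variant.chrom, p):
        for tx in gene.transcripts.values():
            if _in_splice_region(p, tx, exon_window, intron_window, branch_window):
                return True
    return False


def _in_splice_region(
    p: int,
    tx,
    exon_window: tuple[int, int],
    intron_window: tuple[int, int],
    branch_window: tuple[int, int] | None,
) -> bool:
    ex_lo, ex_hi = exon_window
    in_lo, in_hi = intron_window
    n = len(tx.exons)
    for i, (s, e) in enumerate(tx.exons):
        # Junction at the exon start (an intron precedes this exon).
        if i > 0:
            # 1..k bases into the exon: positions s .. s+k-1
            if s + ex_lo - 1 <= p <= s + ex_hi - 1:
                return True
            # 1..k bases into the intron: positions s-1 downward
            if s - in_hi <= p <= s - in_lo:
                return True
            # Branch-point window upstream of the acceptor (plus strand:
            # acceptor is the exon start; minus strand handled below).
            if branch_window is not None and tx.strand != "-":
                b_lo, b_hi = branch_window
                if s - b_hi <= p <= s - b_lo:
                    return True
        # Junction at the exon end (an intron follows this exon).
        if i < n - 1:
            if e - ex_hi <= p <= e - ex_lo:
                return True
            if e + in_lo - 1 <= p <= e + in_hi - 1:
                return True
            if branch_window is not None and tx.strand == "-":
                b_lo, b_hi = branch_window
                if e + b_lo - 1 <= p <= e + b_hi - 1:
                    return True
    return False


def derive_target_region(
    variant: SplicingVariant, gene_models: GeneModels | None = None
) -> TargetRegion:
    """Region predicted to be affected, expanded to the containing gene span.

    The affected window spans the minimal and maximal coordinates among the
    variant position and the four SpliceAI offset positions. When the
    variant's gene is annotated, the region is expanded to cover the gene's
    full span (the gene is the unit covered by the long reads); otherwise the
    bare affected window is used with a logged warning.
    """
    affected_1based = [variant.pos] + [variant.pos + d for d in variant.offsets]
    start = min(affected_1based) - 1  # to 0-based
    end = max(affected_1based)  # half-open
    gene = gene_models.get(variant.gene_symbol) if gene_models is not None else None
    if gene is not None and gene.chrom == variant.chrom:
        start = min(start, gene.start)
        end = max(end, gene.end)
    else:
        logger.warning(
            "gene %s not found in annotation for %s; using SpliceAI-affected "
            "window only",
            variant.gene_symbol,
            variant.variant_id,
        )
    return TargetRegion(variant.chrom, start, end, variant.gene_symbol)


# ---------------------------------------------------------------------------
# VCF I/O


def _genotype_of(sample) -> tuple[int, int] | None:
    gt = sample.get("GT")
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return None
    return (gt[0], gt[1])


def _is_pass(record: pysam.VariantRecord) -> bool:
    filters = list(record.filter.keys())
    return filters == [] or filters == ["PASS"]


def read_splicing_variants(
    vcf_path: str, sample: str | None = None
) -> list[SplicingVariant]:
    """Read SpliceAI-annotated candidate splicing variants from a VCF.

    Multi-allelic records are split into bi-allelic candidates; the
    per-variant scores come from the transcript record with the maximal delta
    score. Records without a SpliceAI INFO field are skipped with a warning.
    """
    out: list[SplicingVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_name = sample or (list(vcf.header.samples)[0] if vcf.header.samples else None)
        for rec in vcf:
            raw = rec.info.get(SPLICEAI_INFO_KEY)
            if raw is None:
                logger.warning("no SpliceAI annotation at %s:%d; skipped", rec.chrom, rec.pos)
                continue
            if isinstance(raw, tuple):
                raw = ",".join(str(r) for r in raw)
            gt = (0, 1)
            if sample_name is not None:
                parsed = _genotype_of(rec.samples[sample_name])
                if parsed is None:
                    continue
                gt = parsed
            records = parse_spliceai_annotation(raw, f"{rec.chrom}:{rec.pos}")
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                matching = [r for r in records if r.allele == alt] or records
                best = best_spliceai_record(matching)
                # Collapse the multi-allelic genotype onto this alt.
                gt_bi = tuple(1 if a == alt_index else 0 for a in gt)
                out.append(
                    SplicingVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        gene_symbol=best.gene_symbol,
                        ds_ag=best.ds_ag,
                        ds_al=best.ds_al,
                        ds_dg=best.ds_dg,
                        ds_dl=best.ds_dl,
                        dp_ag=best.dp_ag,
                        dp_al=best.dp_al,
                        dp_dg=best.dp_dg,
                        dp_dl=best.dp_dl,
                        genotype=gt_bi,
                        filter_pass=_is_pass(rec),
                    )
                )
    return out


def read_informative_snvs(
    vcf_path: str, sample: str | None = None
) -> list[AlleleInformativeSNV]:
    """Read heterozygous, PASS, single-nucleotide candidate informative SNVs."""
    out: list[AlleleInformativeSNV] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_name = sample or (list(vcf.header.samples)[0] if vcf.header.samples else None)
        for rec in vcf:
            if not _is_pass(rec):
                continue
            if sample_name is not None:
                gt = _genotype_of(rec.samples[sample_name])
                if gt is None or gt[0] == gt[1]:
                    continue
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    out.append(AlleleInformativeSNV(rec.chrom, rec.pos, rec.ref, alt))
    return out


def as_informative_snv(variant: SplicingVariant) -> AlleleInformativeSNV | None:
    """View an SNV splicing variant as its own informative site (None for indels)."""
    if not variant.is_snv:
        return None
    return AlleleInformativeSNV(
        variant.chrom, variant.pos, variant.ref_allele, variant.alt_allele
    )
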