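"""End-to-end orchestration: from inputs to the corrected summary table.

For every splicing variant the pipeline derives the target region, selects
spanning reads, removes chimeras, gates candidate informative SNVs,
partitions (and, over multi-SNV reads, phases) the reads into two alleles,
collapses each allele pool into isoform groups, tests per-isoform usage
between alleles, and finally Bonferroni-corrects the per-pair minimum
p-values across the unique variants tested.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from . import __version__
from .alignments import collect_observations, remove_chimeric_reads, select_spanning_reads
from .allelic import (
    AllelePartition,
    PhasedBlock,
    block_partition,
    emit_phased_vcf,
    gate_candidate_snv,
    partition_reads,
    phase_informative_sites,
)
from .diffusage import (
    DiffUsageRecord,
    PairSkipped,
    bonferroni_correct,
    per_isoform_exact_test,
    records_to_frame,
    significant_variants,
    summarize_pair,
    unique_variants_tested,
    write_summary,
)
from .genemodels import GeneModels
from .isoforms import (
    collapse_isoforms,
    extract_junction_chain,
    match_annotation,
    quantify_per_allele,
)
from .variants import (
    AlleleInformativeSNV,
    SplicingVariant,
    as_informative_snv,
    derive_target_region,
    read_informative_snvs,
    read_splicing_variants,
    select_splicing_variants,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters (defaults follow the published settings).

    ``mode`` is "transcriptome" or "amplicon"; the amplicon preset raises
    the base-quality threshold to 15 and, because its variant list is
    user-curated, skips the delta-score filter.
    """

    delta_threshold: float = 0.5
    min_informative_reads: int = 10
    min_base_quality: int = 10
    min_isoform_support: int = 4
    alpha: float = 0.05
    s_max: int = 16
    min_intron: int = 20
    single_exon_overlap: float = 0.8
    junction_fuzz: int = 0
    splice_region_only: bool = False
    bonferroni_per_pair: bool = False
    workers: int = 1
    mode: str = "transcriptome"
    write_allele_bams: bool = True
    write_phased_vcfs: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_threshold <= 1.0:
            raise ValueError("delta_threshold must be in [0, 1]")
        if self.min_informative_reads < 1 or self.min_isoform_support < 1:
            raise ValueError("read-support thresholds must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in ("transcriptome", "amplicon"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def amplicon(cls, **overrides) -> "PipelineConfig":
        overrides.setdefault("min_base_quality", 15)
        return cls(mode="amplicon", **overrides)

    @property
    def apply_delta_filter(self) -> bool:
        return self.mode != "amplicon"


@dataclass
class PairAnalysis:
    """One (variant, informative site-or-block) unit of analysis."""

    site_id: str
    partition: AllelePartition
    snv: AlleleInformativeSNV | None = None
    block: PhasedBlock | None = None
    groups: list = field(default_factory=list)
    usage: pd.DataFrame | None = None
    record: DiffUsageRecord | None = None
    skip_reason: str | None = None


@dataclass
class VariantAnalysis:
    variant: SplicingVariant
    pairs: list[PairAnalysis] = field(default_factory=list)
    n_spanning_reads: int = 0
    drop_reason: str | None = None

    @property
    def tested(self) -> bool:
        return any(p.record is not None for p in self.pairs)


@dataclass
class RunResult:
    config: PipelineConfig
    analyses: list[VariantAnalysis]
    records: list[DiffUsageRecord] = field(default_factory=list)
    funnel: dict[str, int] = field(default_factory=dict)
    summary_path: Path | None = None

    @property
    def summary(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def analyze_variant(
    variant: SplicingVariant,
    reads: Sequence[pysam.AlignedSegment],
    candidate_snvs: Sequence[AlleleInformativeSNV],
    gene_models: GeneModels,
    config: PipelineConfig,
) -> VariantAnalysis:
    """Run the per-variant stages on an in-memory read collection.

    ``reads`` may be any superset of the reads near the variant; spanning
    selection and chimera removal happen here. Every candidate SNV that
    passes the coverage/quality gate yields its own variant-site pair, the
    variant itself acts as a site when it is an SNV with gated coverage
    (exonic, or intronic under intron retention), and when two or more
    sites pass, their phased haplotype block yields one more pair.
    """
    analysis = VariantAnalysis(variant=variant)
    region = derive_target_region(variant, gene_models)
    p0 = variant.pos - 1
    spanning = [
        r
        for r in reads
        if not (r.is_secondary or r.is_supplementary or r.is_unmapped)
        and r.reference_name == variant.chrom
        and r.reference_start <= p0 < r.reference_end
    ]
    spanning = remove_chimeric_reads(spanning, region)
    analysis.n_spanning_reads = len(spanning)
    if not spanning:
        analysis.drop_reason = "no_spanning_reads"
        return analysis

    # Candidate informative sites: user-supplied SNVs inside the region,
    # plus the splicing variant itself when it is an SNV.
    sites: list[AlleleInformativeSNV] = []
    seen_pos: set[int] = set()
    self_site = as_informative_snv(variant)
    if self_site is not None:
        sites.append(self_site)
        seen_pos.add(self_site.pos)
    for snv in candidate_snvs:
        if snv.chrom != variant.chrom or snv.pos in seen_pos:
            continue
        if region.contains(snv.pos - 1):
            sites.append(snv)
            seen_pos.add(snv.pos)
    sites.sort(key=lambda s: s.pos)

    gated: list[tuple[AlleleInformativeSNV, AllelePartition, dict[str, int | None]]] = []
    for site in sites:
        obs = collect_observations(spanning, site.pos - 1)
        passed, retained = gate_candidate_snv(
            obs, config.min_informative_reads, config.min_base_quality
        )
        if not passed:
            continue
        n_low = sum(
            1
            for o in obs
            if o.has_base and o.phred_q is not None and o.phred_q < config.min_base_quality
        )
        part = partition_reads(retained, site, n_low_quality=n_low)
        calls: dict[str, int | None] = {}
        for o in retained:
            if o.base == site.ref_allele:
                calls[o.read_id] = 0
            elif o.base == site.alt_allele:
                calls[o.read_id] = 1
            else:
                calls[o.read_id] = None
        gated.append((site, part, calls))

    if not gated:
        analysis.drop_reason = "no_informative_site"
        return analysis

    pairs = [
        PairAnalysis(site_id=site.site_id, partition=part, snv=site)
        for site, part, _ in gated
    ]
    if len(gated) >= 2:
        positions = [site.pos for site, _, _ in gated]
        matrix: dict[str, list[int | None]] = {}
        for j, (_, _, calls) in enumerate(gated):
            for rid, c in calls.items():
                matrix.setdefault(rid, [None] * len(gated))[j] = c
        matrix = {
            rid: row for rid, row in matrix.items() if any(c is not None for c in row)
        }
        if matrix:
            block = phase_informative_sites(matrix, positions, s_max=config.s_max)
            pairs.append(
                PairAnalysis(
                    site_id=block.block_id,
                    partition=block_partition(block),
                    block=block,
                )
            )

    reads_by_id = {r.query_name: r for r in spanning}
    for pair in pairs:
        _test_pair(variant, pair, reads_by_id, gene_models, config)
    analysis.pairs = pairs
    if not analysis.tested:
        analysis.drop_reason = "no_testable_pair"
    return analysis


def _test_pair(
    variant: SplicingVariant,
    pair: PairAnalysis,
    reads_by_id: dict[str, pysam.AlignedSegment],
    gene_models: GeneModels,
    config: PipelineConfig,
) -> None:
    part = pair.partition
    assigned = sorted(part.ref_read_ids | part.alt_read_ids)
    entries = []
    for rid in assigned:
        read = reads_by_id.get(rid)
        if read is None:
            continue
        chain = extract_junction_chain(read, config.min_intron)
        entries.append((rid, chain, read.reference_start, read.reference_end))
    groups = collapse_isoforms(
        entries,
        min_support=config.min_isoform_support,
        single_exon_overlap=config.single_exon_overlap,
    )
    gene = gene_models.get(variant.gene_symbol)
    groups = match_annotation(groups, gene, fuzz=config.junction_fuzz)
    pair.groups = groups
    if not groups:
        pair.skip_reason = "no_supported_isoform"
        return
    usage = quantify_per_allele(groups, part)
    pair.usage = usage
    hap_info = "."
    if pair.block is not None:
        hap_info = ";".join(
            f"{p}:{g}" for p, g in zip(pair.block.positions, pair.block.genotype_strings())
        )
    try:
        pvals = per_isoform_exact_test(usage)
        pair.record = summarize_pair(
            variant.variant_id, pair.site_id, pvals, part, haplotype_info=hap_info
        )
    except PairSkipped as skip:
        pair.skip_reason = skip.reason


def correct_and_collect(
    analyses: Sequence[VariantAnalysis], config: PipelineConfig
) -> tuple[list[DiffUsageRecord], dict[str, int]]:
    """Bonferroni-correct across tested variants and build the funnel."""
    raw = [p.record for a in analyses for p in a.pairs if p.record is not None]
    if raw:
        if config.bonferroni_per_pair:
            n_tests = len(raw)
        else:
            n_tests = unique_variants_tested(raw)
        records = bonferroni_correct(raw, n_tests, alpha=config.alpha)
    else:
        records = []
    funnel = {
        "variants_in": len(analyses),
        "variants_with_informative_site": sum(1 for a in analyses if a.pairs),
        "variants_tested": sum(1 for a in analyses if a.tested),
        "variants_significant": len(significant_variants(records)),
    }
    return records, funnel


def analyze_bundle(bundle, config: PipelineConfig | None = None) -> RunResult:
    """Run the analysis stages directly on a simulated in-memory bundle."""
    config = config or PipelineConfig()
    variants = [bundle.splicing_variant]
    if config.apply_delta_filter:
        variants = select_splicing_variants(variants, config.delta_threshold)
    analyses = [
        analyze_variant(v, bundle.reads, bundle.informative_snvs, bundle.gene_models, config)
        for v in variants
    ]
    records, funnel = correct_and_collect(analyses, config)
    return RunResult(config=config, analyses=analyses, records=records, funnel=funnel)


# ---------------------------------------------------------------------------
# File-based run


def _analyze_from_files(
    variant: SplicingVariant,
    bam_path: str,
    snvs: Sequence[AlleleInformativeSNV],
    gene_models: GeneModels,
    config: PipelineConfig,
) -> VariantAnalysis:
    with pysam.AlignmentFile(bam_path) as bam:
        reads = select_spanning_reads(bam, variant.chrom, variant.pos)
        return analyze_variant(variant, reads, snvs, gene_models, config)


def _worker_task(args) -> VariantAnalysis:
    variant, bam_path, snvs, gtf_path, config = args
    gene_models = GeneModels.from_gtf(gtf_path)
    return _analyze_from_files(variant, bam_path, snvs, gene_models, config)


def run(
    config: PipelineConfig,
    bam_path: str | Path,
    splicing_vcf: str | Path,
    snv_vcf: str | Path,
    gtf_path: str | Path,
    outdir: str | Path,
    prefix: str = "run",
) -> RunResult:
    """Execute the full pipeline from files and write all outputs.

    Outputs under ``outdir``: the corrected summary TSV
    (``<prefix>_minpvalue005_spvar_corrected.tsv``), per-pair isoform-usage
    TSVs and allele-separated BAMs, per-block phased VCFs, and a JSON run
    metadata file with the configuration and per-stage funnel counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in (bam_path, splicing_vcf, snv_vcf, gtf_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")

    gene_models = GeneModels.from_gtf(str(gtf_path))
    all_variants = read_splicing_variants(str(splicing_vcf))
    if config.apply_delta_filter:
        variants = select_splicing_variants(
            all_variants,
            config.delta_threshold,
            splice_region_only=config.splice_region_only,
            gene_models=gene_models,
        )
    else:
        variants = [v for v in all_variants if v.is_heterozygous and v.filter_pass]
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt_allele))
    snvs = read_informative_snvs(str(snv_vcf))

    if config.workers > 1 and len(variants) > 1:
        tasks = [
            (v, str(bam_path), snvs, str(gtf_path), config) for v in variants
        ]
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            analyses = list(pool.map(_worker_task, tasks))
    else:
        analyses = [
            _analyze_from_files(v, str(bam_path), snvs, gene_models, config)
            for v in variants
        ]
    # Deterministic merge regardless of worker scheduling.
    analyses.sort(key=lambda a: (a.variant.chrom, a.variant.pos, a.variant.alt_allele))

    records, funnel = correct_and_collect(analyses, config)
    result = RunResult(
        config=config, analyses=analyses, records=records, funnel=funnel
    )
    result.summary_path = write_summary(records, outdir / prefix)
    _write_pair_outputs(result, bam_path, outdir, prefix, config)
    meta = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "funnel": funnel,
        "inputs": {
            "bam": str(bam_path),
            "splicing_vcf": str(splicing_vcf),
            "snv_vcf": str(snv_vcf),
            "gtf": str(gtf_path),
        },
    }
    with open(outdir / f"{prefix}_run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return result


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in ".-" else "_" for c in name)


def _unique_name(base: str, used: set[str]) -> str:
    name, k = base, 1
    while name in used:
        k += 1
        name = f"{base}.{k}"
    used.add(name)
    return name


def _write_pair_outputs(
    result: RunResult,
    bam_path: str | Path,
    outdir: Path,
    prefix: str,
    config: PipelineConfig,
) -> None:
    used_names: set[str] = set()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        header = bam.header
        for analysis in result.analyses:
            variant = analysis.variant
            reads: dict[str, pysam.AlignedSegment] = {}
            if analysis.pairs:
                for read in select_spanning_reads(bam, variant.chrom, variant.pos):
                    reads[read.query_name] = read
            site_by_pos = {
                p.snv.pos: p.snv for p in analysis.pairs if p.snv is not None
            }
            for pair in analysis.pairs:
                base = _unique_name(
                    f"{prefix}_{_safe(variant.variant_id)}_{_safe(pair.site_id)}",
                    used_names,
                )
                if pair.usage is not None:
                    pair.usage.to_csv(outdir / f"{base}_isoforms.tsv", sep="\t")
                if config.write_allele_bams:
                    write_allele_bams(
                        outdir / base, pair.partition, reads, header
                    )
                if config.write_phased_vcfs and pair.block is not None:
                    site_variants = [site_by_pos[p] for p in pair.block.positions]
                    emit_phased_vcf(
                        pair.block, site_variants, str(outdir / f"{base}_phased.vcf")
                    )


def write_allele_bams(
    base: Path,
    partition: AllelePartition,
    reads_by_id: dict[str, pysam.AlignedSegment],
    header,
) -> tuple[Path, Path]:
    """Write the partition's two read sets as indexed BAM files, verbatim."""
    paths = []
    for allele, ids in (("allele1", partition.ref_read_ids), ("allele2", partition.alt_read_ids)):
        path = Path(f"{base}_{allele}.bam")
        members = sorted(
            (reads_by_id[rid] for rid in ids if rid in reads_by_id),
            key=lambda r: (r.reference_start, r.query_name),
        )
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for read in members:
                out.write(read)
        pysam.index(str(path))
        paths.append(path)
    return paths[0], paths[1]
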