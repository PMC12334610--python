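"""Synthetic spliced-read scenarios with ground truth.

Emits everything the pipeline consumes — pre-aligned spliced long reads
(CIGARs constructed directly from each read's true isoform), the two
heterozygous variant lists, and the gene annotation — together with a
machine-readable truth table, all deterministic under a seed. The simulator
emulates the structure of allele-tagged nanopore data: two haplotypes
distinguished by informative SNVs, each expressing its own isoform mixture,
with i.i.d. substitution errors and a discretized-normal Phred quality
model. It does not model nanopore signal-level artifacts, indels, or
quality-correlated errors (an optional quality-coupled mode aside).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genemodels import Gene, GeneModels, Transcript
from .variants import AlleleInformativeSNV, SplicingVariant

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimScenario:
    """Full specification of one synthetic allele-specific splicing scenario.

    Coordinates in ``isoforms`` are 0-based half-open genomic exon intervals;
    variant/SNV positions are 1-based as in VCF. ``phase`` holds, per
    informative SNV, the allele (1 or 2) carrying the alternate base; the
    splicing variant's alternate base sits on ``variant_allele``. ``mixtures``
    maps each allele to its isoform-probability vector. The seed fully
    determines the emitted reads and files.
    """

    gene_symbol: str
    chrom: str
    strand: str
    isoforms: dict[str, tuple[tuple[int, int], ...]]
    annotated_isoforms: tuple[str, ...]
    variant_pos: int  # 1-based
    variant_ref: str
    variant_alt: str
    variant_ds: tuple[float, float, float, float]
    variant_dp: tuple[int, int, int, int]
    variant_allele: int
    snv_positions: tuple[int, ...]  # 1-based
    snv_phase: tuple[int, ...]
    mixtures: dict[int, dict[str, float]]
    n_reads: int = 100
    error_rate: float = 0.0
    qual_mean: float = 20.0
    qual_sd: float = 5.0
    qual_clip: tuple[int, int] = (2, 40)
    truncation_p: float = 0.0  # geometric 5' loss per exon-base, 0 disables
    quality_coupled_errors: bool = False
    read_id_prefix: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for allele, mix in self.mixtures.items():
            undefined = set(mix) - set(self.isoforms)
            if undefined:
                raise ValueError(
                    f"mixture for allele {allele} references undefined "
                    f"isoform(s) {sorted(undefined)}"
                )
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture for allele {allele} sums to {total}")
        if len(self.snv_phase) != len(self.snv_positions):
            raise ValueError("snv_phase and snv_positions length mismatch")

    @property
    def expected_significant(self) -> bool:
        """True when the two alleles are configured with different mixtures."""
        iso = sorted(self.isoforms)
        m1, m2 = self.mixtures[1], self.mixtures[2]
        return any(abs(m1.get(i, 0.0) - m2.get(i, 0.0)) > 1e-12 for i in iso)


@dataclass
class SimBundle:
    """In-memory result of one simulated scenario, writable to disk."""

    scenario: SimScenario
    header: pysam.AlignmentHeader
    reads: list[pysam.AlignedSegment]
    truth: pd.DataFrame  # read_id, true_allele, true_isoform
    splicing_variant: SplicingVariant
    informative_snvs: list[AlleleInformativeSNV]
    gene_models: GeneModels
    paths: dict[str, Path] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write BAM(+index), VCFs, GTF and truth TSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bam_path = outdir / "reads.bam"
        with pysam.AlignmentFile(str(bam_path), "wb", header=self.header) as bam:
            for read in sorted(
                self.reads, key=lambda r: (r.reference_start, r.query_name)
            ):
                bam.write(read)
        pysam.index(str(bam_path))
        sv = self.splicing_variant
        spliceai = "|".join(
            [
                sv.alt_allele,
                sv.gene_symbol,
                *(f"{d:.2f}" for d in (sv.ds_ag, sv.ds_al, sv.ds_dg, sv.ds_dl)),
                *(str(d) for d in sv.offsets),
            ]
        )
        splicing_vcf = outdir / "splicing_variants.vcf"
        _write_vcf(
            splicing_vcf,
            self.header,
            [(sv.chrom, sv.pos, sv.ref_allele, sv.alt_allele, f"SpliceAI={spliceai}")],
        )
        snv_vcf = outdir / "informative_snvs.vcf"
        _write_vcf(
            snv_vcf,
            self.header,
            [
                (s.chrom, s.pos, s.ref_allele, s.alt_allele, ".")
                for s in self.informative_snvs
            ],
        )
        gtf_path = outdir / "gene_models.gtf"
        self.gene_models.to_gtf(str(gtf_path))
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        self.paths = {
            "bam": bam_path,
            "splicing_vcf": splicing_vcf,
            "snv_vcf": snv_vcf,
            "gtf": gtf_path,
            "truth": truth_path,
        }
        return self.paths


def _write_vcf(path: Path, header: pysam.AlignmentHeader, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=SpliceAI,Number=.,Type=String,Description='
            '"SpliceAI sub-scores ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|'
            'DP_AG|DP_AL|DP_DG|DP_DL">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for sq in header.to_dict().get("SQ", []):
            fh.write(f"##contig=<ID={sq['SN']},length={sq['LN']}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSIM\n")
        for chrom, pos, ref, alt, info in sorted(rows, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t{info}\tGT\t0/1\n")


def simulate_scenario(
    scenario: SimScenario, outdir: str | Path | None = None
) -> SimBundle:
    """Generate a deterministic fixture bundle for one scenario.

    Reads are emitted pre-aligned: each read's CIGAR is constructed from its
    true isoform (M runs over exons, N runs over introns; retained introns
    are part of the M run), bases are copied from its haplotype sequence
    with i.i.d. substitution errors at the configured rate, and qualities
    come from the discretized-normal quality model.
    """
    rng = np.random.default_rng(scenario.seed)
    contig_len = max(e for iso in scenario.isoforms.values() for _, e in iso) + 1000
    reference = rng.choice(_BASES, size=contig_len)
    # Pin declared ref bases, then build the two haplotype sequences.
    het_sites = [(scenario.variant_pos, scenario.variant_ref, scenario.variant_alt,
                  scenario.variant_allele)]
    snv_alts = []
    for pos, phase in zip(scenario.snv_positions, scenario.snv_phase):
        ref_b = str(reference[pos - 1])
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        snv_alts.append((pos, ref_b, alt_b))
        het_sites.append((pos, ref_b, alt_b, phase))
    hap = {1: reference.copy(), 2: reference.copy()}
    for pos, ref_b, alt_b, allele in het_sites:
        hap[1][pos - 1] = ref_b
        hap[2][pos - 1] = ref_b
        hap[allele][pos - 1] = alt_b

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": scenario.chrom, "LN": int(contig_len)}],
        }
    )
    iso_names = sorted(scenario.isoforms)
    lo, hi = scenario.qual_clip
    reads: list[pysam.AlignedSegment] = []
    truth_rows = []
    for allele in (1, 2):
        mix = scenario.mixtures[allele]
        probs = np.array([mix.get(n, 0.0) for n in iso_names])
        chosen = rng.choice(len(iso_names), size=scenario.n_reads, p=probs)
        for i, iso_idx in enumerate(chosen):
            iso_name = iso_names[iso_idx]
            exons = list(scenario.isoforms[iso_name])
            if scenario.truncation_p > 0.0:
                exons = _truncate_5p(
                    exons, scenario.strand, scenario.truncation_p, rng
                )
            read_id = f"{scenario.read_id_prefix}a{allele}_{i:05d}"
            reads.append(
                _build_read(
                    read_id, scenario.chrom, exons, hap[allele], rng,
                    scenario, header, lo, hi,
                )
            )
            truth_rows.append((read_id, allele, iso_name))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "true_allele", "true_isoform"]
    )
    sv = SplicingVariant(
        chrom=scenario.chrom,
        pos=scenario.variant_pos,
        ref_allele=scenario.variant_ref,
        alt_allele=scenario.variant_alt,
        gene_symbol=scenario.gene_symbol,
        ds_ag=scenario.variant_ds[0],
        ds_al=scenario.variant_ds[1],
        ds_dg=scenario.variant_ds[2],
        ds_dl=scenario.variant_ds[3],
        dp_ag=scenario.variant_dp[0],
        dp_al=scenario.variant_dp[1],
        dp_dg=scenario.variant_dp[2],
        dp_dl=scenario.variant_dp[3],
    )
    snvs = [
        AlleleInformativeSNV(scenario.chrom, pos, ref_b, alt_b)
        for pos, ref_b, alt_b in snv_alts
    ]
    gene = Gene(scenario.gene_symbol, scenario.chrom, scenario.strand)
    for name in scenario.annotated_isoforms:
        gene.transcripts[name] = Transcript(
            name, scenario.chrom, scenario.strand, scenario.isoforms[name]
        )
    bundle = SimBundle(
        scenario=scenario,
        header=header,
        reads=reads,
        truth=truth,
        splicing_variant=sv,
        informative_snvs=snvs,
        gene_models=GeneModels([gene]),
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _truncate_5p(
    exons: list[tuple[int, int]], strand: str, p: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Geometric 5' loss emulating degraded/partial cDNA.

    At least 50 transcript bases are always kept so the read remains
    alignable.
    """
    total = sum(e - s for s, e in exons)
    loss = min(int(rng.geometric(p)) - 1, max(total - 50, 0))
    if loss <= 0:
        return exons
    # Walk exons from the transcript 5' end, dropping `loss` bases.
    ordered = list(reversed(exons)) if strand == "-" else list(exons)
    trimmed: list[tuple[int, int]] = []
    remaining = loss
    for s, e in ordered:
        length = e - s
        if remaining >= length:
            remaining -= length
            continue
        if strand == "-":
            trimmed.append((s, e - remaining))
        else:
            trimmed.append((s + remaining, e))
        remaining = 0
    if strand == "-":
        trimmed = list(reversed(trimmed))
    return trimmed


def _build_read(
    read_id: str,
    chrom: str,
    exons: list[tuple[int, int]],
    hap_seq: np.ndarray,
    rng: np.random.Generator,
    scenario: SimScenario,
    header: pysam.AlignmentHeader,
    qlo: int,
    qhi: int,
) -> pysam.AlignedSegment:
    # Merge touching exons, then alternate M/N cigar runs.
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    cigar = []
    seq_parts = []
    for i, (s, e) in enumerate(merged):
        if i > 0:
            cigar.append((3, s - merged[i - 1][1]))  # N
        cigar.append((0, e - s))  # M
        seq_parts.append(hap_seq[s:e])
    seq = np.concatenate(seq_parts)
    n = len(seq)
    quals = np.clip(
        np.rint(rng.normal(scenario.qual_mean, scenario.qual_sd, size=n)), qlo, qhi
    ).astype(np.uint8)
    if scenario.error_rate > 0.0:
        if scenario.quality_coupled_errors:
            err_p = 10.0 ** (-quals.astype(float) / 10.0)
            err_mask = rng.random(n) < err_p
        else:
            err_mask = rng.random(n) < scenario.error_rate
        idx = np.nonzero(err_mask)[0]
        for j in idx:
            others = [b for b in "ACGT" if b != seq[j]]
            seq[j] = others[rng.integers(3)]
    read = pysam.AlignedSegment(header)
    read.query_name = read_id
    read.query_sequence = "".join(seq.tolist())
    read.flag = 0
    read.reference_id = 0
    read.reference_start = merged[0][0]
    read.mapping_quality = 60
    read.cigartuples = cigar
    read.query_qualities = [int(q) for q in quals]
    return read


def write_merged(bundles: list[SimBundle], outdir: str | Path) -> dict[str, Path]:
    """Write several single-gene bundles as one multi-contig input set.

    Bundles must sit on distinct contigs and use distinct read-id prefixes.
    Emits one coordinate-sorted indexed BAM, combined splicing-variant and
    informative-SNV VCFs, a combined GTF, and a concatenated truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sq = []
    for b in bundles:
        sq.extend(b.header.to_dict()["SQ"])
    if len({entry["SN"] for entry in sq}) != len(sq):
        raise ValueError("merged bundles must use distinct contigs")
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": sq}
    )
    tid = {entry["SN"]: i for i, entry in enumerate(sq)}
    bam_path = outdir / "reads.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for b in bundles:
            chrom = b.header.to_dict()["SQ"][0]["SN"]
            for r in sorted(b.reads, key=lambda r: (r.reference_start, r.query_name)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.query_name
                a.query_sequence = r.query_sequence
                a.flag = r.flag
                a.reference_id = tid[chrom]
                a.reference_start = r.reference_start
                a.mapping_quality = r.mapping_quality
                a.cigartuples = r.cigartuples
                a.query_qualities = r.query_qualities
                out.write(a)
    pysam.index(str(bam_path))
    sv_rows, snv_rows = [], []
    genes = GeneModels()
    for b in bundles:
        sv = b.splicing_variant
        spliceai = "|".join(
            [
                sv.alt_allele,
                sv.gene_symbol,
                *(f"{d:.2f}" for d in (sv.ds_ag, sv.ds_al, sv.ds_dg, sv.ds_dl)),
                *(str(d) for d in sv.offsets),
            ]
        )
        sv_rows.append(
            (sv.chrom, sv.pos, sv.ref_allele, sv.alt_allele, f"SpliceAI={spliceai}")
        )
        snv_rows.extend(
            (s.chrom, s.pos, s.ref_allele, s.alt_allele, ".")
            for s in b.informative_snvs
        )
        for gene in b.gene_models:
            genes.add(gene)
    splicing_vcf = outdir / "splicing_variants.vcf"
    _write_vcf(splicing_vcf, header, sv_rows)
    snv_vcf = outdir / "informative_snvs.vcf"
    _write_vcf(snv_vcf, header, snv_rows)
    gtf_path = outdir / "gene_models.gtf"
    genes.to_gtf(str(gtf_path))
    truth_path = outdir / "truth.tsv"
    pd.concat([b.truth for b in bundles], ignore_index=True).to_csv(
        truth_path, sep="\t", index=False
    )
    return {
        "bam": bam_path,
        "splicing_vcf": splicing_vcf,
        "snv_vcf": snv_vcf,
        "gtf": gtf_path,
        "truth": truth_path,
    }


# ---------------------------------------------------------------------------
# Presets


def _twelve_exon_gene(
    start: int = 1000, exon_len: int = 120, intron_len: int = 300, n_exons: int = 12
) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return exons


def mcardle_like_preset(
    n_reads: int = 100, error_rate: float = 0.0, seed: int = 0
) -> SimScenario:
    """A McArdle-disease-like amplicon scenario: intronic acceptor variant.

    A 12-exon gene; the variant allele carries an A>C change 3 bp upstream
    of exon 7's acceptor and expresses a mixture of exon-7 skipping (22%),
    retention of the preceding intron (8%), retention of both flanking
    introns (2%) and canonical transcript (68%), versus a near-canonical
    wild-type allele. Intron-retention reads carry a base at the intronic
    variant position, so the variant can act as its own informative site, as
    can the two exonic SNVs.
    """
    exons = _twelve_exon_gene()
    canonical = tuple(exons)
    skip = tuple(e for i, e in enumerate(exons) if i != 6)
    # Retention merges the intron into a single M run by fusing exon pairs.
    ret = tuple(
        [(exons[5][0], exons[6][1])] + [e for i, e in enumerate(exons) if i not in (5, 6)]
    )
    dret = tuple(
        [(exons[5][0], exons[7][1])]
        + [e for i, e in enumerate(exons) if i not in (5, 6, 7)]
    )
    variant_pos0 = exons[6][0] - 3  # 3 bases into the intron from the acceptor
    snv1 = exons[1][0] + 60  # mid exon 2
    snv2 = exons[9][0] + 60  # mid exon 10
    return SimScenario(
        gene_symbol="GLYPH1",
        chrom="chrS",
        strand="+",
        isoforms={
            "canonical": canonical,
            "exon7_skip": skip,
            "intron6_retention": ret,
            "double_retention": dret,
        },
        annotated_isoforms=("canonical",),
        variant_pos=variant_pos0 + 1,
        variant_ref="A",
        variant_alt="C",
        variant_ds=(0.98, 0.98, 0.0, 0.0),
        variant_dp=(2, -3, 10, -10),
        variant_allele=2,
        snv_positions=(snv1 + 1, snv2 + 1),
        snv_phase=(2, 2),
        mixtures={
            1: {
                "canonical": 0.97,
                "exon7_skip": 0.01,
                "intron6_retention": 0.01,
                "double_retention": 0.01,
            },
            2: {
                "canonical": 0.68,
                "exon7_skip": 0.22,
                "intron6_retention": 0.08,
                "double_retention": 0.02,
            },
        },
        n_reads=n_reads,
        error_rate=error_rate,
        seed=seed,
    )


def null_twin(scenario: SimScenario) -> SimScenario:
    """The same scenario with identical isoform mixtures on both alleles."""
    return replace(
        scenario,
        mixtures={1: dict(scenario.mixtures[1]), 2: dict(scenario.mixtures[1])},
    )


def two_gene_fixture(seed: int = 0, n_reads: int = 40) -> tuple[SimScenario, SimScenario]:
    """An effect scenario plus a null scenario on a second gene/contig.

    Useful for end-to-end funnel tests: two variants enter, both reach the
    test stage, one is truly significant.
    """
    effect = replace(
        mcardle_like_preset(n_reads=n_reads, error_rate=0.0, seed=seed),
        read_id_prefix="g1_",
    )
    null = null_twin(mcardle_like_preset(n_reads=n_reads, error_rate=0.0, seed=seed + 1))
    rename = {name: f"g2_{name}" for name in null.isoforms}
    null = replace(
        null,
        gene_symbol="GLYPH2",
        chrom="chrT",
        read_id_prefix="g2_",
        isoforms={rename[n]: ex for n, ex in null.isoforms.items()},
        annotated_isoforms=tuple(rename[n] for n in null.annotated_isoforms),
        mixtures={
            a: {rename[n]: p for n, p in mix.items()}
            for a, mix in null.mixtures.items()
        },
    )
    return effect, null
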