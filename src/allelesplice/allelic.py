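"""Allele separation and read-backed phasing.

Gates candidate allele-informative SNVs by coverage and base quality,
partitions spanning reads into the two alleles by the base each read carries
at the SNV, and — when a read bundle covers several informative sites —
phases the sites into two haplotypes by minimum error correction (MEC) and
assigns each read to the nearer haplotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignments import BaseObservation
from .variants import AlleleInformativeSNV, SplicingVariant, as_informative_snv

UNASSIGNED = 0
HAP1 = 1
HAP2 = 2


@dataclass
class AllelePartition:
    """Disjoint assignment of reads to the two alleles at one site or block.

    ``ref_read_ids`` holds reads carrying the reference base (allele 1),
    ``alt_read_ids`` the alternate base (allele 2). Reads with any other
    base are counted in ``n_other_base`` and excluded — an erroneous call
    that is neither ref nor alt cannot be assigned and would otherwise risk
    mis-separation.
    """

    site_id: str
    ref_read_ids: set[str] = field(default_factory=set)
    alt_read_ids: set[str] = field(default_factory=set)
    n_other_base: int = 0
    n_low_quality: int = 0

    @property
    def ref_coverage(self) -> int:
        return len(self.ref_read_ids)

    @property
    def alt_coverage(self) -> int:
        return len(self.alt_read_ids)

    def allele_of(self, read_id: str) -> int:
        if read_id in self.ref_read_ids:
            return HAP1
        if read_id in self.alt_read_ids:
            return HAP2
        return UNASSIGNED


def gate_candidate_snv(
    observations: Sequence[BaseObservation],
    min_reads: int = 10,
    min_bq: int = 10,
) -> tuple[bool, list[BaseObservation]]:
    """Coverage/quality gate for one candidate informative SNV.

    Retains observations where the read contains a base (A/C/G/T — not a
    deletion or splice) with Phred quality >= ``min_bq``; the site passes
    when at least ``min_reads`` such observations exist, regardless of which
    allele they support.
    """
    retained = [
        o
        for o in observations
        if o.has_base and o.phred_q is not None and o.phred_q >= min_bq
    ]
    return len(retained) >= min_reads, retained


def partition_reads(
    observations: Sequence[BaseObservation],
    snv: AlleleInformativeSNV,
    n_low_quality: int = 0,
) -> AllelePartition:
    """Split gated observations into ref-allele and alt-allele read sets."""
    part = AllelePartition(site_id=snv.site_id, n_low_quality=n_low_quality)
    for o in observations:
        if o.base == snv.ref_allele:
            part.ref_read_ids.add(o.read_id)
        elif o.base == snv.alt_allele:
            part.alt_read_ids.add(o.read_id)
        else:
            part.n_other_base += 1
    return part


def self_informative_site(
    variant: SplicingVariant,
    observations: Sequence[BaseObservation],
    min_reads: int = 10,
    min_bq: int = 10,
) -> AllelePartition | None:
    """Use an SNV splicing variant as its own allele-informative site.

    Works for exonic variants, and for intronic variants whenever
    intron-retention reads carry a base at the variant position (spliced
    reads have no base there and do not count toward the gate). Returns
    None when the variant is an indel or the gate fails.
    """
    snv = as_informative_snv(variant)
    if snv is None:
        return None
    passed, retained = gate_candidate_snv(observations, min_reads, min_bq)
    if not passed:
        return None
    return partition_reads(retained, snv)


# ---------------------------------------------------------------------------
# MEC phasing


@dataclass
class PhasedBlock:
    """Two haplotypes over a set of informative sites, with read assignments.

    ``haplotype`` gives haplotype 1's allele (0=ref, 1=alt) at each site;
    haplotype 2 is the complement. ``read_assignment`` maps each read to
    HAP1/HAP2/UNASSIGNED; ``mec_cost`` is the total number of allele calls
    that disagree with the nearer haplotype, summed over all reads — the
    minimum-error-correction objective. Swapping haplotype labels leaves the
    cost and the unordered read bipartition unchanged.
    """

    positions: tuple[int, ...]  # 1-based site positions, ascending
    haplotype: tuple[int, ...]
    read_assignment: dict[str, int]
    mec_cost: int

    @property
    def block_id(self) -> str:
        return f"block:{self.positions[0]}-{self.positions[-1]}"

    def genotype_strings(self) -> list[str]:
        """Phased VCF genotypes per site: '0|1' where hap1 carries ref."""
        return ["0|1" if h == 0 else "1|0" for h in self.haplotype]


def _read_cost(calls: Sequence[int | None], hap: Sequence[int]) -> tuple[int, int]:
    """Mismatch counts of one read against a haplotype and its complement."""
    d1 = d2 = 0
    for c, h in zip(calls, hap):
        if c is None:
            continue
        if c != h:
            d1 += 1
        else:
            d2 += 1
    return d1, d2


def _total_cost(matrix: Mapping[str, Sequence[int | None]], hap: Sequence[int]) -> int:
    return sum(min(*_read_cost(calls, hap)) for calls in matrix.values())


def _exhaustive_mec(
    matrix: Mapping[str, Sequence[int | None]], n_sites: int
) -> tuple[tuple[int, ...], int]:
    """Minimum-cost haplotype over all 2^(S-1) label-fixed phasings."""
    best_hap: tuple[int, ...] | None = None
    best_cost = None
    for tail in itertools.product((0, 1), repeat=n_sites - 1):
        hap = (0, *tail)
        cost = _total_cost(matrix, hap)
        if best_cost is None or cost < best_cost:
            best_hap, best_cost = hap, cost
    assert best_hap is not None and best_cost is not None
    return best_hap, best_cost


def _refine(
    matrix: Mapping[str, Sequence[int | None]], hap: list[int], n_sites: int
) -> tuple[list[int], int]:
    """Hill-climb single-site flips until no flip lowers the MEC cost."""
    best_cost = _total_cost(matrix, hap)
    improved = True
    while improved:
        improved = False
        for s in range(n_sites):
            hap[s] ^= 1
            cost = _total_cost(matrix, hap)
            if cost < best_cost:
                best_cost = cost
                improved = True
            else:
                hap[s] ^= 1
    return hap, best_cost


def _greedy_mec(
    matrix: Mapping[str, Sequence[int | None]], n_sites: int
) -> tuple[tuple[int, ...], int]:
    """Multi-start greedy MEC with single-site flip refinement.

    One start extends sites in genomic order, each new site taking the
    allele minimizing the partial cost over the sites fixed so far; every
    distinct read row (missing calls filled with the greedy values) seeds
    a further start. Each start is hill-climbed by single-site flips; the
    best refined haplotype wins. Deterministic given the matrix.
    """
    greedy = [0]
    for s in range(1, n_sites):
        costs = []
        for a in (0, 1):
            trial = greedy + [a]
            sub = {rid: calls[: s + 1] for rid, calls in matrix.items()}
            costs.append(_total_cost(sub, trial))
        greedy.append(0 if costs[0] <= costs[1] else 1)

    starts: list[list[int]] = [list(greedy)]
    seen = {tuple(greedy)}
    for rid in sorted(matrix):
        calls = matrix[rid]
        candidate = [
            c if c is not None else greedy[s] for s, c in enumerate(calls)
        ]
        if candidate[0] == 1:  # canonical labelling: first site on hap1 = 0
            candidate = [1 - c for c in candidate]
        key = tuple(candidate)
        if key not in seen:
            seen.add(key)
            starts.append(candidate)

    best_hap: tuple[int, ...] | None = None
    best_cost: int | None = None
    for start in starts:
        hap, cost = _refine(matrix, list(start), n_sites)
        if best_cost is None or cost < best_cost:
            best_hap, best_cost = tuple(hap), cost
    assert best_hap is not None and best_cost is not None
    if best_hap[0] == 1:
        best_hap = tuple(1 - h for h in best_hap)
    return best_hap, best_cost


def phase_informative_sites(
    matrix: Mapping[str, Sequence[int | None]],
    positions: Sequence[int],
    s_max: int = 16,
    force_heuristic: bool = False,
) -> PhasedBlock:
    """Phase >= 2 informative sites into two haplotypes by MEC.

    ``matrix`` maps read id to its allele call per site (0=ref, 1=alt, None
    when the read does not cover the site), with sites ordered by genomic
    position. The search is exhaustive over the 2^(S-1) phasings with
    haplotype 1 fixed to ref at the first site while S <= ``s_max``, and
    greedy with local refinement beyond. Each read is then assigned to the
    haplotype nearer in Hamming distance over its covered sites; equidistant
    reads stay unassigned rather than inflating either allele.
    """
    n_sites = len(positions)
    if n_sites < 2:
        raise ValueError("phasing requires at least 2 sites; use partition_reads")
    for rid, calls in matrix.items():
        if len(calls) != n_sites:
            raise ValueError(f"read {rid}: {len(calls)} calls for {n_sites} sites")
        if all(c is None for c in calls):
            raise ValueError(f"read {rid} covers no site")
    if n_sites <= s_max and not force_heuristic:
        hap, cost = _exhaustive_mec(matrix, n_sites)
    else:
        hap, cost = _greedy_mec(matrix, n_sites)
    assignment = {}
    for rid, calls in matrix.items():
        d1, d2 = _read_cost(calls, hap)
        if d1 < d2:
            assignment[rid] = HAP1
        elif d2 < d1:
            assignment[rid] = HAP2
        else:
            assignment[rid] = UNASSIGNED
    return PhasedBlock(
        positions=tuple(positions),
        haplotype=hap,
        read_assignment=assignment,
        mec_cost=cost,
    )


def block_partition(block: PhasedBlock) -> AllelePartition:
    """View a phased block as an allele partition (hap1 = ref side)."""
    part = AllelePartition(site_id=block.block_id)
    for rid, a in block.read_assignment.items():
        if a == HAP1:
            part.ref_read_ids.add(rid)
        elif a == HAP2:
            part.alt_read_ids.add(rid)
    return part


def emit_phased_vcf(
    block: PhasedBlock,
    variants: Sequence[AlleleInformativeSNV],
    path: str,
    sample: str = "SAMPLE",
) -> None:
    """Write the block's sites as a phased VCF ('0|1'/'1|0' genotypes).

    ``variants`` must cover every site position of the block, in any order.
    """
    by_pos = {v.pos: v for v in variants}
    missing = [p for p in block.positions if p not in by_pos]
    if missing:
        raise ValueError(f"no input variant at phased site position(s) {missing}")
    gts = block.genotype_strings()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {by_pos[p].chrom for p in block.positions}
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for pos, gt in zip(block.positions, gts):
            v = by_pos[pos]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT\t{gt}\n"
            )
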