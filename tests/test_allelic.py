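import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from allelesplice.alignments import BaseObservation
from allelesplice.allelic import (
    HAP1,
    HAP2,
    UNASSIGNED,
    block_partition,
    emit_phased_vcf,
    gate_candidate_snv,
    partition_reads,
    phase_informative_sites,
    self_informative_site,
)
from allelesplice.variants import AlleleInformativeSNV, SplicingVariant
from conftest import CHROM

SNV = AlleleInformativeSNV(CHROM, 1000, "A", "G")


def obs(base, q=30, rid=None, _counter=[0]):
    _counter[0] += 1
    return BaseObservation(rid or f"r{_counter[0]}", base, q if base else None)


class TestGate:
    def test_pass_with_one_low_quality_dropped(self):
        observations = [obs("A") for _ in range(11)] + [obs("G", q=5)]
        passed, retained = gate_candidate_snv(observations)
        assert passed and len(retained) == 11

    def test_fail_below_min_reads(self):
        observations = [obs("A") for _ in range(9)]
        passed, retained = gate_candidate_snv(observations)
        assert not passed and len(retained) == 9

    def test_amplicon_bq_threshold(self):
        observations = [obs("A", q=12) for _ in range(12)]
        passed, retained = gate_candidate_snv(observations, min_bq=15)
        assert not passed and retained == []

    def test_absent_bases_do_not_count(self):
        observations = [obs(None) for _ in range(20)] + [obs("A") for _ in range(3)]
        passed, retained = gate_candidate_snv(observations, min_reads=10)
        assert not passed and len(retained) == 3

    def test_gate_counts_any_base_regardless_of_allele(self):
        # ref=A alt=G but reads showing T still count toward coverage
        observations = [obs("T") for _ in range(10)]
        passed, _ = gate_candidate_snv(observations)
        assert passed


class TestPartition:
    def test_counts_and_other_base(self):
        observations = [obs(b) for b in "AAGGGT"]
        part = partition_reads(observations, SNV)
        assert part.ref_coverage == 2
        assert part.alt_coverage == 3
        assert part.n_other_base == 1

    def test_all_ref_degenerate(self):
        observations = [obs("A") for _ in range(5)]
        part = partition_reads(observations, SNV)
        assert part.alt_coverage == 0 and part.ref_coverage == 5

    def test_swapped_alleles_mirror(self):
        observations = [obs(b, rid=f"x{i}") for i, b in enumerate("AAGGG")]
        part = partition_reads(observations, SNV)
        flipped = partition_reads(
            observations, AlleleInformativeSNV(CHROM, 1000, "G", "A")
        )
        assert part.ref_read_ids == flipped.alt_read_ids
        assert part.alt_read_ids == flipped.ref_read_ids

    @given(
        bases=st.lists(st.sampled_from("ACGT"), min_size=0, max_size=50),
    )
    @settings(deadline=None, max_examples=100)
    def test_partition_conservation(self, bases):
        observations = [
            BaseObservation(f"r{i}", b, 30) for i, b in enumerate(bases)
        ]
        part = partition_reads(observations, SNV)
        assert (
            part.ref_coverage + part.alt_coverage + part.n_other_base
            == len(observations)
        )
        assert not (part.ref_read_ids & part.alt_read_ids)


class TestSelfInformativeSite:
    variant = SplicingVariant(
        chrom=CHROM, pos=1000, ref_allele="A", alt_allele="G",
        gene_symbol="GENE1", ds_ag=0.9, ds_al=0.0, ds_dg=0.0, ds_dl=0.0,
        dp_ag=-2, dp_al=0, dp_dg=0, dp_dl=0,
    )

    def test_exonic_snv_partitions(self):
        observations = [obs(b) for b in "AAAAAGGGGG"]
        part = self_informative_site(self.variant, observations)
        assert part is not None
        assert part.ref_coverage == 5 and part.alt_coverage == 5

    def test_all_spliced_out_gives_absent(self):
        observations = [obs(None) for _ in range(30)]
        assert self_informative_site(self.variant, observations) is None

    def test_intron_retention_reads_only(self):
        # 12 retention reads carry a base; 30 spliced reads do not
        observations = [obs(None) for _ in range(30)] + [
            obs("A" if i < 6 else "G") for i in range(12)
        ]
        part = self_informative_site(self.variant, observations)
        assert part is not None
        assert part.ref_coverage + part.alt_coverage == 12

    def test_indel_variant_never_self_informative(self):
        import dataclasses

        indel = dataclasses.replace(self.variant, alt_allele="GT")
        observations = [obs(b) for b in "AAAAAGGGGG"]
        assert self_informative_site(indel, observations) is None


def random_matrix(rng, n_sites, n_reads):
    matrix = {}
    for i in range(n_reads):
        calls = [
            None if rng.random() < 0.2 else int(rng.integers(2))
            for _ in range(n_sites)
        ]
        if all(c is None for c in calls):
            calls[int(rng.integers(n_sites))] = int(rng.integers(2))
        matrix[f"r{i}"] = calls
    return matrix


class TestMECPhasing:
    def test_perfectly_consistent_reads(self):
        matrix = {"r1": [0, 0], "r2": [0, 0], "r3": [1, 1], "r4": [1, 1]}
        block = phase_informative_sites(matrix, [100, 200])
        assert block.mec_cost == 0
        assert block.haplotype in ((0, 0), (1, 1))
        assert {block.read_assignment[r] for r in ("r1", "r2")} == {HAP1}
        assert {block.read_assignment[r] for r in ("r3", "r4")} == {HAP2}

    def test_conflicted_read_unassigned_on_tie(self):
        matrix = {
            "r1": [0, 0], "r2": [0, 0], "r3": [1, 1], "r4": [1, 1], "r5": [0, 1],
        }
        block = phase_informative_sites(matrix, [100, 200])
        assert block.mec_cost == 1
        assert block.read_assignment["r5"] == UNASSIGNED

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            phase_informative_sites({"r1": [0]}, [100])

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng, 4, 20)
        block = phase_informative_sites(matrix, [1, 2, 3, 4])
        comp = tuple(1 - h for h in block.haplotype)
        cost_comp = sum(
            min(
                sum(1 for c, h in zip(calls, comp) if c is not None and c != h),
                sum(1 for c, h in zip(calls, block.haplotype) if c is not None and c != h),
            )
            for calls in matrix.values()
        )
        assert cost_comp == block.mec_cost

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        matrix = random_matrix(rng, 5, 25)
        block1 = phase_informative_sites(matrix, list(range(5)))
        reversed_matrix = dict(reversed(list(matrix.items())))
        block2 = phase_informative_sites(reversed_matrix, list(range(5)))
        assert block1.haplotype == block2.haplotype
        assert block1.read_assignment == block2.read_assignment

    def test_exhaustive_attains_oracle_minimum(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_sites = int(rng.integers(2, 7))
            matrix = random_matrix(rng, n_sites, int(rng.integers(2, 25)))
            block = phase_informative_sites(matrix, list(range(n_sites)))
            assert block.mec_cost == _oracles.exhaustive_mec_cost(matrix, n_sites)

    def test_heuristic_attains_oracle_minimum(self):
        rng = np.random.default_rng(5)
        n_hit = 0
        for _ in range(100):
            n_sites = int(rng.integers(2, 7))
            matrix = random_matrix(rng, n_sites, int(rng.integers(2, 25)))
            block = phase_informative_sites(
                matrix, list(range(n_sites)), force_heuristic=True
            )
            if block.mec_cost == _oracles.exhaustive_mec_cost(matrix, n_sites):
                n_hit += 1
        assert n_hit == 100


class TestBlockPartitionAndVCF:
    def test_block_partition_sides(self):
        matrix = {"r1": [0, 0], "r2": [1, 1]}
        block = phase_informative_sites(matrix, [100, 200])
        part = block_partition(block)
        assert part.ref_read_ids == {"r1"}
        assert part.alt_read_ids == {"r2"}

    def test_emit_phased_vcf_genotypes(self, tmp_path):
        matrix = {"r1": [0, 1], "r2": [0, 1], "r3": [1, 0], "r4": [1, 0]}
        block = phase_informative_sites(matrix, [100, 200])
        snvs = [
            AlleleInformativeSNV(CHROM, 100, "A", "G"),
            AlleleInformativeSNV(CHROM, 200, "C", "T"),
        ]
        path = tmp_path / "phased.vcf"
        emit_phased_vcf(block, snvs, str(path))
        lines = [
            l.split("\t") for l in path.read_text().splitlines()
            if not l.startswith("#")
        ]
        gts = {int(f[1]): f[9] for f in lines}
        # hap1 fixed to ref at first site -> "0|1" there, flipped at second
        assert gts == {100: "0|1", 200: "1|0"}

    def test_emit_phased_vcf_missing_site_errors(self, tmp_path):
        matrix = {"r1": [0, 1], "r2": [1, 0]}
        block = phase_informative_sites(matrix, [100, 200])
        with pytest.raises(ValueError):
            emit_phased_vcf(
                block,
                [AlleleInformativeSNV(CHROM, 100, "A", "G")],
                str(tmp_path / "p.vcf"),
            )
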