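import numpy as np
import pytest

import _oracles
from allelesplice.allelic import AllelePartition
from allelesplice.isoforms import (
    JunctionChain,
    collapse_isoforms,
    extract_junction_chain,
    match_annotation,
    quantify_per_allele,
)
from conftest import CHROM, build_read, random_cigar


class TestExtractJunctionChain:
    def test_single_intron(self, make_read):
        read = make_read(name="r", ref_start=999, cigar="100M200N100M")
        chain = extract_junction_chain(read)
        assert chain.introns == ((1099, 1299),)

    def test_no_intron(self, make_read):
        read = make_read(name="r", ref_start=0, cigar="300M")
        assert extract_junction_chain(read).is_single_exon

    def test_two_introns_cumulative_sums(self, make_read):
        read = make_read(name="r", ref_start=100, cigar="50M100N50M30N50M")
        chain = extract_junction_chain(read)
        assert chain.introns == ((150, 250), (300, 330))

    def test_short_skip_ignored(self, make_read):
        read = make_read(name="r", ref_start=0, cigar="50M10N50M100N50M")
        chain = extract_junction_chain(read, min_intron=20)
        assert chain.introns == ((110, 210),)

    def test_deletions_do_not_create_junctions(self, make_read):
        read = make_read(name="r", ref_start=0, cigar="50M30D50M")
        assert extract_junction_chain(read).is_single_exon

    def test_agrees_with_expansion_oracle(self, header):
        rng = np.random.default_rng(42)
        for _ in range(300):
            ref_start, cigar = random_cigar(rng)
            read = build_read(header, name="r", ref_start=ref_start, cigar=cigar)
            chain = extract_junction_chain(read, min_intron=20)
            assert list(chain.introns) == _oracles.introns_by_expansion(
                ref_start, cigar, 20
            )


def entries(*specs):
    """specs: (read_id, introns tuple, start, end)."""
    return [
        (rid, JunctionChain(CHROM, introns), start, end)
        for rid, introns, start, end in specs
    ]


CHAIN_X = ((1099, 1299),)
CHAIN_Y = ((1099, 1500),)


class TestCollapse:
    def test_support_threshold(self):
        reads = entries(
            *[(f"x{i}", CHAIN_X, 1000, 1400) for i in range(5)],
            *[(f"y{i}", CHAIN_Y, 1000, 1600) for i in range(3)],
        )
        groups = collapse_isoforms(reads, min_support=4)
        assert len(groups) == 1
        assert groups[0].chain.introns == CHAIN_X
        assert groups[0].n_support == 5

    def test_both_at_threshold(self):
        reads = entries(
            *[(f"x{i}", CHAIN_X, 1000, 1400) for i in range(4)],
            *[(f"y{i}", CHAIN_Y, 1000, 1600) for i in range(4)],
        )
        assert len(collapse_isoforms(reads, min_support=4)) == 2

    def test_no_qualifying_groups(self):
        reads = entries(("x1", CHAIN_X, 1000, 1400))
        assert collapse_isoforms(reads, min_support=4) == []

    def test_read_order_invariance(self):
        reads = entries(
            *[(f"x{i}", CHAIN_X, 1000 + i, 1400 + i) for i in range(6)],
            *[(f"y{i}", CHAIN_Y, 1000 + i, 1600 + i) for i in range(5)],
            *[(f"m{i}", (), 2000 + i, 2500 + i) for i in range(4)],
        )
        forward = collapse_isoforms(reads, min_support=4)
        backward = collapse_isoforms(list(reversed(reads)), min_support=4)
        assert forward == backward

    def test_representative_ends_are_medians(self):
        reads = entries(
            ("a", CHAIN_X, 1000, 1400),
            ("b", CHAIN_X, 1010, 1410),
            ("c", CHAIN_X, 1020, 1420),
            ("d", CHAIN_X, 1030, 1480),
        )
        (group,) = collapse_isoforms(reads, min_support=4)
        assert group.rep_start == 1015
        assert group.rep_end == 1415

    def test_single_exon_reciprocal_overlap_clustering(self):
        near = [(f"m{i}", (), 1000 + i, 2000 + i) for i in range(4)]
        far = [(f"f{i}", (), 5000 + i, 6000 + i) for i in range(4)]
        groups = collapse_isoforms(entries(*near, *far), min_support=4)
        assert len(groups) == 2
        assert {g.rep_start for g in groups} == {1001, 5001}

    def test_each_read_in_at_most_one_group(self):
        reads = entries(
            *[(f"x{i}", CHAIN_X, 1000, 1400) for i in range(5)],
            *[(f"y{i}", CHAIN_Y, 1000, 1600) for i in range(5)],
            *[(f"m{i}", (), 1000, 1400) for i in range(5)],
        )
        groups = collapse_isoforms(reads, min_support=4)
        all_ids = [rid for g in groups for rid in g.read_ids]
        assert len(all_ids) == len(set(all_ids))


class TestMatchAnnotation:
    def test_exact_chain_match(self, small_gene_models):
        gene = small_gene_models["GENE1"]
        reads = entries(
            *[(f"r{i}", ((1200, 1500), (1700, 2000)), 1000, 2200) for i in range(4)]
        )
        groups = match_annotation(collapse_isoforms(reads), gene)
        assert groups[0].label == "TX1"

    def test_skipping_chain_match(self, small_gene_models):
        gene = small_gene_models["GENE1"]
        reads = entries(*[(f"r{i}", ((1200, 2000),), 1000, 2200) for i in range(4)])
        groups = match_annotation(collapse_isoforms(reads), gene)
        assert groups[0].label == "TX2"

    def test_novel_chain_gets_ordinal(self, small_gene_models):
        gene = small_gene_models["GENE1"]
        reads = entries(
            *[(f"r{i}", ((1200, 1500),), 1000, 2200) for i in range(4)],
            *[(f"s{i}", ((1250, 1500), (1700, 2000)), 1000, 2200) for i in range(4)],
        )
        groups = match_annotation(collapse_isoforms(reads), gene)
        assert sorted(g.label for g in groups) == ["novel-1", "novel-2"]
        again = match_annotation(collapse_isoforms(reads), gene)
        assert [g.label for g in groups] == [g.label for g in again]

    def test_no_gene_all_novel(self):
        reads = entries(*[(f"r{i}", CHAIN_X, 1000, 1400) for i in range(4)])
        groups = match_annotation(collapse_isoforms(reads), None)
        assert groups[0].label == "novel-1"

    def test_junction_fuzz_window(self, small_gene_models):
        gene = small_gene_models["GENE1"]
        reads = entries(
            *[(f"r{i}", ((1202, 1500), (1700, 1999)), 1000, 2200) for i in range(4)]
        )
        exact = match_annotation(collapse_isoforms(reads), gene, fuzz=0)
        fuzzy = match_annotation(collapse_isoforms(reads), gene, fuzz=3)
        assert exact[0].label == "novel-1"
        assert fuzzy[0].label == "TX1"


class TestQuantify:
    def make_partition(self):
        return AllelePartition(
            site_id="s",
            ref_read_ids={f"x{i}" for i in range(8)} | {"y0", "y1"},
            alt_read_ids={f"y{i}" for i in range(2, 12)},
        )

    def test_usage_fractions(self):
        reads = entries(
            *[(f"x{i}", CHAIN_X, 1000, 1400) for i in range(8)],
            *[(f"y{i}", CHAIN_Y, 1000, 1600) for i in range(12)],
        )
        groups = match_annotation(collapse_isoforms(reads), None)
        table = quantify_per_allele(groups, self.make_partition())
        x_label = [g.label for g in groups if g.chain.introns == CHAIN_X][0]
        y_label = [g.label for g in groups if g.chain.introns == CHAIN_Y][0]
        assert table.loc[x_label, "count_allele1"] == 8
        assert table.loc[y_label, "count_allele1"] == 2
        assert table.loc[x_label, "usage_allele1"] == pytest.approx(0.8)
        assert table.loc[y_label, "usage_allele2"] == pytest.approx(1.0)
        assert table["usage_allele1"].sum() == pytest.approx(1.0)
        assert table["usage_allele2"].sum() == pytest.approx(1.0)

    def test_total_conservation(self):
        reads = entries(
            *[(f"x{i}", CHAIN_X, 1000, 1400) for i in range(8)],
            *[(f"y{i}", CHAIN_Y, 1000, 1600) for i in range(12)],
            ("unpartitioned", CHAIN_X, 1000, 1400),
        )
        part = self.make_partition()
        groups = match_annotation(collapse_isoforms(reads), None)
        table = quantify_per_allele(groups, part)
        n_assigned = sum(
            1
            for g in groups
            for rid in g.read_ids
            if rid in part.ref_read_ids | part.alt_read_ids
        )
        assert int(table[["count_allele1", "count_allele2"]].sum().sum()) == n_assigned
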