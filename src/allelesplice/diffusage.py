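"""Per-variant differential isoform-usage testing between alleles.

For each isoform the two alleles' counts form a 2x2 table (this isoform vs
all others, allele 1 vs allele 2) tested with Fisher's exact test
(two-sided, point-probability method). Each variant-site pair is summarized
by its minimum p-value, and a Bonferroni correction over the number of
unique splicing variants that reached the test stage controls the
family-wise error at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .allelic import AllelePartition

SUMMARY_SUFFIX = "_minpvalue005_spvar_corrected.tsv"
SUMMARY_COLUMNS = [
    "splicing_variant",
    "allele_informative_site",
    "ref_coverage",
    "alt_coverage",
    "min_p",
    "corrected_p",
    "significant",
    "haplotype_info",
]


class PairSkipped(Exception):
    """A variant-site pair cannot be tested; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class DiffUsageRecord:
    """One summary row: a splicing variant tested at one informative site."""

    variant_id: str
    site_id: str
    ref_coverage: int
    alt_coverage: int
    isoform_p: dict[str, float]
    min_p: float
    corrected_p: float | None = None
    significant: bool | None = None
    haplotype_info: str = "."


def per_isoform_exact_test(counts: pd.DataFrame) -> dict[str, float]:
    """Two-sided exact p-value per isoform from a per-allele count table.

    ``counts`` must carry ``count_allele1``/``count_allele2`` columns indexed
    by isoform label (the output of ``quantify_per_allele``). For isoform i
    the 2x2 table is [[count(i, a1), rest(a1)], [count(i, a2), rest(a2)]];
    the two-sided p sums hypergeometric point probabilities <= that of the
    observed table at fixed margins. Isoforms with zero counts in both
    alleles are uninformative and excluded.
    """
    c1 = counts["count_allele1"]
    c2 = counts["count_allele2"]
    t1, t2 = int(c1.sum()), int(c2.sum())
    if t1 == 0:
        raise PairSkipped("no_reads_allele1")
    if t2 == 0:
        raise PairSkipped("no_reads_allele2")
    pvals: dict[str, float] = {}
    for isoform in counts.index:
        a, b = int(c1[isoform]), int(c2[isoform])
        if a == 0 and b == 0:
            continue
        table = [[a, t1 - a], [b, t2 - b]]
        pvals[isoform] = float(fisher_exact(table, alternative="two-sided")[1])
    if not pvals:
        raise PairSkipped("no_informative_isoform")
    return pvals


def summarize_pair(
    variant_id: str,
    site_id: str,
    isoform_p: dict[str, float],
    partition: AllelePartition,
    haplotype_info: str = ".",
) -> DiffUsageRecord:
    """Collapse a pair's per-isoform p-values to the minimum (uncorrected)."""
    if not isoform_p:
        raise PairSkipped("no_pvalues")
    return DiffUsageRecord(
        variant_id=variant_id,
        site_id=site_id,
        ref_coverage=partition.ref_coverage,
        alt_coverage=partition.alt_coverage,
        isoform_p=dict(isoform_p),
        min_p=min(isoform_p.values()),
        haplotype_info=haplotype_info,
    )


def bonferroni_correct(
    records: Sequence[DiffUsageRecord],
    n_variants_tested: int,
    alpha: float = 0.05,
) -> list[DiffUsageRecord]:
    """Bonferroni-correct each pair's minimum p across tested variants.

    ``n_variants_tested`` is the number of unique splicing variants that
    reached the test stage; every pair of a variant inherits the same
    denominator. corrected_p = min(1, min_p * n); a pair is flagged when
    corrected_p < alpha.
    """
    if n_variants_tested < 1:
        raise ValueError("n_variants_tested must be >= 1")
    out = []
    for rec in records:
        corrected = min(1.0, rec.min_p * n_variants_tested)
        out.append(
            replace(rec, corrected_p=corrected, significant=corrected < alpha)
        )
    return out


def unique_variants_tested(records: Sequence[DiffUsageRecord]) -> int:
    return len({r.variant_id for r in records})


def significant_variants(records: Sequence[DiffUsageRecord]) -> set[str]:
    """Variants with at least one pair flagged significant."""
    return {r.variant_id for r in records if r.significant}


def records_to_frame(records: Sequence[DiffUsageRecord]) -> pd.DataFrame:
    rows = [
        {
            "splicing_variant": r.variant_id,
            "allele_informative_site": r.site_id,
            "ref_coverage": r.ref_coverage,
            "alt_coverage": r.alt_coverage,
            "min_p": r.min_p,
            "corrected_p": r.corrected_p,
            "significant": r.significant,
            "haplotype_info": r.haplotype_info,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df.sort_values(
        ["splicing_variant", "allele_informative_site"], kind="stable"
    ).reset_index(drop=True)


def write_summary(records: Sequence[DiffUsageRecord], prefix: str | Path) -> Path:
    """Write the per-pair summary TSV (``<prefix>_minpvalue005_spvar_corrected.tsv``)."""
    path = Path(str(prefix) + SUMMARY_SUFFIX)
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
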