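"""Light gene-model containers backed by GTF annotation.

All coordinates are 0-based half-open internally; GTF's 1-based inclusive
coordinates are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils


@dataclass(frozen=True)
class Transcript:
    """One transcript model: an ordered, disjoint set of exons on one strand."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty exon ({s}, {e}) in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons (the junction chain)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class Gene:
    gene_symbol: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class GeneModels:
    """Collection of genes indexed by symbol, loadable from an Ensembl-dialect GTF."""

    def __init__(self, genes: Iterable[Gene] = ()) -> None:
        self._genes: dict[str, Gene] = {g.gene_symbol: g for g in genes}

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self._genes

    def __getitem__(self, gene_symbol: str) -> Gene:
        return self._genes[gene_symbol]

    def __iter__(self) -> Iterator[Gene]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def get(self, gene_symbol: str) -> Gene | None:
        return self._genes.get(gene_symbol)

    def add(self, gene: Gene) -> None:
        self._genes[gene.gene_symbol] = gene

    def overlapping(self, chrom: str, pos: int) -> list[Gene]:
        """Genes whose span contains 0-based position ``pos``."""
        return [
            g
            for g in self._genes.values()
            if g.chrom == chrom and g.start <= pos < g.end
        ]

    @classmethod
    def from_gtf(cls, gtf_path: str) -> "GeneModels":
        """Load gene models from a GTF file (attributes gene_name/transcript_id)."""
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
        genes: dict[str, Gene] = {}
        exons_by_tx: dict[str, list[tuple[int, int]]] = {}
        tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
        for feat in db.features_of_type("exon"):
            gene_name = _first_attr(feat, "gene_name", "gene_id")
            tx_id = _first_attr(feat, "transcript_id")
            if gene_name is None or tx_id is None:
                continue
            # GTF start is 1-based inclusive -> 0-based half-open
            exons_by_tx.setdefault(tx_id, []).append((feat.start - 1, feat.end))
            tx_meta[tx_id] = (gene_name, feat.seqid, feat.strand or ".")
        for tx_id, exons in exons_by_tx.items():
            gene_name, chrom, strand = tx_meta[tx_id]
            gene = genes.setdefault(gene_name, Gene(gene_name, chrom, strand))
            gene.transcripts[tx_id] = Transcript(tx_id, chrom, strand, tuple(exons))
        return cls(genes.values())

    def to_gtf(self, path: str, source: str = "allelesplice") -> None:
        """Write the models back out as GTF (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            for gene in self._genes.values():
                attrs = f'gene_id "{gene.gene_symbol}"; gene_name "{gene.gene_symbol}";'
                fh.write(
                    f"{gene.chrom}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for tx in gene.transcripts.values():
                    tx_attrs = attrs + f' transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{gene.chrom}\t{source}\ttranscript\t{tx.start + 1}\t{tx.end}"
                        f"\t.\t{gene.strand}\t.\t{tx_attrs}\n"
                    )
                    for s, e in tx.exons:
                        fh.write(
                            f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t.\t{tx_attrs}\n"
                        )


def _first_attr(feat, *keys: str) -> str | None:
    for key in keys:
        if key in feat.attributes:
            vals = feat.attributes[key]
            if vals:
                return vals[0]
    return None
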