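"""Transcript models and GTF input/output.

Coordinates are 1-based inclusive in GTF files (the standard) and 0-based
half-open everywhere inside the package.  The conversion lives only here:
:func:`gtf_to_internal` and :func:`internal_to_gtf`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Gene",
    "Annotation",
    "gtf_to_internal",
    "internal_to_gtf",
    "read_gtf",
    "write_gtf",
]

Exon = tuple[int, int]  # (start, end), 0-based half-open


def gtf_to_internal(start: int, end: int) -> Exon:
    """GTF 1-based inclusive -> 0-based half-open."""
    return (start - 1, end)


def internal_to_gtf(exon: Exon) -> tuple[int, int]:
    """0-based half-open -> GTF 1-based inclusive."""
    return (exon[0] + 1, exon[1])


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    transcripts: dict[str, list[Exon]] = field(default_factory=dict)

    def add_transcript(self, tx_id: str, exons: Iterable[Exon]) -> None:
        exons = sorted((int(s), int(e)) for s, e in exons)
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"{tx_id}: empty/inverted exon ({s},{e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{tx_id}: overlapping exons")
        self.transcripts[tx_id] = exons

    def exons_in_transcription_order(self, tx_id: str) -> list[Exon]:
        exons = self.transcripts[tx_id]
        return exons if self.strand == "+" else exons[::-1]


@dataclass
class Annotation:
    """A set of gene models with a transcript -> gene map."""

    genes: dict[str, Gene] = field(default_factory=dict)

    @property
    def tx_to_gene(self) -> dict[str, str]:
        return {
            tx: g.gene_id for g in self.genes.values() for tx in g.transcripts
        }

    def transcripts(self) -> list[str]:
        return [tx for g in self.genes.values() for tx in g.transcripts]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> Annotation:
    """Parse exon records of a GTF file into an :class:`Annotation`.

    Only ``exon`` features are used; ``gene_id`` and ``transcript_id``
    attributes are required.
    """
    per_tx: dict[str, list[Exon]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            d = dict(_ATTR_RE.findall(attrs))
            gene_id, tx_id = d.get("gene_id"), d.get("transcript_id")
            if gene_id is None or tx_id is None:
                raise ValueError(f"exon record lacks gene_id/transcript_id: {line!r}")
            per_tx.setdefault(tx_id, []).append(gtf_to_internal(int(start), int(end)))
            tx_meta[tx_id] = (gene_id, chrom, strand)
    ann = Annotation()
    for tx_id, exons in per_tx.items():
        gene_id, chrom, strand = tx_meta[tx_id]
        gene = ann.genes.setdefault(gene_id, Gene(gene_id, chrom, strand))
        gene.add_transcript(tx_id, exons)
    return ann


def write_gtf(annotation: Annotation, path) -> None:
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            g_start = min(s for ex in gene.transcripts.values() for s, _ in ex)
            g_end = max(e for ex in gene.transcripts.values() for _, e in ex)
            gs, ge = internal_to_gtf((g_start, g_end))
            fh.write(
                f"{gene.chrom}\tribolens\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\t"
                f'gene_id "{gene.gene_id}";\n'
            )
            for tx_id, exons in gene.transcripts.items():
                ts, te = internal_to_gtf((exons[0][0], exons[-1][1]))
                fh.write(
                    f"{gene.chrom}\tribolens\ttranscript\t{ts}\t{te}\t.\t{gene.strand}\t.\t"
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";\n'
                )
                for exon in exons:
                    es, ee = internal_to_gtf(exon)
                    fh.write(
                        f"{gene.chrom}\tribolens\texon\t{es}\t{ee}\t.\t{gene.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";\n'
                    )
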