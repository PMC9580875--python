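"""circRNA structure resolution, sequence assembly, and coordinate mapping.

A circRNA supplied as a genomic span is resolved into exon blocks when it
overlaps a gene on the same strand; antisense and intergenic circRNAs (and
user-supplied feature sets) are taken as-is.  The assembled transcript is a
linear 5'->3' RNA string; ``CoordinateMap`` converts transcript windows back
to genomic intervals, which is the inverse of the assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import GenomeAccessor, GenomicInterval, GeneModel

logger = logging.getLogger(__name__)

CIRC_CLASSES = ("sense_overlapping", "antisense", "intergenic", "user_features")

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between transcript positions and genomic positions.

    Blocks are sorted by genomic start.  Transcript position 0 is the 5'-most
    transcript nucleotide: the genomic leftmost base of the first block on the
    ``+`` strand, the genomic rightmost base of the last block on ``-``.

    ``wrap`` > 0 models a circular transcript whose first ``wrap`` nucleotides
    are repeated after the 3' end, so that windows spanning the backsplice
    junction stay addressable; wrapped positions map back modulo the length.
    """

    blocks: tuple[GenomicInterval, ...]
    strand: str
    wrap: int = 0

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError("blocks overlap or are unsorted")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    def genome_position(self, t: int) -> int:
        """Genomic coordinate of the single transcript position *t*."""
        n = self.length
        if not 0 <= t < n + self.wrap:
            raise ValueError(f"transcript position {t} out of range [0, {n + self.wrap})")
        t %= n
        f = t if self.strand == "+" else n - 1 - t
        for b in self.blocks:
            if f < len(b):
                return b.start + f
            f -= len(b)
        raise AssertionError("unreachable")

    def _map_forward_range(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Map a forward-offset range (strand-independent) to genomic pieces."""
        out = []
        off = 0
        for b in self.blocks:
            b_lo, b_hi = off, off + len(b)
            s, e = max(lo, b_lo), min(hi, b_hi)
            if s < e:
                out.append((b.start + (s - b_lo), b.start + (e - b_lo)))
            off = b_hi
        return out

    def map_to_genome(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Genomic intervals covered by the transcript window [t_start, t_end).

        Returns one interval per contiguous genomic run, sorted by genomic
        start; total length equals the window length.  Windows reaching into
        the wrapped region are split at the junction and mapped modulo the
        transcript length.
        """
        n = self.length
        if not (0 <= t_start < t_end <= n + self.wrap):
            raise ValueError(
                f"window [{t_start}, {t_end}) out of transcript range [0, {n + self.wrap}]"
            )
        segments = [(t_start, min(t_end, n))]
        if t_end > n:
            segments.append((0, t_end - n))
        pieces: list[tuple[int, int]] = []
        for s, e in segments:
            if self.strand == "+":
                pieces.extend(self._map_forward_range(s, e))
            else:
                pieces.extend(self._map_forward_range(n - e, n - s))
        pieces.sort()
        merged: list[tuple[int, int]] = []
        for s, e in pieces:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return [
            GenomicInterval(self.chrom, s, e, strand=self.strand) for s, e in merged
        ]


@dataclass(frozen=True)
class CircStructure:
    """A resolved circRNA: block list, class, transcript sequence and map."""

    name: str
    chrom: str
    strand: str
    circ_class: str
    blocks: tuple[GenomicInterval, ...]
    sequence: str
    cmap: CoordinateMap
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.circ_class not in CIRC_CLASSES:
            raise ValueError(f"unknown circRNA class {self.circ_class!r}")

    @property
    def length(self) -> int:
        return self.cmap.length


def classify_circ(circ: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Classify a circRNA span against the gene annotation.

    ``sense_overlapping`` if it shares >= 1 bp with a gene on the same strand,
    else ``antisense`` for an opposite-strand overlap, else ``intergenic``.
    """
    sense = antisense = False
    for gene in genes:
        if gene.chrom != circ.chrom:
            continue
        if circ.overlap_bp(gene.span) > 0:
            if gene.strand == circ.strand:
                sense = True
            else:
                antisense = True
    if sense:
        return "sense_overlapping"
    if antisense:
        return "antisense"
    return "intergenic"


def _donor_gene(circ: GenomicInterval, genes: Sequence[GeneModel]) -> GeneModel:
    """Same-strand overlapping gene with the largest bp overlap (ties: gene_id)."""
    candidates = [
        g
        for g in genes
        if g.chrom == circ.chrom
        and g.strand == circ.strand
        and circ.overlap_bp(g.span) > 0
    ]
    return min(candidates, key=lambda g: (-circ.overlap_bp(g.span), g.gene_id))


def split_to_blocks(
    circ: GenomicInterval, genes: Sequence[GeneModel], circ_class: str
) -> tuple[GenomicInterval, ...]:
    """Resolve a circRNA span into blocks according to its class.

    Sense-overlapping circRNAs keep the intersection of their span with the
    exons of the donor gene, clipped to the span; antisense and intergenic
    circRNAs become a single block.  A sense-overlapping circRNA lying
    entirely within an intron falls back to a single block with a warning.
    """
    if circ_class != "sense_overlapping":
        return (GenomicInterval(circ.chrom, circ.start, circ.end,
                                name=circ.name, strand=circ.strand),)
    gene = _donor_gene(circ, genes)
    blocks = []
    for exon in gene.exons:
        s, e = max(circ.start, exon.start), min(circ.end, exon.end)
        if s < e:
            blocks.append(
                GenomicInterval(circ.chrom, s, e, name=circ.name, strand=circ.strand)
            )
    if not blocks:
        logger.warning(
            "circRNA %s overlaps gene %s but no exon; treated as a single block",
            circ.name, gene.gene_id,
        )
        return (GenomicInterval(circ.chrom, circ.start, circ.end,
                                name=circ.name, strand=circ.strand),)
    return tuple(blocks)


def accept_user_features(
    features: Sequence[GenomicInterval],
) -> dict[str, tuple[GenomicInterval, ...]]:
    """Group user-supplied feature intervals by circRNA name, unmodified.

    Features of one circRNA must share chromosome and strand and must not
    overlap each other; they are sorted by genomic start.
    """
    grouped: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for iv in features:
        if iv.name not in grouped:
            order.append(iv.name)
        grouped.setdefault(iv.name, []).append(iv)
    out: dict[str, tuple[GenomicInterval, ...]] = {}
    for name in order:
        ivs = sorted(grouped[name], key=lambda iv: iv.start)
        chroms = {iv.chrom for iv in ivs}
        strands = {iv.strand for iv in ivs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"features of circRNA {name!r} span multiple chromosomes/strands"
            )
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(f"features of circRNA {name!r} overlap each other")
        out[name] = tuple(ivs)
    return out


def assemble_sequence(
    blocks: Sequence[GenomicInterval],
    strand: str,
    genome: GenomeAccessor,
    wrap: int = 0,
) -> tuple[str, CoordinateMap]:
    """Assemble the 5'->3' RNA transcript of a block list and its map.

    ``+`` strand: left-to-right concatenation of block sequences; ``-``:
    reverse complement of that concatenation.  DNA is transcribed to RNA.
    ``wrap`` appends the first *wrap* transcript nucleotides after the 3' end
    to expose backsplice-junction-spanning windows.
    """
    chrom = blocks[0].chrom
    dna = "".join(genome.fetch(chrom, b.start, b.end) for b in blocks)
    if strand == "-":
        dna = reverse_complement_dna(dna)
    rna = dna_to_rna(dna)
    wrap = min(wrap, len(rna))
    cmap = CoordinateMap(blocks=tuple(blocks), strand=strand, wrap=wrap)
    return rna + rna[:wrap], cmap


def build_structures(
    circs: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    genome: GenomeAccessor,
    mode: str = "full_sequence",
    wrap: int = 0,
) -> dict[str, CircStructure]:
    """Resolve every input circRNA into a :class:`CircStructure`.

    ``full_sequence`` mode classifies each span against the annotation and
    performs exon splitting; ``features`` mode treats the input rows as the
    final block composition (one circRNA per BED name, multiple rows allowed).
    """
    structures: dict[str, CircStructure] = {}
    if mode == "features":
        for name, blocks in accept_user_features(circs).items():
            strand = blocks[0].strand
            seq, cmap = assemble_sequence(blocks, strand, genome, wrap=wrap)
            span = GenomicInterval(
                blocks[0].chrom, blocks[0].start, blocks[-1].end,
                name=name, strand=strand,
            )
            structures[name] = CircStructure(
                name=name, chrom=blocks[0].chrom, strand=strand,
                circ_class="user_features", blocks=blocks,
                sequence=seq, cmap=cmap, span=span,
            )
        return structures
    if mode != "full_sequence":
        raise ValueError(f"unknown mode {mode!r}")
    for circ in circs:
        circ_class = classify_circ(circ, genes)
        blocks = split_to_blocks(circ, genes, circ_class)
        seq, cmap = assemble_sequence(blocks, circ.strand, genome, wrap=wrap)
        structures[circ.name] = CircStructure(
            name=circ.name, chrom=circ.chrom, strand=circ.strand,
            circ_class=circ_class, blocks=blocks,
            sequence=seq, cmap=cmap, span=circ,
        )
    return structures
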