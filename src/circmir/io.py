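"""Readers and writers for the genomic file formats touched by the pipeline.

All coordinates are kept in the BED convention internally: 0-based start,
exclusive end.  GTF input (1-based, inclusive) is converted on read.  DNA is
uppercased on read; miRNA sequences are stored as RNA (T converted to U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

if TYPE_CHECKING:  # pragma: no cover
    from .merge import Interaction

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")

#: Output table header, fixed order.
RESULT_COLUMNS = [
    "Chrom",
    "Start",
    "End",
    "miRNA Name",
    "Circ Name",
    "Strand",
    "Seed Category",
    "ID",
    "Software Matched",
    "Validated",
    "AGO",
    "circBase ID",
]

RNA_ALPHABET = set("ACGUN")


class ParseError(ValueError):
    """Malformed input file content."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    The universal coordinate currency of the pipeline: circRNA spans, exon
    blocks, predicted-site footprints and annotation records are all
    ``GenomicInterval`` instances.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene as an ordered set of merged exon blocks on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end,
            name=self.gene_id, strand=self.strand,
        )


@dataclass(frozen=True, slots=True)
class MiRNA:
    """A mature miRNA: name plus RNA sequence written 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"miRNA {self.name!r} has an empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.name!r} contains non-RNA characters {sorted(bad)}"
            )


def _split_fields(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.rstrip("\n").split("\t")]
    return line.split()


def read_bed(path: str | Path, *, autoname: bool = True) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a list of intervals, in file order.

    Missing name columns are auto-filled with ``circ_<row#>`` (data rows
    counted from 1) when *autoname* is true, otherwise left empty.  A missing
    or ``.`` strand defaults to ``+`` with a logged warning.  Comment,
    ``track`` and ``browser`` lines are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    row = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            row += 1
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            if not name and autoname:
                name = f"circ_{row}"
            if len(fields) > 5 and fields[5] in VALID_STRANDS:
                strand = fields[5]
            else:
                strand = "+"
                logger.warning("%s:%d: missing strand, assuming '+'", path, lineno)
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, strand=strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def ensure_unique_names(intervals: Sequence[GenomicInterval], what: str = "record") -> None:
    """Raise if two intervals share a name (names are join keys downstream)."""
    seen: dict[str, int] = {}
    for iv in intervals:
        seen[iv.name] = seen.get(iv.name, 0) + 1
    dups = sorted(n for n, c in seen.items() if c > 1)
    if dups:
        raise ParseError(f"duplicate {what} names: {', '.join(dups)}")


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping/adjacent [start, end) pairs."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(blocks):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from a GTF file and assemble one ``GeneModel`` per gene.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention.  Overlapping exon records of a gene are merged into
    maximal blocks.  Exons without a ``gene_id`` attribute, or with strand
    ``.``, are skipped with a warning.
    """
    path = Path(path)
    per_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: unparseable GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            gene_ids = feat.attributes.get("gene_id", [])
            if not gene_ids or not gene_ids[0]:
                logger.warning("%s:%d: exon without gene_id skipped", path, lineno)
                continue
            if feat.strand not in VALID_STRANDS:
                logger.warning("%s:%d: exon with strand '.' skipped", path, lineno)
                continue
            gid = gene_ids[0]
            if gid in meta and meta[gid] != (feat.seqid, feat.strand):
                raise ParseError(
                    f"{path}:{lineno}: gene {gid} spans multiple chromosomes/strands"
                )
            meta[gid] = (feat.seqid, feat.strand)
            per_gene.setdefault(gid, []).append((feat.start - 1, feat.end))
    genes = []
    for gid in sorted(per_gene):
        chrom, strand = meta[gid]
        exons = tuple(
            GenomicInterval(chrom, s, e, name=gid, strand=strand)
            for s, e in _merge_blocks(per_gene[gid])
        )
        genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=exons))
    return genes


def read_mirna_fasta(path: str | Path) -> list[MiRNA]:
    """Read mature miRNA sequences from FASTA; T is converted to U on read.

    Names are the header up to the first whitespace.  Duplicate names and
    non-nucleotide characters raise :class:`ParseError`.
    """
    path = Path(path)
    mirnas: list[MiRNA] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seen:
            raise ParseError(f"{path}: duplicate miRNA name {name!r}")
        seen.add(name)
        seq = str(record.seq).upper().replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: miRNA {name!r} contains invalid characters {sorted(bad)}"
            )
        if len(seq) < 15:
            logger.warning("%s: miRNA %s is unusually short (%d nt)", path, name, len(seq))
        mirnas.append(MiRNA(name=name, sequence=seq))
    return mirnas


class GenomeAccessor:
    """Random access to chromosome sequence, returned as uppercase DNA.

    Backed either by a pyfaidx-indexed FASTA on disk or by an in-memory
    mapping (used by the synthetic-data generator and in tests).
    """

    def __init__(self, seqs: Mapping[str, str] | None = None, fasta=None):
        if (seqs is None) == (fasta is None):
            raise ValueError("provide exactly one of seqs or fasta")
        self._seqs = dict(seqs) if seqs is not None else None
        self._fasta = fasta

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAccessor":
        import pyfaidx

        return cls(fasta=pyfaidx.Fasta(str(path), sequence_always_upper=True))

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "GenomeAccessor":
        return cls(seqs={c: s.upper() for c, s in seqs.items()})

    def __contains__(self, chrom: str) -> bool:
        if self._seqs is not None:
            return chrom in self._seqs
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not found in genome")
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """DNA sequence of ``chrom[start:end)`` (0-based half-open)."""
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not found in genome")
        n = self.length(chrom)
        if start < 0 or end > n or end <= start:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds (length {n})"
            )
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()


def interactions_to_frame(interactions: Iterable["Interaction"]) -> pd.DataFrame:
    """Assemble the 12-column result table as a DataFrame."""
    rows = []
    for it in interactions:
        rows.append(
            {
                "Chrom": it.interval.chrom,
                "Start": it.interval.start,
                "End": it.interval.end,
                "miRNA Name": it.mirna_name,
                "Circ Name": it.circ_name,
                "Strand": it.strand,
                "Seed Category": it.seed_category,
                "ID": it.id,
                "Software Matched": it.software_matched,
                "Validated": "Yes" if it.validated else "No",
                "AGO": "Yes" if it.ago else "No",
                "circBase ID": it.circbase_id or "",
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_csv(interactions: Iterable["Interaction"], path: str | Path) -> None:
    """Write the final interaction table as comma-delimited CSV with header."""
    frame = interactions_to_frame(interactions)
    frame.to_csv(path, index=False, lineterminator="\n")
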