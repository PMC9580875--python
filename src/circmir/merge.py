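"""Cross-engine merging and annotation of predicted sites.

Sites are first projected back to genomic coordinates through each circRNA's
coordinate map.  Sites of the same (miRNA, circRNA) pair whose genomic
footprints overlap by at least 1 bp are grouped by transitive closure into a
single interaction; the group records how many distinct engines support it.
Interactions are then flagged against experimentally validated miRNA:RNA
records, Argonaute peak intervals, and a circBase-style identifier table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .builder import CircStructure
from .engines import PredictedSite, seed_rank
from .io import GenomicInterval, read_bed

logger = logging.getLogger(__name__)

_TAG_PRIORITY = ("M", "RH", "TS")


@dataclass
class Interaction:
    """One merged miRNA:circRNA binding site, matching the output schema."""

    interval: GenomicInterval
    mirna_name: str
    circ_name: str
    strand: str
    seed_category: str
    tag: str
    software_matched: int
    id: str = ""
    validated: bool = False
    ago: bool = False
    circbase_id: str = ""
    members: tuple[PredictedSite, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.software_matched <= 3:
            raise ValueError("software_matched must be in 1..3")
        if self.tag not in _TAG_PRIORITY:
            raise ValueError(f"unknown engine tag {self.tag!r}")


@dataclass
class AnnotationDB:
    """Interval indices over the optional annotation tables.

    ``validated`` and ``ago`` are per-chromosome interval trees; validated
    records may carry a miRNA name (BED name column, first ``|``-separated
    token), in which case the flag additionally requires name equality.
    ``circbase`` maps exact (chrom, start, end, strand) circRNA spans to IDs.
    """

    validated: dict[str, IntervalTree] = field(default_factory=dict)
    ago: dict[str, IntervalTree] = field(default_factory=dict)
    circbase: dict[tuple[str, int, int, str], str] = field(default_factory=dict)

    @staticmethod
    def _index(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
        return trees

    @classmethod
    def from_intervals(
        cls,
        validated: list[GenomicInterval] | None = None,
        ago: list[GenomicInterval] | None = None,
        circbase: list[GenomicInterval] | None = None,
    ) -> "AnnotationDB":
        db = cls(
            validated=cls._index(validated or []),
            ago=cls._index(ago or []),
        )
        for iv in circbase or []:
            db.circbase[(iv.chrom, iv.start, iv.end, iv.strand)] = iv.name
        return db

    @classmethod
    def from_files(
        cls,
        validated_bed: str | Path | None = None,
        ago_bed: str | Path | None = None,
        circbase_bed: str | Path | None = None,
    ) -> "AnnotationDB":
        load = lambda p: read_bed(p, autoname=False) if p else []
        return cls.from_intervals(
            validated=load(validated_bed),
            ago=load(ago_bed),
            circbase=load(circbase_bed),
        )


def sites_to_genomic(
    sites: list[PredictedSite], structures: dict[str, CircStructure]
) -> list[PredictedSite]:
    """Attach genomic coordinates to every site via its circRNA's map.

    Sites spanning block junctions carry multiple intervals; the reported
    primary footprint is the 5'-most interval, and the multi-block fact is
    logged.
    """
    for site in sites:
        struct = structures[site.circ_name]
        intervals = struct.cmap.map_to_genome(site.t_start, site.t_end)
        site.genomic = tuple(intervals)
        site.chrom = struct.chrom
        site.strand = struct.strand
        if len(intervals) > 1:
            logger.info(
                "site %s:%s [%d,%d) spans %d blocks; reporting the 5'-most",
                site.mirna_name, site.circ_name, site.t_start, site.t_end,
                len(intervals),
            )
    return sites


def _footprints_overlap(a: PredictedSite, b: PredictedSite) -> bool:
    return any(ia.overlaps(ib) for ia in a.genomic for ib in b.genomic)


def _group_sites(sites: list[PredictedSite]) -> list[list[PredictedSite]]:
    """Transitive closure of pairwise genomic overlap (one miRNA:circ pair)."""
    parent = list(range(len(sites)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(range(len(sites)), key=lambda k: sites[k].genomic[0].start)
    # sweep: only neighbors within the running max end can overlap
    for a_pos, ka in enumerate(order):
        for kb in order[a_pos + 1 :]:
            if sites[kb].genomic[0].start > max(iv.end for iv in sites[ka].genomic):
                break
            if _footprints_overlap(sites[ka], sites[kb]):
                parent[find(ka)] = find(kb)
    groups: dict[int, list[PredictedSite]] = {}
    for k in range(len(sites)):
        groups.setdefault(find(k), []).append(sites[k])
    return list(groups.values())


def _representative(members: list[PredictedSite]) -> PredictedSite:
    """Site whose footprint represents the group.

    Prefer a seed-scan (TS) site -- its window is the seed-match window --
    then any seed-classified site; best category first, then smallest start.
    """
    ts = [s for s in members if s.engine == "TS"]
    classified = [s for s in members if s.seed_category != "none"]
    pool = ts or classified or members
    return min(pool, key=lambda s: (-seed_rank(s.seed_category), s.t_start, s.t_end))


def merge_across_engines(sites: list[PredictedSite]) -> list[Interaction]:
    """Merge sites of the same miRNA:circRNA pair whose footprints overlap.

    ``software_matched`` counts distinct engine tags in the group; the ID tag
    is chosen by priority M > RH > TS; the seed category is the best in the
    group.  Sites must already carry genomic coordinates.
    """
    by_pair: dict[tuple[str, str], list[PredictedSite]] = {}
    for site in sites:
        if not site.genomic:
            raise ValueError("sites must be projected to genomic coordinates first")
        by_pair.setdefault((site.mirna_name, site.circ_name), []).append(site)
    interactions = []
    for (mirna_name, circ_name), pair_sites in sorted(by_pair.items()):
        for members in _group_sites(pair_sites):
            tags = {s.engine for s in members}
            tag = next(t for t in _TAG_PRIORITY if t in tags)
            rep = _representative(members)
            if rep.seed_category != "none" or rep.engine == "TS":
                footprint = rep.primary_interval
            else:
                start = min(iv.start for s in members for iv in s.genomic)
                end = max(iv.end for s in members for iv in s.genomic)
                footprint = GenomicInterval(
                    rep.chrom, start, end, strand=rep.strand
                )
            category = max((s.seed_category for s in members), key=seed_rank)
            interactions.append(
                Interaction(
                    interval=footprint,
                    mirna_name=mirna_name,
                    circ_name=circ_name,
                    strand=members[0].strand,
                    seed_category=category,
                    tag=tag,
                    software_matched=len(tags),
                    members=tuple(members),
                )
            )
    return interactions


def assign_ids(interactions: list[Interaction]) -> list[Interaction]:
    """Assign ``INT_<tag>_<n>`` IDs in canonical output order.

    Canonical order is (chrom, start, end, miRNA name); numbering starts at 1
    and is unique within the run.
    """
    ordered = sorted(
        interactions,
        key=lambda it: (it.interval.chrom, it.interval.start, it.interval.end, it.mirna_name),
    )
    for n, it in enumerate(ordered, start=1):
        it.id = f"INT_{it.tag}_{n}"
    return ordered


def flag_overlaps(
    interactions: list[Interaction],
    db: AnnotationDB,
    require_name_match: bool = True,
) -> list[Interaction]:
    """Set the Validated and AGO flags by >= 1 bp genomic overlap.

    A validated record carrying a miRNA name (first ``|``-separated token of
    its BED name) must also name the interaction's miRNA when
    ``require_name_match`` is true; bare records match on coordinates alone.
    """
    for it in interactions:
        iv = it.interval
        vtree = db.validated.get(iv.chrom)
        if vtree is not None:
            for hit in vtree.overlap(iv.start, iv.end):
                record_mirna = (hit.data or "").split("|")[0]
                if record_mirna and require_name_match:
                    if record_mirna == it.mirna_name:
                        it.validated = True
                        break
                else:
                    it.validated = True
                    break
        atree = db.ago.get(iv.chrom)
        if atree is not None and atree.overlap(iv.start, iv.end):
            it.ago = True
    return interactions


def circbase_lookup(
    interactions: list[Interaction],
    structures: dict[str, CircStructure],
    db: AnnotationDB,
    tolerance: int = 0,
) -> list[Interaction]:
    """Attach circBase-style IDs by exact span match (optional +/- tolerance).

    The circRNA's original input span (not its exon blocks) is compared with
    the identifier table on (chrom, start, end, strand).
    """
    for it in interactions:
        span = structures[it.circ_name].span
        key = (span.chrom, span.start, span.end, span.strand)
        if key in db.circbase:
            it.circbase_id = db.circbase[key]
        elif tolerance > 0:
            for (chrom, start, end, strand), cid in db.circbase.items():
                if (
                    chrom == span.chrom
                    and strand == span.strand
                    and abs(start - span.start) <= tolerance
                    and abs(end - span.end) <= tolerance
                ):
                    it.circbase_id = cid
                    break
    return interactions
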