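"""Deterministic synthetic dataset with planted miRNA binding sites.

Generates a toy genome (three chromosomes, a few kilobases each), a gene
annotation covering multi-exon plus- and minus-strand genes, circRNAs of all
three classes (sense-overlapping, antisense, intergenic), synthetic miRNAs,
and annotation BEDs (validated sites, AGO peaks, circBase-style IDs) -- with
binding sites of known category planted at recorded coordinates.

Background sequence is rejection-screened so that no circRNA transcript
contains an exact seed match for any fixture miRNA outside the planted
windows; exact-seed recovery is therefore complete by construction.  The
duplex-energy and alignment engines may legitimately report additional
low-affinity background sites, so recovery tests on those engines assert a
superset, not exclusivity.

Everything is driven by one integer seed; the same seed yields byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .builder import (
    CoordinateMap,
    reverse_complement_rna,
    rna_to_dna,
)
from .io import GenomeAccessor, GenomicInterval

_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: planted element kinds and their target-site lengths given a 22-nt miRNA
SITE_KINDS = ("full", "8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class PlantRequest:
    """One site to plant: which miRNA, which circRNA, what kind, where."""

    mirna: str
    circ: str
    kind: str
    t_start: int
    validated: bool = False
    ago: bool = False
    decoy_validated: bool = False  # emit a wrong-named validated record


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site (seed window, transcript + genome)."""

    mirna: str
    circ: str
    kind: str
    category: str
    t_start: int
    t_end: int
    chrom: str
    g_start: int
    g_end: int
    strand: str
    validated: bool
    ago: bool


@dataclass
class FixtureTruth:
    """Serializable truth table of a generated fixture."""

    seed: int
    sites: list[PlantedSite]
    circbase: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "sites": [dataclasses.asdict(s) for s in self.sites],
                "circbase": self.circbase,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        data = json.loads(text)
        return cls(
            seed=data["seed"],
            sites=[PlantedSite(**s) for s in data["sites"]],
            circbase=data["circbase"],
        )


@dataclass
class Fixture:
    """File paths plus in-memory truth of a generated dataset."""

    directory: Path
    genome_fa: Path
    gtf: Path
    circ_bed: Path
    features_bed: Path
    mirna_fa: Path
    validated_bed: Path
    ago_bed: Path
    circbase_bed: Path
    truth_json: Path
    truth: FixtureTruth


# -- fixed layout of the toy locus ------------------------------------------

_CHROM_SIZES = {"chr1": 8000, "chr2": 4000, "chr3": 3000}

_GENES = {
    "GA": ("chr1", "+", [(1000, 1400), (2000, 2400), (3000, 3500)]),
    "GB": ("chr1", "-", [(5000, 5600), (6200, 6800)]),
    "GC": ("chr2", "+", [(500, 1500)]),
}

_CIRCS = [
    GenomicInterval("chr1", 1100, 3300, name="circ_multi", strand="+"),
    GenomicInterval("chr1", 5100, 6700, name="circ_minus", strand="-"),
    GenomicInterval("chr2", 800, 1300, name="circ_anti", strand="-"),
    GenomicInterval("chr3", 1000, 1500, name="circ_inter", strand="+"),
]

# resolved block structure of the default circRNAs (see _GENES):
_BLOCKS = {
    "circ_multi": [(1100, 1400), (2000, 2400), (3000, 3300)],   # sense, 3 exons
    "circ_minus": [(5100, 5600), (6200, 6700)],                 # sense on minus
    "circ_anti": [(800, 1300)],                                 # antisense
    "circ_inter": [(1000, 1500)],                               # intergenic
}

_DEFAULT_CIRCBASE = {"circ_multi": "synth_circ_0001", "circ_anti": "synth_circ_0002"}

_DEFAULT_PLAN = [
    PlantRequest("syn-miR-1", "circ_multi", "full", 40, validated=True),
    PlantRequest("syn-miR-2", "circ_multi", "8mer", 380),
    PlantRequest("syn-miR-3", "circ_multi", "7mer-m8", 760, decoy_validated=True),
    PlantRequest("syn-miR-1", "circ_minus", "full", 100, ago=True),
    PlantRequest("syn-miR-3", "circ_anti", "8mer", 200),
    PlantRequest("syn-miR-4", "circ_anti", "6mer", 350),
    PlantRequest("syn-miR-4", "circ_inter", "7mer-A1", 150, validated=True),
    PlantRequest("syn-miR-2", "circ_inter", "full", 300, ago=True),
]

_MIRNA_LEN = 22


def _site_element(mirna_seq: str, kind: str) -> str:
    """Target-site RNA string (5'->3') for a planted element."""
    rc28 = reverse_complement_rna(mirna_seq[1:8])
    rc27 = reverse_complement_rna(mirna_seq[1:7])
    if kind == "full":
        return reverse_complement_rna(mirna_seq)
    if kind == "8mer":
        return rc28 + "A"
    if kind == "7mer-m8":
        return rc28
    if kind == "7mer-A1":
        return rc27 + "A"
    if kind == "6mer":
        return rc27
    raise ValueError(f"unknown site kind {kind!r}")


def _seed_window(kind: str, t_start: int, element_len: int) -> tuple[int, int, str]:
    """(seed window start, end, category) of a planted element."""
    if kind == "full":
        # the canonical 8mer window sits at the 3' end of the full complement
        return t_start + element_len - 8, t_start + element_len, "8mer"
    return t_start, t_start + element_len, kind


class _FixtureBuilder:
    def __init__(self, seed: int, plan: list[PlantRequest], circbase: dict[str, str]):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.plan = plan
        self.circbase_map = circbase
        self.genome = {
            chrom: list(self.rng.choice(list("ACGT"), size=size))
            for chrom, size in _CHROM_SIZES.items()
        }
        self.cmaps = {
            name: CoordinateMap(
                blocks=tuple(
                    GenomicInterval(circ.chrom, s, e, name=name, strand=circ.strand)
                    for s, e in _BLOCKS[name]
                ),
                strand=circ.strand,
            )
            for circ in _CIRCS
            for name in [circ.name]
        }
        self.protected: dict[str, set[int]] = {c.name: set() for c in _CIRCS}
        self.mirnas: dict[str, str] = {}

    # -- sequence plumbing -------------------------------------------------

    def _set_transcript_base(self, circ: str, t: int, rna_base: str) -> None:
        cmap = self.cmaps[circ]
        g = cmap.genome_position(t)
        dna = rna_to_dna(rna_base)
        if cmap.strand == "-":
            dna = _DNA_COMP[dna]
        self.genome[cmap.chrom][g] = dna

    def _transcript(self, circ: str) -> str:
        cmap = self.cmaps[circ]
        genome = GenomeAccessor.from_dict(
            {c: "".join(s) for c, s in self.genome.items()}
        )
        from .builder import assemble_sequence

        seq, _ = assemble_sequence(cmap.blocks, cmap.strand, genome)
        return seq

    # -- miRNA design ------------------------------------------------------

    def make_mirnas(self) -> None:
        names = sorted({req.mirna for req in self.plan})
        seeds_seen: set[str] = set()
        for name in names:
            for _ in range(100):
                body = "".join(self.rng.choice(list("ACGU"), size=_MIRNA_LEN - 1))
                seq = "U" + body  # A opposite position 1 makes full sites 8mer
                if seq[1:8] not in seeds_seen:
                    seeds_seen.add(seq[1:8])
                    self.mirnas[name] = seq
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw distinct miRNA seeds")

    # -- planting ----------------------------------------------------------

    def plant(self) -> list[PlantedSite]:
        planted = []
        for req in self.plan:
            if req.kind not in SITE_KINDS:
                raise ValueError(f"unknown site kind {req.kind!r}")
            mirna_seq = self.mirnas[req.mirna]
            element = _site_element(mirna_seq, req.kind)
            cmap = self.cmaps[req.circ]
            t0, t1 = req.t_start, req.t_start + len(element)
            if t1 > cmap.length:
                raise ValueError(
                    f"planted site [{t0},{t1}) longer than circRNA "
                    f"{req.circ} (length {cmap.length})"
                )
            intervals = cmap.map_to_genome(t0, t1)
            if len(intervals) != 1:
                raise ValueError(
                    f"planted site for {req.mirna} on {req.circ} crosses a "
                    "block junction; choose a different t_start"
                )
            for off, base in enumerate(element):
                self._set_transcript_base(req.circ, t0 + off, base)
            prot = self.protected[req.circ]
            prot.update(range(t0, t1))
            # guard the flanks so a planted category cannot silently upgrade
            if req.kind in ("7mer-m8", "6mer") and t1 < cmap.length:
                self._flank(req.circ, t1, forbid={"A"})
                prot.add(t1)
            if req.kind in ("6mer", "7mer-A1") and t0 > 0:
                comp_m8 = reverse_complement_rna(mirna_seq[7])
                self._flank(req.circ, t0 - 1, forbid={comp_m8})
                prot.add(t0 - 1)
            w0, w1, category = _seed_window(req.kind, t0, len(element))
            g = cmap.map_to_genome(w0, w1)[0]
            planted.append(
                PlantedSite(
                    mirna=req.mirna,
                    circ=req.circ,
                    kind=req.kind,
                    category=category,
                    t_start=w0,
                    t_end=w1,
                    chrom=g.chrom,
                    g_start=g.start,
                    g_end=g.end,
                    strand=cmap.strand,
                    validated=req.validated,
                    ago=req.ago,
                )
            )
        return planted

    def _flank(self, circ: str, t: int, forbid: set[str]) -> None:
        current = self._transcript(circ)[t]
        if current in forbid:
            choice = next(b for b in "CGUA" if b not in forbid)
            self._set_transcript_base(circ, t, choice)

    # -- background screening ----------------------------------------------

    def screen(self, max_rounds: int = 300) -> None:
        """Mutate background until no unplanted exact seed match survives."""
        site_strings = {
            name: [s for _, s in _seed_site_variants(seq)]
            for name, seq in self.mirnas.items()
        }
        for _ in range(max_rounds):
            clean = True
            for circ in self.cmaps:
                transcript = self._transcript(circ)
                prot = self.protected[circ]
                for variants in site_strings.values():
                    for site in variants:
                        start = transcript.find(site)
                        while start != -1:
                            window = set(range(start, start + len(site)))
                            if not window <= prot:
                                editable = sorted(window - prot)
                                t = editable[len(editable) // 2]
                                old = transcript[t]
                                new = str(
                                    self.rng.choice([b for b in "ACGU" if b != old])
                                )
                                self._set_transcript_base(circ, t, new)
                                transcript = self._transcript(circ)
                                clean = False
                            start = transcript.find(site, start + 1)
            if clean:
                return
        raise RuntimeError("background screening did not converge")  # pragma: no cover

    # -- output ------------------------------------------------------------

    def write(self, out_dir: Path, planted: list[PlantedSite]) -> Fixture:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome_fa": out_dir / "genome.fa",
            "gtf": out_dir / "annotation.gtf",
            "circ_bed": out_dir / "circs.bed",
            "features_bed": out_dir / "circ_features.bed",
            "mirna_fa": out_dir / "mirnas.fa",
            "validated_bed": out_dir / "validated.bed",
            "ago_bed": out_dir / "ago.bed",
            "circbase_bed": out_dir / "circbase.bed",
            "truth_json": out_dir / "truth.json",
        }
        with open(paths["genome_fa"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = "".join(self.genome[chrom])
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["gtf"], "w") as fh:
            for gid in sorted(_GENES):
                chrom, strand, exons = _GENES[gid]
                for s, e in exons:
                    fh.write(
                        f"{chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f'gene_id "{gid}"; transcript_id "{gid}.1";\n'
                    )
        with open(paths["circ_bed"], "w") as fh:
            for c in _CIRCS:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t0\t{c.strand}\n")
        with open(paths["features_bed"], "w") as fh:
            for c in _CIRCS:
                for s, e in _BLOCKS[c.name]:
                    fh.write(f"{c.chrom}\t{s}\t{e}\t{c.name}\t0\t{c.strand}\n")
        with open(paths["mirna_fa"], "w") as fh:
            for name in sorted(self.mirnas):
                fh.write(f">{name}\n{self.mirnas[name]}\n")
        validated_rows, ago_rows = [], []
        for req, site in zip(self.plan, planted):
            iv = (site.chrom, site.g_start, site.g_end, site.strand)
            if req.validated:
                validated_rows.append((*iv[:3], f"{site.mirna}|{site.circ}", iv[3]))
            if req.decoy_validated:
                validated_rows.append((*iv[:3], "syn-miR-99|decoy", iv[3]))
            if req.ago:
                ago_rows.append((*iv[:3], "ago_peak", iv[3]))
        with open(paths["validated_bed"], "w") as fh:
            for chrom, s, e, name, strand in validated_rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
        with open(paths["ago_bed"], "w") as fh:
            for chrom, s, e, name, strand in ago_rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
        with open(paths["circbase_bed"], "w") as fh:
            for c in _CIRCS:
                if c.name in self.circbase_map:
                    fh.write(
                        f"{c.chrom}\t{c.start}\t{c.end}\t"
                        f"{self.circbase_map[c.name]}\t0\t{c.strand}\n"
                    )
            # off-by-one decoy: must never match the exact-span lookup
            decoy = next((c for c in _CIRCS if c.name not in self.circbase_map), None)
            if decoy is not None:
                fh.write(
                    f"{decoy.chrom}\t{decoy.start + 1}\t{decoy.end}\t"
                    f"synth_circ_0099\t0\t{decoy.strand}\n"
                )
        truth = FixtureTruth(seed=self.seed, sites=planted, circbase=dict(self.circbase_map))
        paths["truth_json"].write_text(truth.to_json() + "\n")
        return Fixture(directory=out_dir, truth=truth, **paths)


def _seed_site_variants(mirna_seq: str) -> list[tuple[str, str]]:
    from .engines import _seed_site_strings

    return _seed_site_strings(mirna_seq)


def generate_fixture(
    out_dir: str | Path,
    seed: int = 42,
    site_plan: list[PlantRequest] | None = None,
    circbase: dict[str, str] | None = None,
) -> Fixture:
    """Generate the synthetic dataset into *out_dir* and return its truth.

    The default site plan plants eight sites covering every seed category,
    both strands, all circRNA classes, and the validated/AGO/circBase
    annotation paths.  A custom ``site_plan`` may reference the built-in
    circRNAs (circ_multi, circ_minus, circ_anti, circ_inter) with arbitrary
    miRNA labels.
    """
    plan = site_plan if site_plan is not None else _DEFAULT_PLAN
    b = _FixtureBuilder(seed, plan, circbase if circbase is not None else _DEFAULT_CIRCBASE)
    b.make_mirnas()
    planted = b.plant()
    b.screen()
    for site in planted:  # planting is invariant under screening
        transcript = b._transcript(site.circ)
        element = _site_element(b.mirnas[site.mirna], site.kind)
        w0 = site.t_start if site.kind != "full" else site.t_start - (len(element) - 8)
        assert transcript[w0 : w0 + len(element)] == element
    return b.write(Path(out_dir), planted)
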