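"""End-to-end pipeline: inputs -> structures -> engines -> merged CSV.

The run is deterministic: work units are dispatched in a fixed order
regardless of worker count and the output rows are sorted canonically by
(chrom, start, end, miRNA name).  A JSON run report with per-stage counts is
written next to the output CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import builder, io, merge
from .engines import EngineConfig, run_engines

logger = logging.getLogger(__name__)

MODES = ("full_sequence", "features")


@dataclass
class RunConfig:
    """Everything a pipeline run needs."""

    input_bed: Path
    genome_fasta: Path
    mirna_fasta: Path
    gtf: Path | None = None
    mode: str = "full_sequence"
    validated_bed: Path | None = None
    ago_bed: Path | None = None
    circbase_bed: Path | None = None
    output_csv: Path = Path("circmir_interactions.csv")
    workers: int = 1
    junction_wrap: bool = False
    engine_config: EngineConfig = field(default_factory=EngineConfig)
    require_name_match: bool = True
    circbase_tolerance: int = 0

    def __post_init__(self) -> None:
        for f in ("input_bed", "genome_fasta", "mirna_fasta", "gtf",
                  "validated_bed", "ago_bed", "circbase_bed", "output_csv"):
            v = getattr(self, f)
            if v is not None:
                setattr(self, f, Path(v))

    def validate(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        required = [self.input_bed, self.genome_fasta, self.mirna_fasta]
        if self.mode == "full_sequence":
            if self.gtf is None:
                raise ValueError("full_sequence mode requires a GTF annotation")
            required.append(self.gtf)
        for p in required + [
            p for p in (self.validated_bed, self.ago_bed, self.circbase_bed) if p
        ]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


@dataclass
class RunReport:
    """Per-stage counts of a pipeline run."""

    n_circ: int = 0
    n_mirna: int = 0
    n_sites_per_engine: dict = field(default_factory=dict)
    n_sites_total: int = 0
    n_interactions: int = 0
    n_validated: int = 0
    n_ago: int = 0
    n_circbase: int = 0
    failed_pairs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write the 12-column CSV plus a report."""
    config.validate()
    report = RunReport()

    circs = io.read_bed(config.input_bed)
    if config.mode == "full_sequence":
        io.ensure_unique_names(circs, "circRNA")
        genes = io.read_gtf(config.gtf)
    else:
        genes = []
    genome = io.GenomeAccessor.from_fasta(config.genome_fasta)
    mirnas = io.read_mirna_fasta(config.mirna_fasta)
    report.n_mirna = len(mirnas)

    wrap = 0
    if config.junction_wrap and mirnas:
        wrap = max(len(m.sequence) for m in mirnas) - 1
    structures = builder.build_structures(
        circs, genes, genome, mode=config.mode, wrap=wrap
    )
    report.n_circ = len(structures)
    logger.info("resolved %d circRNA structures", len(structures))

    output = run_engines(
        mirnas, structures, config.engine_config, workers=config.workers
    )
    report.failed_pairs = output.failures
    report.n_sites_total = len(output.sites)
    for s in output.sites:
        report.n_sites_per_engine[s.engine] = (
            report.n_sites_per_engine.get(s.engine, 0) + 1
        )
    logger.info("engines reported %d sites", len(output.sites))

    merge.sites_to_genomic(output.sites, structures)
    interactions = merge.merge_across_engines(output.sites)
    interactions = merge.assign_ids(interactions)

    db = merge.AnnotationDB.from_files(
        validated_bed=config.validated_bed,
        ago_bed=config.ago_bed,
        circbase_bed=config.circbase_bed,
    )
    merge.flag_overlaps(interactions, db, require_name_match=config.require_name_match)
    merge.circbase_lookup(interactions, structures, db, tolerance=config.circbase_tolerance)

    report.n_interactions = len(interactions)
    report.n_validated = sum(it.validated for it in interactions)
    report.n_ago = sum(it.ago for it in interactions)
    report.n_circbase = sum(bool(it.circbase_id) for it in interactions)

    io.write_results_csv(interactions, config.output_csv)
    report_path = Path(str(config.output_csv) + ".report.json")
    report_path.write_text(report.to_json() + "\n")
    logger.info(
        "wrote %d interactions to %s (report: %s)",
        len(interactions), config.output_csv, report_path,
    )
    return report
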