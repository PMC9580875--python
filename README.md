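# circmir

Prediction and annotation of miRNA binding sites on circular RNAs.

Circular RNAs (circRNAs) are covalently closed transcripts that can act as
miRNA sponges, sequestering miRNAs away from their linear targets.  Single
site-prediction tools produce thousands of candidate miRNA:circRNA pairs
with high false-positive rates; candidates become useful for functional
work only when several independent methods agree and when the site
coincides with experimental evidence of RISC engagement.  `circmir` is a
self-contained pipeline for exactly that workflow, aimed at researchers
studying circRNA function in any organism for which a genome, a gene
annotation and a miRNA catalogue exist:

1. **Sequence extraction** — circRNA genomic spans (BED) are resolved
   against the gene annotation (GTF): sense-overlapping circRNAs are split
   into exons, antisense/intergenic ones are kept as a single block, and
   the strand-correct transcript sequence is assembled from the genome
   FASTA.  A bidirectional transcript↔genome coordinate map is maintained.
2. **Site prediction** — three independent engines scan every
   (miRNA, circRNA) pair: an exact seed-match scanner (8mer / 7mer-m8 /
   7mer-A1 / 6mer categories), a nearest-neighbor minimum-free-energy
   duplex dynamic program (ΔG = initiation + Σ stacks + loop penalties),
   and a position-weighted Smith–Waterman local aligner (WC +5, G:U +1,
   mismatch −3, gaps −9/−4, seed positions 2–8 scaled ×4, threshold 140,
   energy filter −1 kcal/mol).
3. **Consensus and annotation** — sites are projected back to genomic
   coordinates, overlapping sites of the same pair are merged across
   engines (the `Software Matched` column counts supporting engines), and
   each interaction is flagged for overlap with validated miRNA:RNA
   records and Argonaute CLIP/ChIP peaks and matched against a
   circBase-style identifier table.

The result is a 12-column CSV (`Chrom, Start, End, miRNA Name, Circ Name,
Strand, Seed Category, ID, Software Matched, Validated, AGO, circBase ID`)
that can be filtered down to, e.g., sites found by all three engines *and*
supported by an AGO peak.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

The package ships a deterministic synthetic-data generator that builds a
toy genome with planted sites of known category and coordinates — useful
both as a demo and as ground truth for the test suite:

```sh
python -c "from circmir import generate_fixture; generate_fixture('demo', seed=42)"
circmir -i demo/circs.bed --genome demo/genome.fa --gtf demo/annotation.gtf \
    --mirnas demo/mirnas.fa --validated demo/validated.bed --ago demo/ago.bed \
    --circbase demo/circbase.bed -o demo/interactions.csv --threads 2
```

which prints

```
circmir: 22 interactions (2 validated, 2 AGO) -> demo/interactions.csv
```

and writes, among others, this row (the first planted site):

```
Chrom,Start,End,miRNA Name,Circ Name,Strand,Seed Category,ID,Software Matched,Validated,AGO,circBase ID
chr1,1154,1162,syn-miR-1,circ_multi,+,8mer,INT_M_1,3,Yes,No,synth_circ_0001
```

Reading: on chr1 at [1154, 1162) the miRNA `syn-miR-1` has an 8mer seed
site on the three-exon circRNA `circ_multi`; all three engines found it
(`Software Matched` 3, ID tag `M` by engine priority), it overlaps a
validated interaction record but no AGO peak, and the circRNA's span is
listed in the identifier table as `synth_circ_0001`.  A JSON run report
with per-stage counts is written next to the CSV
(`demo/interactions.csv.report.json`).

Library use mirrors the CLI:

```python
from circmir import RunConfig, run_pipeline
report = run_pipeline(RunConfig(
    input_bed="demo/circs.bed", genome_fasta="demo/genome.fa",
    gtf="demo/annotation.gtf", mirna_fasta="demo/mirnas.fa",
    output_csv="demo/interactions.csv",
))
```

Use `--coord` when the input BED already lists the final feature (block)
coordinates of each circRNA (several rows per name); `--junction-wrap` to
expose sites spanning the backsplice junction; `--params params.yaml` to
override any engine constant.

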