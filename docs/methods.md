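# Methods

`circmir` predicts miRNA binding sites on circular RNAs (circRNAs) and
annotates them with external evidence.  This note documents the models the
package implements, the defaults it pins, the design choices that were
genuinely open, and what its synthetic test data can and cannot show.

## Sequence extraction and the coordinate map

A circRNA arrives as a genomic span (BED).  Its transcript structure is
resolved against the gene annotation:

* **sense-overlapping** (>= 1 bp overlap with a gene on the same strand):
  the transcript is the intersection of the span with the donor gene's
  merged exons, clipped to the span.  When the span overlaps several
  same-strand genes, the gene with the largest bp overlap donates its exon
  model (ties broken by lexicographically smallest gene id).  A span that
  lies entirely inside an intron falls back to a single block with a
  warning rather than producing an empty transcript.
* **antisense** and **intergenic** spans are treated as a single exon.
* In **features mode** the user supplies the block composition directly
  (one BED row per block, grouped by name) and no splitting is performed.

Exon blocks are *clipped* to the circRNA span when a boundary falls inside
an exon; taking the whole exon would report sequence outside the declared
span.  All internal coordinates are 0-based half-open (BED native); GTF is
converted on read.  The transcript is the left-to-right concatenation of
block sequences (reverse-complemented as a whole on the minus strand),
transcribed to RNA.  `CoordinateMap` inverts the assembly: transcript
windows map back to 1..k genomic intervals (k > 1 across exon junctions),
with total length conserved and minus-strand windows anchored at the
genomic right edge.

The transcript is linear by default, matching the behaviour of
coordinate-driven site scanning; sites spanning the backsplice junction are
invisible.  An optional *junction wrap* appends the first (miRNA length − 1)
nucleotides after the 3' end so junction-spanning windows become
addressable; the map then returns the two wrapped genomic pieces.  Genome
`N` characters pass through assembly and are unpairable/mismatched in every
engine.

## The three engines

All engines scan each (miRNA, circRNA transcript) pair independently, with
no cross-engine filtering, and report transcript-space footprints, a score,
a seed category, and a three-line pairing trace (`|` Watson–Crick, `:` G:U
wobble, space mismatch/unpaired, `-` gap).

### Exact seed scan (TS)

The canonical site categories are defined on miRNA positions counted
1-based from the 5' end: **8mer** (WC pairing over positions 2–8 plus an A
opposite position 1), **7mer-m8** (2–8), **7mer-A1** (2–7 plus A1), and
**6mer** (2–7).  The scanner tests each transcript start position against
the reverse complements of the seed regions in that precedence order and
reports the best category per start.  Reported windows are the matched
sequences: 8 nt for 8mer, 7 for 7mer-m8 and 7mer-A1, 6 for 6mer.
*offset-6mer* (positions 3–8) is implemented but disabled by default, since
only 8mer/7mer/6mer classes are scanned by the reference tools this engine
emulates.

Seed classification of alignment-derived sites uses the same definitions
and additionally requires the seed block to be a *contiguous* antiparallel
WC helix — a bulged or wobbled "seed" is not a seed.  This keeps categories
consistent across engines: any classified site contains an exact seed
match.

### Duplex hybridization (RH)

Intermolecular minimum-free-energy duplexes are computed by dynamic
programming over miRNA × transcript.  A duplex structure is a monotone
antiparallel set of canonical pairs (WC or G:U); it is scored as

    ΔG = initiation + Σ stacks + Σ loop penalties        [kcal/mol, 37 °C]

with nearest-neighbor stacking terms for adjacent pairs and
length-dependent bulge/interior penalties (plus a Ninio-style asymmetry
term, 0.48 kcal/mol per unpaired-length difference, capped at 3.0) for
interrupted helices.  Intramolecular structure (target accessibility) is
deliberately not modeled; only the hybrid is scored.  Parameters:

* stacking table: Turner-style values over the six pair types; all WC/WC
  stacks are ≤ 0 (enforced), wobble-containing stacks mostly stabilizing,
  with the known destabilizing 5'GU3'/3'UG5' case positive.  The table is
  symmetric under duplex reversal (enforced).
* duplex initiation +4.09 kcal/mol; bulge penalties 3.8–4.9 for lengths
  1–10; interior penalties 1.7–3.7 for total sizes 2–20.
* per-side loop cap 10 nt: longer unpaired stretches end a duplex, which
  also bounds the DP at O(m·n·cap²).

All cells with energy at or below the reporting threshold (default
−20 kcal/mol, the energy-filter convention of hybridization-based site
scanners) are traced back; duplexes are selected greedily best-first
(lower energy, then smaller footprint start) subject to non-overlapping
target footprints.

### Position-weighted local alignment (M)

The reversed miRNA (3'→5') is aligned against the transcript (5'→3') by
Smith–Waterman with affine gaps (Gotoh).  Substitution scores are
complementarity-based: WC +5, G:U wobble +1, mismatch −3; gap open −9
(first gapped base), gap extend −4.  Substitution scores at miRNA positions
2–8 are multiplied by 4.0, encoding the dominance of seed pairing; gap
costs are not scaled.  All non-overlapping local maxima scoring at least
140 are collected by recursive segment splitting (find best, split target
around its footprint, recurse).  Each surviving alignment is re-scored with
the duplex energy model over its footprint and kept only when that energy
is at most −1.0 kcal/mol.  These constants mirror the published defaults of
the alignment-based scanner this engine emulates; every one of them is
config-overridable (`--params`, YAML).

## Merging and annotation

Sites are projected to genomic coordinates; a junction-spanning site keeps
all its genomic pieces but reports the 5'-most piece as its Start/End.
Sites of the same (miRNA, circRNA) pair whose genomic footprints overlap by
at least 1 bp are grouped by transitive closure — engines report windows of
different widths around the same seed, so "same interaction" cannot demand
identical coordinates.  Each group becomes one interaction:

* `Software Matched` = number of distinct engine tags in the group (1–3);
* ID tag priority M > RH > TS; IDs are `INT_<tag>_<n>` with `n` counting
  from 1 in output order (chrom, start, end, miRNA name);
* the representative footprint is the seed-scan window when a TS (or any
  seed-classified) member exists, else the union span;
* the seed category is the best in the group.

`Validated` is set by ≥ 1 bp overlap with a validated-interaction record;
when the record's BED name carries a miRNA (first `|`-separated token), the
names must also agree (default; coordinate-only matching is available,
since both rich TarBase-style and bare peak-style inputs occur).  `AGO` is
pure coordinate overlap with any Argonaute peak.  The circBase-style ID is
attached by exact (chrom, start, end, strand) match of the circRNA's
original input span; a ± N bp tolerance exists but defaults to 0.

Parallelism is over (miRNA, circRNA) work units with order-preserving
collection, so the output is byte-identical for any worker count.

## Synthetic data

`circmir.synthetic.generate_fixture` builds a fully known dataset: three
chromosomes (8/4/3 kb), three genes (multi-exon plus-strand, two-exon
minus-strand, single-exon), and four circRNAs covering every class and both
strands (a three-exon sense circRNA, a two-exon minus-strand circRNA, an
antisense and an intergenic single-block circRNA).  Four 22-nt miRNAs are
drawn with distinct seeds and a 5'-terminal U (so a full-complement site
carries the 8mer's A1 by construction).  The default plan plants eight
sites — every seed category, three full-complement sites that all three
engines must find, minus-strand and multi-exon contexts — and writes
validated/AGO records over designated sites (including one wrong-named
decoy record that must *not* set the Validated flag) plus exact-span and
off-by-one circBase records.

Background sequence is rejection-screened: any exact seed match for any
fixture miRNA outside a planted window is mutated away, and planted flanks
are guarded so a planted category cannot silently upgrade (e.g. a 6mer
followed by A becoming a 7mer-A1).  Exact-seed recovery is therefore
complete and category-exact by construction.  The energy and alignment
engines may legitimately report extra low-affinity background sites, so
tests assert recovery of planted sites, not exclusivity.

What the fixture does **not** emulate: realistic genome composition and
repeat content, miRBase-scale miRNA sets, alternative isoforms per
backsplice locus, expression levels, or the size of real annotation
databases.  Passing recovery tests therefore demonstrates correctness of
the machinery, not expected yield or precision on real data.

## Numerical choices and problem sizes

Ties are broken deterministically everywhere (documented sort keys);
energies are compared exactly (the DP and its oracle share one float
pipeline).  The validation oracles are brute-force reference
implementations kept in `circmir.validation`: a per-window complementarity
scanner, a memoized recursion over all loop-capped duplex structures
(itself cross-checked against a generate-everything enumerator at tiny
sizes), an independently written recursive aligner (cross-checked against a
literal column-path enumerator), a per-base coordinate walker, and an O(n²)
transitive-closure grouper.  Oracle comparisons run at 500–1000 random
instances with miRNA ≤ 8 nt / windows ≤ 12 nt for the duplex program and
miRNA ≤ 6 nt / targets ≤ 10 nt for the aligner — sizes at which exhaustive
enumeration is exact and fast while still exercising every recurrence case.

## Known limitations

* Seed-match-centred engines only; no conservation scoring, context
  features, or target-accessibility folding.
* The energy parameterization is a canonical nearest-neighbor table, not a
  fitted model; absolute ΔG values should be read comparatively.
* One structure per circRNA: no isoform enumeration per backsplice locus.
* Junction-spanning sites require the opt-in wrap flag and are reported as
  split genomic intervals.
* The internal species annotation database of the original workflow is out
  of scope; annotation tables are supplied as explicit BED files.
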