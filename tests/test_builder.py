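"""circRNA classification, block splitting, assembly, coordinate mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circmir import (
    CoordinateMap,
    GenomeAccessor,
    GenomicInterval,
    GeneModel,
    assemble_sequence,
    classify_circ,
    split_to_blocks,
)
from circmir.builder import accept_user_features, build_structures
from circmir.validation import per_base_map


def gene(gene_id, chrom, strand, exons):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, name=gene_id, strand=strand) for s, e in exons),
    )


GENE_PLUS = gene("G1", "chr1", "+", [(50, 150), (300, 400), (450, 600)])
GENE_MINUS = gene("G2", "chr1", "-", [(50, 1000)])


class TestClassify:
    @pytest.mark.parametrize(
        "circ,genes,expected",
        [
            (GenomicInterval("chr1", 100, 500, strand="+"), [GENE_PLUS], "sense_overlapping"),
            (GenomicInterval("chr1", 100, 500, strand="+"), [GENE_MINUS], "antisense"),
            (GenomicInterval("chr9", 10, 90, strand="+"), [GENE_PLUS], "intergenic"),
            # same-strand overlap wins over an opposite-strand one
            (GenomicInterval("chr1", 100, 500, strand="+"), [GENE_MINUS, GENE_PLUS],
             "sense_overlapping"),
        ],
    )
    def test_classification(self, circ, genes, expected):
        assert classify_circ(circ, genes) == expected


class TestSplitToBlocks:
    def test_exon_intersection_clipped_to_span(self):
        circ = GenomicInterval("chr1", 100, 500, name="c", strand="+")
        blocks = split_to_blocks(circ, [GENE_PLUS], "sense_overlapping")
        got = [(b.start, b.end) for b in blocks]
        # brute-force per-base membership: keep a base iff in circ span AND in an exon
        keep = [
            p for p in range(circ.start, circ.end)
            if any(e.start <= p < e.end for e in GENE_PLUS.exons)
        ]
        runs = []
        for p in keep:
            if runs and p == runs[-1][1]:
                runs[-1] = (runs[-1][0], p + 1)
            else:
                runs.append((p, p + 1))
        assert got == runs == [(100, 150), (300, 400), (450, 500)]

    def test_antisense_single_block(self):
        circ = GenomicInterval("chr1", 100, 500, name="c", strand="+")
        blocks = split_to_blocks(circ, [GENE_MINUS], "antisense")
        assert [(b.start, b.end) for b in blocks] == [(100, 500)]

    def test_intronic_falls_back_to_single_block(self, caplog):
        circ = GenomicInterval("chr1", 160, 290, name="c", strand="+")
        with caplog.at_level("WARNING"):
            blocks = split_to_blocks(circ, [GENE_PLUS], "sense_overlapping")
        assert [(b.start, b.end) for b in blocks] == [(160, 290)]
        assert "single block" in caplog.text

    def test_largest_overlap_gene_donates_exons(self):
        small = gene("A_small", "chr1", "+", [(90, 120)])
        big = gene("B_big", "chr1", "+", [(50, 150), (300, 400)])
        circ = GenomicInterval("chr1", 100, 350, name="c", strand="+")
        blocks = split_to_blocks(circ, [small, big], "sense_overlapping")
        assert [(b.start, b.end) for b in blocks] == [(100, 150), (300, 350)]


class TestUserFeatures:
    def test_grouped_passthrough(self):
        rows = [
            GenomicInterval("chr1", 300, 400, name="circX", strand="+"),
            GenomicInterval("chr1", 100, 150, name="circX", strand="+"),
        ]
        grouped = accept_user_features(rows)
        assert [(b.start, b.end) for b in grouped["circX"]] == [(100, 150), (300, 400)]

    def test_multi_chromosome_error(self):
        rows = [
            GenomicInterval("chr1", 100, 150, name="circX"),
            GenomicInterval("chr2", 100, 150, name="circX"),
        ]
        with pytest.raises(ValueError, match="chromosomes"):
            accept_user_features(rows)

    def test_single_row_matches_single_block_mode(self):
        genome = GenomeAccessor.from_dict({"chr1": "AAACGTACAAA" * 10})
        circ = GenomicInterval("chr1", 20, 60, name="c", strand="+")
        default = build_structures([circ], [], genome, mode="full_sequence")["c"]
        features = build_structures([circ], [], genome, mode="features")["c"]
        assert default.sequence == features.sequence
        assert default.blocks == features.blocks


class TestAssemble:
    GENOME = GenomeAccessor.from_dict({"chr1": "AAACGTACAAA"})

    def test_plus_strand(self):
        seq, _ = assemble_sequence(
            [GenomicInterval("chr1", 3, 8)], "+", self.GENOME
        )
        assert seq == "CGUAC"

    def test_minus_strand_reverse_complement(self):
        seq, _ = assemble_sequence(
            [GenomicInterval("chr1", 3, 8, strand="-")], "-", self.GENOME
        )
        assert seq == "GUACG"

    def test_length_conserved_across_blocks(self):
        seq, cmap = assemble_sequence(
            [GenomicInterval("chr1", 3, 5), GenomicInterval("chr1", 8, 10)],
            "+", self.GENOME,
        )
        assert len(seq) == 4 == cmap.length

    def test_out_of_bounds_block_errors(self):
        with pytest.raises(ValueError, match="bounds"):
            assemble_sequence([GenomicInterval("chr1", 5, 100)], "+", self.GENOME)


class TestCoordinateMap:
    def test_plus_strand_offset(self):
        cmap = CoordinateMap((GenomicInterval("chr1", 100, 200),), "+")
        assert [(i.start, i.end) for i in cmap.map_to_genome(10, 20)] == [(110, 120)]

    def test_minus_strand_window_zero_maps_to_right_edge(self):
        cmap = CoordinateMap((GenomicInterval("chr1", 100, 200, strand="-"),), "-")
        assert [(i.start, i.end) for i in cmap.map_to_genome(0, 10)] == [(190, 200)]

    def test_junction_spanning_window(self):
        cmap = CoordinateMap(
            (GenomicInterval("chr1", 100, 150), GenomicInterval("chr1", 300, 400)), "+"
        )
        assert [(i.start, i.end) for i in cmap.map_to_genome(45, 55)] == [
            (145, 150), (300, 305),
        ]

    def test_out_of_range_errors(self):
        cmap = CoordinateMap((GenomicInterval("chr1", 100, 200),), "+")
        with pytest.raises(ValueError):
            cmap.map_to_genome(90, 101)

    def test_wrap_addresses_backsplice_junction(self):
        cmap = CoordinateMap((GenomicInterval("chr1", 100, 150),), "+", wrap=10)
        pieces = cmap.map_to_genome(45, 55)
        assert [(i.start, i.end) for i in pieces] == [(100, 105), (145, 150)]
        assert sum(len(i) for i in pieces) == 10


def random_structure(rng):
    n_blocks = int(rng.integers(1, 5))
    pos = 0
    blocks = []
    for _ in range(n_blocks):
        pos += int(rng.integers(1, 30))
        length = int(rng.integers(1, 40))
        blocks.append((pos, pos + length))
        pos += length
    strand = "+" if rng.random() < 0.5 else "-"
    return blocks, strand


class TestMappingProperties:
    """Round trip, length conservation, monotonicity and per-base agreement."""

    def test_roundtrip_and_per_base_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            blocks, strand = random_structure(rng)
            end = max(e for _, e in blocks)
            genome = GenomeAccessor.from_dict(
                {"chr1": "".join(rng.choice(list("ACGT"), size=end + 5))}
            )
            ivs = tuple(GenomicInterval("chr1", s, e, strand=strand) for s, e in blocks)
            seq, cmap = assemble_sequence(ivs, strand, genome)
            total = cmap.length
            t0 = int(rng.integers(0, total))
            t1 = int(rng.integers(t0 + 1, total + 1))
            pieces = cmap.map_to_genome(t0, t1)
            # conservation
            assert sum(len(p) for p in pieces) == t1 - t0
            # agreement with the per-base brute-force mapper
            assert [(p.start, p.end) for p in pieces] == per_base_map(ivs, strand, t0, t1)
            # round trip: re-extracting the genomic pieces reproduces the window
            sub, _ = assemble_sequence(pieces, strand, genome)
            assert sub == seq[t0:t1]
            # monotonicity on the minus strand
            if strand == "-" and t1 - t0 > 1:
                g = [cmap.genome_position(t) for t in range(t0, t1)]
                assert all(a > b for a, b in zip(g, g[1:]))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        gaps=st.lists(st.tuples(st.integers(1, 20), st.integers(1, 30)),
                      min_size=1, max_size=4),
        minus=st.booleans(),
        data=st.data(),
    )
    def test_map_is_bijective(self, gaps, minus, data):
        """Every transcript position maps to a distinct genomic base inside a
        block, and the interval mapper covers exactly those bases."""
        pos, blocks = 0, []
        for gap, length in gaps:
            pos += gap
            blocks.append(GenomicInterval("chr1", pos, pos + length))
            pos += length
        strand = "-" if minus else "+"
        cmap = CoordinateMap(tuple(blocks), strand)
        positions = [cmap.genome_position(t) for t in range(cmap.length)]
        assert len(set(positions)) == cmap.length
        assert all(any(b.start <= g < b.end for b in blocks) for g in positions)
        t0 = data.draw(st.integers(0, cmap.length - 1))
        t1 = data.draw(st.integers(t0 + 1, cmap.length))
        covered = sorted(
            g for iv in cmap.map_to_genome(t0, t1) for g in range(iv.start, iv.end)
        )
        assert covered == sorted(positions[t0:t1])
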