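"""The three prediction engines against their brute-force reference oracles."""

import numpy as np
import pytest

from circmir import (
    EnergyModel,
    MiRNA,
    MirandaParams,
    classify_seed,
    duplex_mfe,
    hybridize_mfe,
    local_align_score,
    run_engines,
    scan_seed_sites,
)
from circmir.engines import ConfigurationError, best_local_alignment
from circmir.validation import (
    enumerate_all_duplex_energies,
    enumerate_alignment_score,
    enumerate_duplex_mfe,
    exhaustive_seed_scan,
    recursive_alignment_score,
)

MIR = "UAGCUUAUCAGACUGAUGUUGA"  # let-7-like reference miRNA


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestClassifySeed:
    def pairing_for(self, window, offset=0):
        """Antiparallel full pairing of MIR positions 1..8 over an 8-nt window."""
        return {p: offset + 8 - p for p in range(1, 9)}

    def test_8mer(self):
        window = "AUAAGCUA"  # revcomp(seed 2-8) + A
        assert classify_seed(MIR, window, self.pairing_for(window)) == "8mer"

    def test_7mer_m8_when_no_a1(self):
        window = "AUAAGCUU"
        assert classify_seed(MIR, window, self.pairing_for(window)) == "7mer-m8"

    def test_wobble_in_seed_breaks_it(self):
        # G:U opposite position 5 (U): target G instead of A
        window = "AUAGGCUU"
        assert classify_seed(MIR, window, self.pairing_for(window)) == "none"

    def test_noncontiguous_seed_pairing_does_not_count(self):
        # positions 2-8 WC paired but with a bulged target base inside
        window = "AUAAGXCUA"
        pairing = {1: 8, 2: 7, 3: 6, 4: 5, 5: 4, 6: 3, 7: 2, 8: 0}
        assert classify_seed(MIR, window, pairing) == "none"


class TestSeedScan:
    def test_planted_8mer_window(self):
        sites = scan_seed_sites(MIR, "GGGAUAAGCUAGGG")
        assert (sites[0].t_start, sites[0].t_end, sites[0].seed_category) == (3, 11, "8mer")

    def test_no_complementarity_is_empty(self):
        assert scan_seed_sites(MIR, "GGGGGGGGGGGG") == []

    def test_two_copies_reported_twice(self):
        transcript = "GGGAUAAGCUAGGGCCAUAAGCUACC"
        eights = [s for s in scan_seed_sites(MIR, transcript) if s.seed_category == "8mer"]
        assert len(eights) == 2

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            mir = random_rna(rng, int(rng.integers(15, 25)))
            transcript = random_rna(rng, int(rng.integers(20, 80)))
            got = [(s.t_start, s.t_end, s.seed_category)
                   for s in scan_seed_sites(mir, transcript)]
            assert got == exhaustive_seed_scan(mir, transcript)

    def test_no_duplicate_footprints(self):
        rng = np.random.default_rng(3)
        transcript = random_rna(rng, 300)
        sites = scan_seed_sites(MIR, transcript + "AUAAGCUA" + transcript)
        keys = [(s.engine, s.t_start, s.t_end) for s in sites]
        assert len(keys) == len(set(keys))


class TestDuplexEngine:
    MODEL = EnergyModel()

    def test_perfect_duplex_energy_is_init_plus_stacks(self):
        expected = self.MODEL.init + (
            self.MODEL.stack_energy("UA", "AU")
            + self.MODEL.stack_energy("AU", "GC")
            + self.MODEL.stack_energy("GC", "CG")
        )
        assert duplex_mfe("UAGC", "GCUA", self.MODEL) == pytest.approx(expected)

    def test_no_pairable_bases_is_empty(self):
        assert hybridize_mfe("AAAA", "CCCC", self.MODEL, e_threshold=-1.0) == []

    def test_nonnegative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            hybridize_mfe("UAGC", "GCUA", self.MODEL, e_threshold=0.0)

    def test_mfe_matches_structure_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(120):
            mir = random_rna(rng, int(rng.integers(2, 9)))
            window = random_rna(rng, int(rng.integers(2, 13)))
            fast = duplex_mfe(mir, window, self.MODEL)
            slow = enumerate_duplex_mfe(mir, window, self.MODEL)
            assert fast == pytest.approx(slow)

    def test_memoized_oracle_matches_full_enumeration(self):
        """The memoized recursion is itself checked against generate-everything."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            mir = random_rna(rng, int(rng.integers(2, 6)))
            window = random_rna(rng, int(rng.integers(2, 7)))
            energies = enumerate_all_duplex_energies(mir, window, self.MODEL)
            expected = min(energies) if energies else float("inf")
            assert enumerate_duplex_mfe(mir, window, self.MODEL) == pytest.approx(expected)

    def test_energy_monotone_under_helix_extension(self):
        """Extending a perfect complementary duplex never raises the energy."""
        rng = np.random.default_rng(9)
        from circmir.builder import reverse_complement_rna

        mir = random_rna(rng, 20)
        energies = []
        for k in range(4, 21):
            prefix = mir[:k]
            energies.append(duplex_mfe(prefix, reverse_complement_rna(prefix), self.MODEL))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_strong_site_reported_with_trace(self):
        from circmir.builder import reverse_complement_rna

        transcript = "GGGG" + reverse_complement_rna(MIR) + "GGGG"
        sites = hybridize_mfe(MIR, transcript, self.MODEL, e_threshold=-20.0)
        assert len(sites) == 1
        (site,) = sites
        assert site.score < -20.0
        assert site.t_start >= 4 and site.t_end <= 4 + len(MIR)
        assert "|" in site.alignment


class TestAlignmentEngine:
    MODEL = EnergyModel()

    def test_perfect_unscaled_match_score(self):
        params = MirandaParams(scale=1.0, score_threshold=10.0)
        aln = best_local_alignment("UAGC", "GCUA", params)
        assert aln.score == 20.0  # 4 matches x 5

    def test_wobble_marked_with_colon(self):
        from circmir.builder import reverse_complement_rna

        site = list(reverse_complement_rna(MIR))
        # replace the base opposite miRNA position 12 (A) with G -> no pair;
        # instead make a G:U wobble: miRNA G pairs target U
        g_pos = MIR.index("G", 8)  # a G in the miRNA 3' region
        site[len(MIR) - 1 - g_pos] = "U"
        transcript = "CCC" + "".join(site) + "CCC"
        sites = local_align_score(MIR, transcript, MirandaParams(), self.MODEL)
        assert len(sites) == 1
        midline = sites[0].alignment.splitlines()[1]
        assert midline.count(":") == 1

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ConfigurationError):
            MirandaParams(match=float("nan")).validate()

    def test_score_matches_recursive_oracle(self):
        rng = np.random.default_rng(31)
        params = MirandaParams()
        for _ in range(200):
            mir = random_rna(rng, int(rng.integers(2, 7)))
            target = random_rna(rng, int(rng.integers(2, 11)))
            aln = best_local_alignment(mir, target, params)
            fast = aln.score if aln else 0.0
            assert fast == pytest.approx(recursive_alignment_score(mir, target, params))

    def test_recursive_oracle_matches_path_enumeration(self):
        rng = np.random.default_rng(13)
        params = MirandaParams()
        for _ in range(15):
            mir = random_rna(rng, int(rng.integers(2, 5)))
            target = random_rna(rng, int(rng.integers(2, 7)))
            assert recursive_alignment_score(mir, target, params) == pytest.approx(
                enumerate_alignment_score(mir, target, params)
            )

    def test_score_invariant_to_context_outside_footprint(self):
        from circmir.builder import reverse_complement_rna

        rng = np.random.default_rng(17)
        site = reverse_complement_rna(MIR)
        scores = []
        for _ in range(5):
            left = random_rna(rng, int(rng.integers(5, 40)))
            right = random_rna(rng, int(rng.integers(5, 40)))
            sites = local_align_score(MIR, left + site + right, MirandaParams(), self.MODEL)
            best = max(s.score for s in sites)
            scores.append(best)
        assert len(set(scores)) == 1


class TestRunEngines:
    def test_all_engines_find_a_planted_strong_site(self, fixture, fixture_run):
        report, _, _ = fixture_run
        assert set(report.n_sites_per_engine) == {"M", "RH", "TS"}

    def test_no_mirnas_is_empty(self):
        out = run_engines([], {})
        assert out.sites == [] and out.failures == []

    def test_site_invariants(self, fixture):
        from circmir import GenomeAccessor, build_structures, read_bed, read_gtf, read_mirna_fasta

        genome = GenomeAccessor.from_fasta(fixture.genome_fa)
        structures = build_structures(
            read_bed(fixture.circ_bed), read_gtf(fixture.gtf), genome
        )
        mirnas = read_mirna_fasta(fixture.mirna_fa)
        out = run_engines(mirnas, structures)
        keys = set()
        for s in out.sites:
            length = structures[s.circ_name].length
            assert 0 <= s.t_start < s.t_end <= length
            key = (s.engine, s.mirna_name, s.circ_name, s.t_start, s.t_end)
            assert key not in keys
            keys.add(key)
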