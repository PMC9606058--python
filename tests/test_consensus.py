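import numpy as np
import pytest

from museomito import (
    CircularSequence,
    DamageModel,
    FragmentModel,
    SimConfig,
    call_consensus,
    call_homopolymer_indels,
    mask_regions,
    pileup,
    recover_terminal,
    simulate_readset,
)
from museomito.consensus import (
    ConsensusResult,
    Pileup,
    apply_indels,
    consensus_from_reads,
    masked_site_count,
    read_mask_bed,
    write_mask_bed,
)
from museomito.mapping import AlignedRead, SeedIndex, map_reads, mark_duplicates, filter_alignments


def _aln(rid, start, ref, seq, strand="+"):
    sub = ref.fetch(start, len(seq))
    return AlignedRead(rid, start, strand, list(zip(sub, seq)), 0)


class TestPileup:
    def test_single_read_depth_one(self, toy_genome):
        p = pileup([_aln("r", 1, toy_genome, toy_genome.fetch(1, 3))], toy_genome)
        assert p.depth[:4].tolist() == [1, 1, 1, 0]

    def test_overlapping_reads_sum(self, toy_genome):
        alns = [
            _aln("a", 1, toy_genome, toy_genome.fetch(1, 10)),
            _aln("b", 5, toy_genome, toy_genome.fetch(5, 10)),
        ]
        p = pileup(alns, toy_genome)
        assert p.depth[0] == 1 and p.depth[6] == 2

    def test_origin_wrapping_read(self, toy_genome):
        L = len(toy_genome)
        p = pileup([_aln("r", L - 4, toy_genome, toy_genome.fetch(L - 4, 10))], toy_genome)
        assert p.depth[L - 5] == 1 and p.depth[0] == 1 and p.depth[4] == 1

    def test_rotation_equivariance(self, toy_genome):
        # pileup in a rotated frame equals the unrotated pileup after
        # back-transforming coordinates
        rot = 150
        rotated = toy_genome.rotate(rot)
        reads = [toy_genome.fetch(1 + 37 * i, 30) for i in range(40)]
        idx_plain = SeedIndex(toy_genome)
        idx_rot = SeedIndex(rotated)
        named = [(f"r{i}", s) for i, s in enumerate(reads)]
        a_plain, _ = map_reads(named, idx_plain)
        a_rot, _ = map_reads(named, idx_rot)
        p_plain = pileup(a_plain, toy_genome).counts
        p_rot = pileup(a_rot, rotated).counts
        back = np.roll(p_rot, rot, axis=1)
        assert np.array_equal(p_plain, back)


class TestCallConsensus:
    def test_depth_two_gives_n(self):
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[0, 0] = 2  # A:2, below the min depth of 3
        assert call_consensus(Pileup(1, counts)).sequence == "N"

    def test_tie_gives_n(self):
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[0, 0] = 2
        counts[2, 0] = 2  # A:2 G:2 at depth 4
        assert call_consensus(Pileup(1, counts)).sequence == "N"

    def test_majority_called_at_depth_three(self):
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[3, 0] = 2
        counts[1, 0] = 1
        assert call_consensus(Pileup(1, counts)).sequence == "T"

    def test_error_free_simulation_recovers_planted_genome(self, full_genome):
        from museomito.simulate import plant_variants, table2_like_variants

        variants = table2_like_variants(full_genome, 31)  # substitutions only
        mutated, _ = plant_variants(full_genome, variants)
        dm = DamageModel(p_max=0.0, p_base=0.0, seq_error=0.0)
        rs = simulate_readset(mutated, FragmentModel(), dm, SimConfig(target_depth=35, seed=4))
        cons, _, _ = consensus_from_reads(rs.reads, full_genome)
        assert len(cons.sequence) == len(mutated)
        mismatches = [
            i + 1
            for i, (c, t) in enumerate(zip(cons.sequence, mutated.residues))
            if c != "N" and c != t
        ]
        assert mismatches == []
        assert cons.called_fraction > 0.99

    def test_consensus_invariant_to_read_order(self, toy_genome):
        dm = DamageModel(p_max=0.1, p_base=0.01, seq_error=0.001)
        rs = simulate_readset(toy_genome, FragmentModel(), dm, SimConfig(target_depth=8, seed=9))
        c1, _, _ = consensus_from_reads(rs.reads, toy_genome)
        c2, _, _ = consensus_from_reads(list(reversed(rs.reads)), toy_genome)
        assert c1.sequence == c2.sequence


class TestRecoverTerminal:
    def test_rotation_zero_identical_to_single_pass(self, toy_genome):
        dm = DamageModel(p_max=0, p_base=0, seq_error=0)
        rs = simulate_readset(toy_genome, FragmentModel(), dm, SimConfig(target_depth=10, seed=2))
        single, _, _ = consensus_from_reads(rs.reads, toy_genome)
        merged = recover_terminal(rs.reads, toy_genome, rotation_bp=0)
        assert merged.sequence == single.sequence

    def test_origin_spanning_reads_recover_terminals(self, toy_genome):
        # reads drawn only across the origin: a single unrotated pass cannot
        # anchor them (no seeds fully inside), the rotated pass can
        L = len(toy_genome)
        reads = []
        for i in range(60):
            start = L - 20 - (i % 10)
            reads.append((f"r{i}", toy_genome.fetch(start, 40)))
        merged = recover_terminal(reads, toy_genome, rotation_bp=200)
        # terminal bases called from the rotated pass
        assert merged.sequence[0] != "N" or merged.sequence[-1] != "N"
        for i, b in enumerate(merged.sequence):
            if b != "N":
                assert b == toy_genome.residues[i]

    def test_passes_agree_on_deep_error_free_data(self, toy_genome):
        dm = DamageModel(p_max=0, p_base=0, seq_error=0)
        rs = simulate_readset(toy_genome, FragmentModel(), dm, SimConfig(target_depth=30, seed=3))
        merged = recover_terminal(rs.reads, toy_genome, rotation_bp=200)
        assert merged.sequence == toy_genome.residues

    def test_non_circular_refused(self):
        lin = CircularSequence("lin", "ACGT" * 100, circular=False)
        with pytest.raises(ValueError):
            recover_terminal([], lin)


class TestMasking:
    def test_paper_style_manual_intervals_mask_510_sites(self, full_genome):
        res = ConsensusResult(full_genome.residues)
        masked = mask_regions(
            res, full_genome, manual_intervals=[(15192, 15294), (16856, 17262)]
        )
        assert masked.sequence.count("N") - full_genome.residues.count("N") == 510
        assert masked_site_count([(15192, 15294), (16856, 17262)]) == 510

    def test_called_fraction_after_masking(self, full_genome):
        res = ConsensusResult(full_genome.residues)
        masked = mask_regions(
            res, full_genome, manual_intervals=[(15192, 15294), (16856, 17262)]
        )
        assert abs(masked.called_fraction - (17408 - 510) / 17408) < 1e-12

    def test_long_homopolymer_auto_masked(self):
        ref = CircularSequence("r", "ACGT" * 30 + "A" * 80 + "CGTA" * 30)
        res = ConsensusResult(ref.residues)
        masked = mask_regions(res, ref, read_len_max=75)
        assert masked.sequence[120:200] == "N" * 80

    def test_tandem_repeat_auto_masked(self):
        unit = "ACGGT"
        ref = CircularSequence("r", "TTAACCGGTTAA" * 10 + unit * 20 + "GGTTAACCGGTT" * 10)
        res = ConsensusResult(ref.residues)
        masked = mask_regions(res, ref, read_len_max=75)
        assert "N" * 100 in masked.sequence

    def test_no_qualifying_repeats_no_change(self, toy_genome):
        res = ConsensusResult(toy_genome.residues)
        masked = mask_regions(res, toy_genome, read_len_max=75)
        assert masked.sequence == toy_genome.residues

    def test_overlapping_manual_intervals_merged(self, toy_genome):
        res = ConsensusResult(toy_genome.residues)
        masked = mask_regions(res, toy_genome, manual_intervals=[(10, 30), (20, 40)])
        manual = [iv for iv in masked.mask_intervals if iv[2] == "manual"]
        assert manual == [(10, 40, "manual")]

    def test_bed_round_trip_converts_coordinates(self, tmp_path):
        intervals = [(15192, 15294, "manual"), (16856, 17262, "manual")]
        p = tmp_path / "mask.bed"
        write_mask_bed(p, intervals, "chrM")
        line = p.read_text().splitlines()[0].split("\t")
        assert (line[1], line[2]) == ("15191", "15294")  # 0-based half-open
        assert read_mask_bed(p) == intervals


class TestHomopolymerIndels:
    def _reads_over_run(self, ref, run_start, run_len, observed, n_reads):
        """Reads spanning the run but carrying ``observed`` run bases; the
        flank beyond the run is kept short so an ungapped aligner accepts
        the shifted tail within its mismatch cap."""
        base = ref.residues[run_start - 1]
        reads = []
        for i in range(n_reads):
            start = run_start - 14 - i
            left = ref.fetch(start, run_start - start)
            right_start = run_start + run_len
            right = ref.fetch(right_start, 2)
            reads.append((f"hp{i}", left + base * observed + right))
        return reads

    def test_two_spanning_reads_one_fewer_repeat(self, full_genome):
        # 14-C run, both spanning reads show 13 Cs, none show 14
        run_start, run_len = 15986, 14
        reads = self._reads_over_run(full_genome, run_start, run_len, 13, 2)
        idx = SeedIndex(full_genome)
        alns, _ = map_reads(reads, idx)
        cands = call_homopolymer_indels(alns, full_genome)
        match = [c for c in cands if c.site == run_start]
        assert len(match) == 1
        c = match[0]
        assert (len(c.ref_allele), len(c.alt_allele)) == (14, 13)
        assert (c.support, c.spanning) == (2, 2)
        assert c.flag == "manual-confirmation"

    def test_single_supporting_read_no_candidate(self, full_genome):
        reads = self._reads_over_run(full_genome, 15986, 14, 13, 1)
        idx = SeedIndex(full_genome)
        alns, _ = map_reads(reads, idx)
        assert [c for c in call_homopolymer_indels(alns, full_genome) if c.site == 15986] == []

    def test_reference_supporting_read_vetoes(self, full_genome):
        reads = self._reads_over_run(full_genome, 15986, 14, 13, 2)
        reads += self._reads_over_run(full_genome, 15986, 14, 14, 1)
        idx = SeedIndex(full_genome)
        alns, _ = map_reads(reads, idx)
        assert [c for c in call_homopolymer_indels(alns, full_genome) if c.site == 15986] == []

    def test_planted_deletion_recovered_in_simulation(self, full_genome, planted):
        variants, mutated, _ = planted
        dm = DamageModel(p_max=0, p_base=0, seq_error=0)
        rs = simulate_readset(mutated, FragmentModel(), dm, SimConfig(target_depth=35, seed=6))
        idx = SeedIndex(full_genome)
        alns, _ = map_reads(rs.reads, idx)
        kept, _ = filter_alignments(mark_duplicates(alns))
        cands = call_homopolymer_indels(kept, full_genome)
        hits = [c for c in cands if c.site == 15986 and len(c.alt_allele) == 13]
        assert len(hits) == 1
        assert hits[0].support >= 2


def test_apply_indels_shifts_coordinates():
    from museomito.consensus import IndelCandidate

    seq = "AACCCCAA"
    cand = IndelCandidate(site=3, ref_allele="CCCC", alt_allele="CCC", support=2, spanning=2)
    edited, cmap = apply_indels(seq, [cand])
    assert edited == "AACCCAA"
    assert cmap[8] == 7  # downstream coordinates shift left by one
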