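import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from museomito import (
    CircularSequence,
    Feature,
    SequenceAlignment,
    align_pair,
    annotate_codon,
    classify_ts_tv,
    difference_counts,
    distance_matrix,
    load_builtin_differences,
    pairwise_differences,
    reclassify_differences,
    summarize_pair,
    translate_codon,
)
from museomito.compare import write_differences, write_distance_matrix
from museomito.io import reverse_complement


class TestTsTv:
    @pytest.mark.parametrize(
        "r,a,expected",
        [
            ("A", "G", "transition"),
            ("C", "T", "transition"),
            ("T", "G", "transversion"),
            ("A", "C", "transversion"),
            ("G", "C", "transversion"),
        ],
    )
    def test_definition(self, r, a, expected):
        assert classify_ts_tv(r, a) == expected

    def test_identical_bases_refused(self):
        with pytest.raises(ValueError):
            classify_ts_tv("A", "A")

    def test_published_difference_set_reclassifies(self):
        # 26 substitutions -> 21 transitions + 5 transversions, recomputed
        recs = reclassify_differences(load_builtin_differences())
        counts = difference_counts(recs)
        assert counts["transitions"] == 21
        assert counts["transversions"] == 5
        assert counts["transitions"] + counts["transversions"] == counts["substitutions"]


class TestGeneticCode:
    def test_mito_specific_codons(self):
        assert translate_codon("TGA") == "W"  # stop in the standard code
        assert translate_codon("ATA") == "M"
        assert translate_codon("AGA") == "*"
        assert translate_codon("AGG") == "*"
        assert translate_codon("TGA", code="standard") == "*"

    def test_tgg_tga_synonymous_only_mitochondrially(self):
        assert translate_codon("TGG") == translate_codon("TGA") == "W"
        assert translate_codon("TGG", "standard") != translate_codon("TGA", "standard")

    def test_published_amino_acid_changes_recomputed(self):
        recs = reclassify_differences(load_builtin_differences())
        aa = {
            r.site: f"{r.ref_aa}/{r.alt_aa}"
            for r in recs
            if r.synonymous is False
        }
        assert aa == {
            4410: "G/D",
            4994: "T/A",
            8650: "G/D",
            11617: "F/L",
            15568: "E/A",
            15647: "S/A",
        }


@pytest.fixture()
def coding_genome():
    """60 bp linear genome with a + strand gene, a - strand gene and a
    control region, for codon annotation."""
    #           1-15: plus gene ATG GGC GAG TGG AAA
    plus = "ATGGGCGAGTGGAAA"
    # 21-35: minus-strand gene, coding seq ATG ACC TTT TAA -> genome revcomp
    minus_coding = "ATGACCTTTTAG"
    genome = plus + "TTTTT" + reverse_complement(minus_coding) + "TTTTT" + "ACGTACGTACGTACGT"
    seq = CircularSequence("g", genome, circular=False)
    feats = [
        Feature("plusgene", "protein_coding", 1, 15, "+"),
        Feature("minusgene", "protein_coding", 21, 32, "-"),
        Feature("ctrl", "control_region", 38, 53, "+"),
    ]
    return seq, feats


class TestAnnotateCodon:
    def test_plus_strand_nonsynonymous(self, coding_genome):
        seq, feats = coding_genome
        # site 5: codon 2 (GGC), position 2, G->A gives GAC: G/D
        ann = annotate_codon(5, seq, "A", feats)
        assert ann == (2, "ggc", "gac", "G", "D", False)

    def test_plus_strand_mito_synonymous_tgg_tga(self, coding_genome):
        seq, feats = coding_genome
        # site 12: codon 4 (TGG), position 3, G->A gives TGA: W/W mitochondrially
        ann = annotate_codon(12, seq, "A", feats)
        assert ann == (3, "tgg", "tga", "W", "W", True)

    def test_minus_strand_codons_reported_in_coding_orientation(self, coding_genome):
        seq, feats = coding_genome
        # minus gene codon 2 is ACC; its middle base sits at genome site 28
        # (genome base G); genome G->C is coding C->G: ACC->AGC, T/S
        assert seq.residues[27] == "G"
        ann = annotate_codon(28, seq, "C", feats)
        assert ann == (2, "acc", "agc", "T", "S", False)

    def test_non_coding_site_returns_none(self, coding_genome):
        seq, feats = coding_genome
        assert annotate_codon(40, seq, "A", feats) is None

    def test_phase_shifts_frame(self):
        seq = CircularSequence("g", "TATGGGC", circular=False)
        feats = [Feature("g1", "protein_coding", 1, 7, "+", phase=1)]
        ann = annotate_codon(3, seq, "C", feats)  # codon ATG position 2
        assert ann[:3] == (2, "atg", "acg")


class TestPairwiseDifferences:
    def test_identical_sequences_empty(self):
        aln = SequenceAlignment([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert pairwise_differences(aln) == []

    def test_n_columns_skipped(self):
        aln = SequenceAlignment([("a", "ACGT"), ("b", "ANGA")])
        recs = pairwise_differences(aln)
        assert [(r.site, r.ref_base, r.alt_base) for r in recs] == [(4, "T", "A")]

    def test_gap_run_single_indel_record(self):
        aln = SequenceAlignment([("a", "ACCCTA"), ("b", "AC--TA")])
        recs = pairwise_differences(aln)
        assert len(recs) == 1
        r = recs[0]
        assert r.kind == "indel" and r.ts_tv is None
        assert r.ref_base == "CC" and r.alt_base == "-"

    def test_homopolymer_single_base_deletion(self):
        # one C missing from a C run: one indel record, ts/tv not applicable
        aln = SequenceAlignment(
            [("a", "TTCCCCCCCCCCCCCCAA"), ("b", "TTCCCCCCCCCCCCC-AA")]
        )
        recs = pairwise_differences(aln)
        assert len(recs) == 1
        assert recs[0].kind == "indel" and recs[0].ts_tv is None

    def test_sites_in_reference_ungapped_frame(self):
        # an insertion in the second sequence must not shift reference sites
        aln = SequenceAlignment([("a", "AC-GTT"), ("b", "ACAGAT")])
        recs = pairwise_differences(aln)
        subs = [r for r in recs if r.kind == "substitution"]
        assert [(r.site, r.ref_base, r.alt_base) for r in subs] == [(4, "T", "A")]
        indels = [r for r in recs if r.kind == "indel"]
        assert len(indels) == 1 and indels[0].site == 2

    def test_planted_variant_round_trip(self, full_genome, planted):
        variants, mutated, _ = planted
        aln = align_pair(full_genome, mutated)
        recs = pairwise_differences(aln)
        found = {(r.site, r.alt_base) for r in recs if r.kind == "substitution"}
        truth = {(v.site, v.alt) for v in variants if v.kind == "substitution"}
        assert found == truth
        assert sum(1 for r in recs if r.kind == "indel") == 1


class TestSummaries:
    def test_headline_percent_divergence(self):
        recs = reclassify_differences(load_builtin_differences())
        s = summarize_pair(recs, covered_length=17408)
        assert len(recs) == 27
        assert round(s.percent_divergence, 2) == 0.16

    def test_empty_differences_zero_rates(self):
        s = summarize_pair([], covered_length=1000)
        assert s.percent_divergence == 0 and s.rate_overall == 0

    def test_region_split_bookkeeping(self, full_genome, planted):
        variants, mutated, _ = planted
        aln = align_pair(full_genome, mutated)
        recs = pairwise_differences(aln)
        region = [(15301, 17408)]
        s = summarize_pair(recs, region, covered_length=17408)
        in_region = sum(
            1 for v in variants if v.kind == "substitution" and 15301 <= v.site <= 17408
        )
        assert s.substitutions == 26
        assert s.substitutions_excl == 26 - in_region
        assert s.substitutions_excl + in_region == s.substitutions

    def test_published_set_region_structure(self):
        # sites in the high-divergence tail: 9 substitutions and the single
        # indel, leaving 17 substitutions and 0 indels outside
        recs = reclassify_differences(load_builtin_differences())
        s = summarize_pair(recs, excluded_region=[(15301, 17408)], covered_length=17408)
        assert (s.substitutions, s.indels) == (26, 1)
        assert (s.substitutions_excl, s.indels_excl) == (17, 0)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = SequenceAlignment([("a", "ACGT"), ("b", "ACGT")])
        assert distance_matrix(aln)[0, 1] == 0

    def test_simple_quarter(self):
        aln = SequenceAlignment([("a", "ACGT"), ("b", "ACGA")])
        assert distance_matrix(aln)[0, 1] == 0.25

    def test_pairwise_deletion_hand_count(self):
        # N column excluded: 1 difference over 3 compared sites
        aln = SequenceAlignment([("a", "ACNT"), ("b", "ACGA")])
        assert distance_matrix(aln)[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_nan(self):
        aln = SequenceAlignment([("a", "NN"), ("b", "AC")])
        assert np.isnan(distance_matrix(aln)[0, 1])

    @settings(max_examples=30, deadline=None)
    @given(
        rows=st.lists(
            st.text(alphabet="ACGTN-", min_size=8, max_size=8), min_size=2, max_size=5
        )
    )
    def test_symmetry_zero_diagonal_and_n_column_invariance(self, rows):
        aln = SequenceAlignment([(f"s{i}", r) for i, r in enumerate(rows)])
        D = distance_matrix(aln)
        assert np.allclose(D, D.T, equal_nan=True)
        assert np.all(np.diag(D) == 0)
        aln2 = SequenceAlignment([(f"s{i}", r + "N") for i, r in enumerate(rows)])
        D2 = distance_matrix(aln2)
        assert np.allclose(D, D2, equal_nan=True)

    def test_phylip_export(self, tmp_path):
        aln = SequenceAlignment([("a", "ACGT"), ("b", "ACGA"), ("c", "NNNN")])
        p = tmp_path / "dist.phy"
        write_distance_matrix(p, aln, distance_matrix(aln))
        lines = p.read_text().splitlines()
        assert lines[0] == "3"
        assert "NA" in lines[3]


def test_ts_plus_tv_equals_substitutions_property(full_genome, planted):
    variants, mutated, _ = planted
    recs = pairwise_differences(align_pair(full_genome, mutated))
    counts = difference_counts(recs)
    assert counts["transitions"] + counts["transversions"] == counts["substitutions"]


def test_difference_table_export(tmp_path):
    recs = reclassify_differences(load_builtin_differences())
    p = tmp_path / "diffs.tsv"
    write_differences(p, recs)
    lines = p.read_text().splitlines()
    assert len(lines) == 28  # header + 27 rows
    assert "4410" in lines[7]
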