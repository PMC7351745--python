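"""Canonicalisation, redundancy collapse and protein consequences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triad.genemodel import TargetGene, generate_synthetic_target
from triad.mechanism import TranspositionSite, apply_edit, enumerate_library, enumerate_sites
from triad.diversity import (
    PROTEIN_ALPHABET_FACTOR,
    canonicalize_deletion,
    canonicalize_edit,
    canonicalize_insertion,
    collapse_unique,
    per_position_diversity,
    protein_consequence,
    theoretical_diversity,
)

dna = st.text(alphabet="ACGT", min_size=6, max_size=30)


def deletion_placements(seq, start, length):
    """Brute force: all starts whose deletion gives the same string."""
    target = seq[:start] + seq[start + length:]
    return [r for r in range(len(seq) - length + 1)
            if seq[:r] + seq[r + length:] == target]


def insertion_placements(seq, point, ins):
    """Brute force: all points where some insert reproduces the mutant."""
    mutant = seq[:point] + ins + seq[point:]
    k = len(ins)
    return [p for p in range(len(seq) + 1)
            if mutant == seq[:p] + mutant[p:p + k] + seq[p:]]


class TestCanonicalizeDeletion:
    def test_homopolymer_example(self):
        ce = canonicalize_deletion("AAAATTTT", 3, 1)
        assert ce.left_pos == 0
        assert ce.ambiguity == (0, 4)

    def test_unique_placement(self):
        ce = canonicalize_deletion("ACGTACGT", 4, 3)
        assert ce.left_pos == 4
        assert ce.ambiguity == (4, 5)

    @settings(max_examples=200, derandomize=True)
    @given(dna, st.integers(0, 25), st.sampled_from([1, 2, 3, 6]))
    def test_matches_brute_force(self, seq, start, length):
        if start + length > len(seq):
            start = len(seq) - length
        ce = canonicalize_deletion(seq, start, length)
        placements = deletion_placements(seq, start, length)
        assert ce.left_pos == min(placements)
        assert list(range(*ce.ambiguity)) == placements

    def test_idempotent(self):
        seq = "ACGGGGTACG"
        ce = canonicalize_deletion(seq, 4, 2)
        ce2 = canonicalize_deletion(seq, ce.left_pos, ce.length)
        assert ce == ce2


class TestCanonicalizeInsertion:
    @settings(max_examples=200, derandomize=True)
    @given(dna, st.integers(0, 30), st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_matches_brute_force(self, seq, point, ins):
        point = min(point, len(seq))
        ce = canonicalize_insertion(seq, point, ins)
        placements = insertion_placements(seq, point, ins)
        assert ce.left_pos == min(placements)
        assert list(range(*ce.ambiguity)) == placements
        # the left-aligned representation reproduces the same mutant
        assert (seq[:ce.left_pos] + ce.inserted + seq[ce.left_pos:]
                == seq[:point] + ins + seq[point:])

    def test_rotation_on_shift(self):
        # inserting GCA after "AGC" context shifts left with rotation
        ce = canonicalize_insertion("TAGCT", 4, "AGC")
        assert ce.left_pos < 4


class TestAmbiguityReapplication:
    def test_every_ambiguous_position_reproduces_mutant(self, toy60):
        from triad.diversity import apply_canonical

        seq = toy60.seq
        for v in enumerate_library(toy60, "del3"):
            ce = canonicalize_edit(toy60, v.edit)
            for p in range(*ce.ambiguity):
                assert seq[:p] + seq[p + ce.length:] == v.seq
        for v in enumerate_library(toy60, "ins3", "sampled:50:3"):
            ce = canonicalize_edit(toy60, v.edit)
            for p in range(*ce.ambiguity):
                assert apply_canonical(seq, ce, at=p) == v.seq


class TestCollapseUnique:
    def test_homopolymer_collapse(self):
        g = TargetGene("h", "A" * 12, 0, 12)
        variants = enumerate_library(g, "del3")
        groups = collapse_unique(variants, gene=g)
        assert len(groups) == 1  # every 3-bp deletion gives A*9

    def test_matches_string_set_oracle(self, toy60):
        variants = enumerate_library(toy60, "del3")
        groups = collapse_unique(variants, gene=toy60)
        assert len(groups) == len({v.seq for v in variants})

    def test_disjoint_edits_do_not_collapse(self):
        g = TargetGene("t", "ACGTGATCCATGCA" + "ATCG" * 4, 0, 30)
        v1 = apply_edit(g, "del3", TranspositionSite(0))
        v2 = apply_edit(g, "del3", TranspositionSite(8))
        assert len(collapse_unique([v1, v2], gene=g)) == 2

    def test_mixed_parents_rejected(self, toy60, gene999):
        v1 = apply_edit(toy60, "del3", TranspositionSite(0))
        v2 = apply_edit(gene999, "del3", TranspositionSite(0))
        with pytest.raises(ValueError):
            collapse_unique([v1, v2], gene=toy60)


class TestTheoreticalDiversity:
    def test_naive_counts(self, gene999):
        assert theoretical_diversity(gene999, "del3", "dna_naive").count == 995
        assert theoretical_diversity(gene999, "ins3", "dna_naive", orientations="A").count == 995 * 64

    def test_monotonicity_protein_dna_naive(self, toy60):
        for kind in ("del3", "ins3"):
            naive = theoretical_diversity(toy60, kind, "dna_naive").count
            unique = theoretical_diversity(toy60, kind, "dna_unique").count
            prot = theoretical_diversity(toy60, kind, "protein_unique").count
            assert prot <= unique <= naive

    def test_protein_estimation_factor_is_21(self, toy60):
        """Above the enumeration cap, each extra randomized triplet scales
        naive protein diversity by 20 amino acids + stop = 21."""
        ins6 = theoretical_diversity(toy60, "ins6", "protein_unique", cap=10_000)
        ins9 = theoretical_diversity(toy60, "ins9", "protein_unique", cap=10_000)
        assert ins9.estimated
        assert ins9.count / ins6.count == PROTEIN_ALPHABET_FACTOR


class TestPerPositionDiversity:
    def test_homopolymer_all_collapse_leftward(self):
        g = TargetGene("h", "A" * 12, 0, 12)
        counts = per_position_diversity(g, "del3")
        assert counts == {0: 1}

    def test_sum_matches_unique_total(self, toy60):
        for kind in ("del3", "ins3"):
            counts = per_position_diversity(toy60, kind)
            total = theoretical_diversity(toy60, kind, "dna_unique").count
            assert sum(counts.values()) == total

    def test_ins3_per_position_bounded_by_64(self, toy60):
        counts = per_position_diversity(toy60, "ins3", orientations="A")
        assert all(c <= 64 for c in counts.values())


class TestCrossCodonFraction:
    def test_exactly_two_thirds_off_frame(self, gene999):
        """A single-triplet deletion window starts at s+1; on a codon-aligned
        ORF exactly 2/3 of transposition positions are not codon-aligned."""
        sites = enumerate_sites(gene999, "del3")
        starts = [(s.s + 1 - gene999.orf_start) % 3 for s in sites]
        frac = sum(1 for x in starts if x != 0) / len(starts)
        # exact 2/3 up to the remainder of n_sites modulo 3
        assert abs(frac - 2 / 3) <= 1 / len(starts)


class TestProteinConsequence:
    def test_clean_codon_aligned_deletion(self, toy_codon_gene):
        v = apply_edit(toy_codon_gene, "del3", TranspositionSite(5))  # deletes [6,9) = CCC
        pc = protein_consequence(toy_codon_gene, v)
        assert pc.klass == "in_frame_clean"
        assert pc.deleted_residues == "P"

    def test_frameshift(self, toy_codon_gene):
        from triad.mechanism import EditSpec, Variant

        seq = toy_codon_gene.seq
        v = Variant(EditSpec("del1", TranspositionSite(4), "", deleted_interval=(5, 6)),
                    seq[:5] + seq[6:])
        assert protein_consequence(toy_codon_gene, v).klass == "frameshift"

    def test_twelve_bp_deletion_removes_four_residues(self):
        g = generate_synthetic_target(60, 0.5, 5)
        from triad.mechanism import EditSpec, Variant

        a = 12  # codon-aligned 12-bp deletion -> 4-residue deletion
        v = Variant(EditSpec("del12", TranspositionSite(a), "", deleted_interval=(a, a + 12)),
                    g.seq[:a] + g.seq[a + 12:])
        pc = protein_consequence(g, v)
        assert pc.klass in ("in_frame_clean", "in_frame_adjacent_sub")
        if pc.klass == "in_frame_clean":
            assert len(pc.deleted_residues) == 4

    def test_del3_classes_match_translate_and_diff_oracle(self, toy60):
        """Exhaustive check against an independent pattern-matching oracle."""
        from Bio.Seq import Seq

        wt = str(Seq(toy60.seq).translate())
        for v in enumerate_library(toy60, "del3"):
            mut = str(Seq(v.seq).translate())
            got = protein_consequence(toy60, v).klass
            if mut == wt:
                expected = "silent"
            elif any(mut == wt[:i] + wt[i + 1:] for i in range(len(wt))):
                expected = "in_frame_clean"
            elif mut.index("*") < len(mut) - 1 if "*" in mut else False:
                expected = "truncation"
            elif any(mut == wt[:i] + x + wt[i + 2:]
                     for i in range(len(wt) - 1) for x in set(mut)):
                expected = "in_frame_adjacent_sub"
            else:
                expected = "complex"
            assert got == expected, (v.edit, wt, mut)

    def test_insertion_with_stop_truncates(self, toy_codon_gene):
        v = apply_edit(toy_codon_gene, "ins3", TranspositionSite(1, "A"), "TAA")
        # insertion at point 6, codon-aligned: ATG AAA TAA ...
        assert protein_consequence(toy_codon_gene, v).klass == "truncation"
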