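"""Alignment, edit calling and ambiguity-aware aggregation.

The affine-gap aligner is cross-checked against an independent pure-Python
Gotoh dynamic program (written here, never imported from the package).
"""

import numpy as np
import pytest

from triad.genemodel import generate_synthetic_target
from triad.indelcaller import (
    AlignmentScoring,
    IndelCall,
    aggregate_counts,
    align_read,
    call_edits,
    merge_pair,
    process_reads,
    summarize_calls,
)

NEG = float("-inf")


def gotoh_score(ref, read, match=5.0, mismatch=-4.0, open_=15.0, ext=0.5,
                free_read_end_gaps=True):
    """Independent affine-gap DP oracle; gap of length L costs open + L*ext.

    With ``free_read_end_gaps`` the leading/trailing stretches of the
    reference not covered by the read cost nothing (semi-global).
    """
    n, m = len(ref), len(read)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in (mis)match
    D = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends with gap in read
    I = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends with gap in ref
    M[0][0] = 0.0
    for j in range(1, m + 1):
        I[0][j] = -(open_ + j * ext)
    for i in range(1, n + 1):
        D[i][0] = 0.0 if free_read_end_gaps else -(open_ + i * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            if j == m and free_read_end_gaps:
                D[i][j] = max(M[i - 1][j], D[i - 1][j], I[i - 1][j])
            else:
                D[i][j] = max(max(M[i - 1][j], I[i - 1][j]) - open_ - ext,
                              D[i - 1][j] - ext)
            I[i][j] = max(max(M[i][j - 1], D[i][j - 1]) - open_ - ext,
                          I[i][j - 1] - ext)
    return max(M[n][m], D[n][m], I[n][m])


class TestAlignRead:
    def test_identity(self):
        ref = "ACGTACGTACGT"
        aln = align_read(ref, ref)
        assert aln.score == 5.0 * len(ref)
        assert call_edits(aln).kind == "wildtype"

    def test_hand_scored_three_bp_gap(self):
        ref = "ACGTACGTACGT"
        read = ref[:3] + ref[6:]  # drop "TAC"
        aln = align_read(read, ref)
        assert aln.score == 9 * 5.0 - (15.0 + 3 * 0.5)

    @pytest.mark.parametrize("trial_block", range(4))
    def test_score_matches_dp_oracle(self, trial_block):
        """200 random <=40-bp instances against the independent DP."""
        rng = np.random.default_rng(100 + trial_block)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            n = int(rng.integers(10, 41))
            ref = "".join(rng.choice(bases, n))
            style = rng.integers(0, 3)
            if style == 0:  # random read
                read = "".join(rng.choice(bases, int(rng.integers(5, 30))))
            elif style == 1:  # substring with a deletion
                a = int(rng.integers(0, max(1, n - 8)))
                sub = ref[a: a + int(rng.integers(6, 9))]
                d = int(rng.integers(0, max(1, len(sub) - 2)))
                read = sub[:d] + sub[d + rng.integers(1, 3):]
            else:  # substring with an insertion
                a = int(rng.integers(0, max(1, n - 8)))
                sub = ref[a: a + int(rng.integers(6, 9))]
                p = int(rng.integers(0, len(sub) + 1))
                read = sub[:p] + "".join(rng.choice(bases, int(rng.integers(1, 4)))) + sub[p:]
            if not read:
                continue
            got = align_read(read, ref).score
            want = gotoh_score(ref, read)
            assert got == pytest.approx(want), (ref, read)


class TestCallEdits:
    def test_in_frame_deletion_round_trip(self, gene999):
        ref = gene999.seq
        read = ref[100:160] + ref[163:230]  # 3-bp deletion at 160
        c = call_edits(align_read(read, ref), "r1")
        assert c.kind == "deletion" and c.in_frame
        from triad.diversity import canonicalize_deletion

        ce = canonicalize_deletion(ref, 160, 3)
        assert c.left_pos == ce.left_pos and c.ambiguity == ce.ambiguity

    def test_one_bp_deletion_is_frameshift(self, gene999):
        ref = gene999.seq
        read = ref[100:160] + ref[161:230]
        c = call_edits(align_read(read, ref), "r1")
        assert c.kind == "frameshift" and not c.in_frame

    def test_insertion_call_reports_inserted_bases(self, gene999):
        ref = gene999.seq
        read = ref[300:360] + "TTAGGG" + ref[360:420]
        c = call_edits(align_read(read, ref), "r1")
        assert c.kind == "insertion" and c.length == 6 and c.in_frame
        mutant = ref[:360] + "TTAGGG" + ref[360:]
        assert mutant[c.left_pos: c.left_pos + 6] == c.inserted

    def test_isolated_mismatch_is_wildtype(self, gene999):
        ref = gene999.seq
        read = list(ref[200:320])
        read[60] = "A" if read[60] != "A" else "C"
        c = call_edits(align_read("".join(read), ref), "r1")
        assert c.kind == "wildtype" and c.n_mismatches == 1

    def test_triplet_substitution_run(self, gene999):
        ref = gene999.seq
        window = ref[260:263]
        repl = {"A": "C", "C": "G", "G": "T", "T": "A"}
        sub = "".join(repl[b] for b in window)
        read = ref[200:260] + sub + ref[263:330]
        c = call_edits(align_read(read, ref), "r1")
        assert c.kind == "substitution_run" and c.left_pos == 260

    def test_two_separated_edits_are_complex(self, gene999):
        ref = gene999.seq
        read = ref[100:140] + ref[143:200] + ref[206:260]
        c = call_edits(align_read(read, ref), "r1")
        assert c.kind == "complex"


class TestMergePair:
    def test_exact_overlap_merges(self):
        from triad.genemodel import revcomp

        frag = generate_synthetic_target(132, 0.5, 3).seq[:130]
        r1, r2 = frag[:75], revcomp(frag[-75:])
        assert merge_pair(r1, r2) == frag

    def test_no_overlap_returns_none(self):
        assert merge_pair("A" * 30, "C" * 30) is None


class TestAggregateCounts:
    def test_equal_split_over_ambiguity(self):
        calls = [IndelCall("r1", "deletion", left_pos=4, length=3, ambiguity=(4, 8), in_frame=True)]
        tab = aggregate_counts(calls, 20)
        assert np.allclose(tab.positional[4:8], 0.25)
        assert tab.positional.sum() == pytest.approx(1.0)

    def test_conservation_on_simulated_run(self, gene999):
        from triad.readsim import sample_library, simulate_reads

        s = sample_library(gene999, "del3", 80, frameshift_rate=0.05, seed=21)
        rs = simulate_reads(s, mean_depth=8, error_rate=0.001, seed=22)
        calls, _ = process_reads(rs.records, gene999.seq)
        tab = aggregate_counts(calls, len(gene999.seq))
        assert tab.total_redistributed() == pytest.approx(tab.total_raw(), abs=1e-9)
        counted = sum(1 for c in calls if c.kind not in ("wildtype", "complex"))
        assert tab.total_raw() == counted

    def test_frameshift_fraction_matches_simulator(self, gene999):
        from triad.readsim import sample_library, simulate_reads

        s = sample_library(gene999, "del3", 300, frameshift_rate=0.2, seed=31)
        rs = simulate_reads(s, mean_depth=6, error_rate=0.0, seed=32)
        calls, _ = process_reads(rs.records, gene999.seq)
        summary = summarize_calls(calls)
        truth_fs = rs.truth["is_frameshift"].mean()
        assert summary["frameshift_fraction"] == pytest.approx(truth_fs, abs=0.02)


class TestPairedEndToEnd:
    def test_paired_reads_called_like_merged(self, gene999):
        from triad.readsim import sample_library, simulate_reads
        from triad.pipeline import truth_recovery

        s = sample_library(gene999, "del3", 40, seed=41)
        rs = simulate_reads(s, mean_depth=5, error_rate=0.0, mode="paired75", seed=42)
        calls, dropped = process_reads(rs.records, gene999.seq)
        assert dropped == 0
        rec = truth_recovery(calls, rs.truth)
        assert rec["recovery"] >= 0.99
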