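"""Read re-alignment and ambiguity-aware InDel calling.

Each (merged) read is globally re-aligned to the reference gene with an
affine-gap Needleman-Wunsch scheme (gap open 15, gap extend 0.5; end gaps
on the read are free because reads are internal fragments of the
sequenced insert).  Alignment gaps are converted to edits, left-aligned to
their canonical position, and aggregated into a count table in which each
read's weight is divided equally over every position its InDel could have
originated from — so positional totals are conserved exactly while
sequence-context redundancy is spread rather than arbitrarily assigned.

Isolated mismatches (sequencing errors) are ignored; a single run of three
contiguous mismatches with no gap is reported as a substitution run
(triplet-substitution libraries).  Reads with more than one separated edit
are classed ``complex`` and excluded from positional tables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from triad.genemodel import revcomp
from triad.diversity import CanonicalEdit, canonicalize_deletion, canonicalize_insertion


@dataclass
class AlignmentScoring:
    """Scores for the affine-gap global alignment.

    A gap of length L costs ``gap_open + L * gap_extend``.  With
    ``end_gap_free`` the unaligned reference overhangs flanking a fragment
    read cost nothing (semi-global alignment).
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 15.0
    gap_extend: float = 0.5
    end_gap_free: bool = True

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


def make_aligner(scoring: AlignmentScoring | None = None) -> Align.PairwiseAligner:
    """Configured Biopython pairwise aligner (C implementation)."""
    sc = scoring or AlignmentScoring()
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = sc.match
    al.mismatch_score = sc.mismatch
    # Biopython charges open+extend for a length-1 gap via open_gap_score
    al.open_gap_score = -(sc.gap_open + sc.gap_extend)
    al.extend_gap_score = -sc.gap_extend
    if sc.end_gap_free:
        # free end gaps in the read row: the reference may overhang the read
        try:
            al.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            al.query_end_gap_score = 0.0
    return al


def align_read(read: str, reference: str,
               scoring: AlignmentScoring | None = None) -> Align.Alignment:
    """Optimal affine-gap global alignment of a read against the reference.

    Returns the first optimal alignment in Biopython's deterministic
    traceback order.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    al = make_aligner(scoring)
    return al.align(reference, read)[0]


@dataclass
class IndelCall:
    """Caller output for one read."""

    read_id: str
    kind: str  # deletion | insertion | substitution_run | wildtype | frameshift | complex
    left_pos: int = -1
    length: int = 0
    inserted: str = ""
    ambiguity: tuple[int, int] = (-1, -1)
    in_frame: bool = False
    n_mismatches: int = 0

    def key(self) -> tuple:
        return (self.kind, self.left_pos, self.length, self.inserted)


def _gap_edits(alignment: Align.Alignment) -> tuple[list[tuple], int, tuple[int, int], list[tuple[int, int]]]:
    """Internal gaps as (ref_pos, deleted_len, inserted_str) plus mismatch info."""
    ref = str(alignment.target)
    read = str(alignment.query)
    tb, qb = alignment.aligned  # aligned blocks, gaps between consecutive blocks
    edits: list[tuple] = []
    mismatch_runs: list[tuple[int, int]] = []
    n_mm = 0
    cur_run_start, cur_run_len = -1, 0
    for bi in range(len(tb)):
        t0, t1 = tb[bi]
        q0, q1 = qb[bi]
        for k in range(t1 - t0):
            if ref[t0 + k] != read[q0 + k]:
                n_mm += 1
                if cur_run_len and cur_run_start + cur_run_len == t0 + k:
                    cur_run_len += 1
                else:
                    if cur_run_len:
                        mismatch_runs.append((cur_run_start, cur_run_len))
                    cur_run_start, cur_run_len = t0 + k, 1
            else:
                if cur_run_len:
                    mismatch_runs.append((cur_run_start, cur_run_len))
                cur_run_start, cur_run_len = -1, 0
        if bi + 1 < len(tb):
            nt0 = tb[bi + 1][0]
            nq0 = qb[bi + 1][0]
            del_len = int(nt0 - t1)
            ins = read[q1:nq0]
            edits.append((int(t1), del_len, ins))
    if cur_run_len:
        mismatch_runs.append((cur_run_start, cur_run_len))
    aligned_span = (int(tb[0][0]), int(tb[-1][1])) if len(tb) else (0, 0)
    return edits, n_mm, aligned_span, mismatch_runs


def call_edits(alignment: Align.Alignment, read_id: str = "",
               orf_start: int = 0) -> IndelCall:
    """Convert one alignment into a classified, canonicalized call.

    ``orf_start`` is accepted for frame bookkeeping but frame is decided
    by the net edit length alone (multiples of 3 are in-frame).
    """
    ref = str(alignment.target)
    edits, n_mm, _, mm_runs = _gap_edits(alignment)
    # merge a deletion and insertion reported at the same point (replacement)
    real_edits = [(p, d, i) for p, d, i in edits if d or i]
    if len(real_edits) > 1:
        return IndelCall(read_id, "complex", n_mismatches=n_mm)
    if not real_edits:
        run3 = [r for r in mm_runs if r[1] == 3]
        if len(run3) == 1 and n_mm == 3:
            p = run3[0][0]
            return IndelCall(read_id, "substitution_run", left_pos=p, length=3,
                             inserted="", ambiguity=(p, p + 1), in_frame=True,
                             n_mismatches=n_mm)
        return IndelCall(read_id, "wildtype", in_frame=True, n_mismatches=n_mm)
    p, d, ins = real_edits[0]
    net = len(ins) - d
    if d and ins:
        # replacement block: anchor at its own position, no shift ambiguity
        return IndelCall(read_id, "complex", left_pos=p, length=d, inserted=ins,
                         ambiguity=(p, p + 1), in_frame=net % 3 == 0, n_mismatches=n_mm)
    if d:
        ce = canonicalize_deletion(ref, p, d)
        kind = "deletion" if d % 3 == 0 else "frameshift"
        return IndelCall(read_id, kind, ce.left_pos, d, "", ce.ambiguity,
                         in_frame=d % 3 == 0, n_mismatches=n_mm)
    ce = canonicalize_insertion(ref, p, ins)
    kind = "insertion" if len(ins) % 3 == 0 else "frameshift"
    return IndelCall(read_id, kind, ce.left_pos, len(ins), ce.inserted, ce.ambiguity,
                     in_frame=len(ins) % 3 == 0, n_mismatches=n_mm)


# -- paired-read merging ----------------------------------------------------


def merge_pair(r1: str, r2: str, min_overlap: int = 20) -> str | None:
    """Naive exact-overlap merge of a read pair (R2 given as sequenced).

    Returns the reconstructed fragment, or None when no exact overlap of
    at least ``min_overlap`` bp exists.
    """
    r2rc = revcomp(r2)
    best = None
    for k in range(min(len(r1), len(r2rc)), min_overlap - 1, -1):
        if r1[-k:] == r2rc[:k]:
            best = r1 + r2rc[k:]
            break
    return best


def pair_up(records: Sequence[tuple[str, str]]) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Split records into single reads and (/1, /2) pairs."""
    singles: list[tuple[str, str]] = []
    halves: dict[str, dict[str, str]] = defaultdict(dict)
    for rid, seq in records:
        if rid.endswith("/1") or rid.endswith("/2"):
            halves[rid[:-2]][rid[-1]] = seq
        else:
            singles.append((rid, seq))
    pairs = [(rid, h.get("1", ""), h.get("2", "")) for rid, h in halves.items()]
    return singles, pairs


def process_reads(records: Sequence[tuple[str, str]], reference: str,
                  scoring: AlignmentScoring | None = None,
                  min_overlap: int = 20) -> tuple[list[IndelCall], int]:
    """Align every read (merging pairs first) and call edits.

    Returns the calls and the number of unmergeable pairs dropped.
    """
    al = make_aligner(scoring)
    singles, pairs = pair_up(records)
    dropped = 0
    merged: list[tuple[str, str]] = list(singles)
    for rid, r1, r2 in pairs:
        if r1 and r2:
            frag = merge_pair(r1, r2, min_overlap)
            if frag is None:
                dropped += 1
                continue
            merged.append((rid, frag))
        elif r1 or r2:
            merged.append((rid, r1 or revcomp(r2)))
    calls = []
    for rid, seq in merged:
        aln = al.align(reference, seq)[0]
        calls.append(call_edits(aln, read_id=rid))
    return calls, dropped


# -- aggregation ------------------------------------------------------------


@dataclass
class CountTable:
    """Ambiguity-aware aggregation of calls against one reference.

    ``edits`` has one row per unique canonical edit with its raw read
    count; ``positional`` holds, per reference position, the summed weight
    after dividing each read equally over its edit's ambiguity interval.
    Wildtype and complex reads are tallied separately and excluded.
    """

    ref_length: int
    edits: pd.DataFrame
    positional: np.ndarray
    n_wildtype: int
    n_complex: int

    def total_raw(self) -> float:
        return float(self.edits["raw_count"].sum())

    def total_redistributed(self) -> float:
        return float(self.positional.sum())


def aggregate_counts(calls: Iterable[IndelCall], ref_length: int) -> CountTable:
    """Group calls by canonical edit and redistribute over ambiguity.

    Each counted read contributes weight 1, split equally between all
    start positions at which its InDel could have originated; the summed
    positional weight therefore equals the raw read total exactly.
    """
    per_edit: dict[tuple, dict] = {}
    positional = np.zeros(ref_length)
    n_wt = n_complex = 0
    for c in calls:
        if c.kind == "wildtype":
            n_wt += 1
            continue
        if c.kind == "complex":
            n_complex += 1
            continue
        k = c.key()
        if k not in per_edit:
            per_edit[k] = {"kind": c.kind, "left_pos": c.left_pos, "length": c.length,
                           "inserted": c.inserted, "ambiguity_start": c.ambiguity[0],
                           "ambiguity_end": c.ambiguity[1], "in_frame": c.in_frame,
                           "raw_count": 0}
        per_edit[k]["raw_count"] += 1
        a, b = c.ambiguity
        w = 1.0 / (b - a)
        positional[a:b] += w
    edits = pd.DataFrame(list(per_edit.values()),
                         columns=["kind", "left_pos", "length", "inserted",
                                  "ambiguity_start", "ambiguity_end", "in_frame",
                                  "raw_count"])
    return CountTable(ref_length=ref_length, edits=edits, positional=positional,
                      n_wildtype=n_wt, n_complex=n_complex)


def summarize_calls(calls: Sequence[IndelCall]) -> dict:
    """Run-level summary: class fractions and unique-edit counts."""
    n = len(calls)
    kinds = pd.Series([c.kind for c in calls])
    counts = kinds.value_counts().to_dict()
    in_frame_indel = sum(1 for c in calls if c.kind in ("deletion", "insertion"))
    unique = len({c.key() for c in calls if c.kind in ("deletion", "insertion", "frameshift",
                                                       "substitution_run")})
    return {
        "n_reads": n,
        "class_counts": counts,
        "in_frame_indel_fraction": in_frame_indel / n if n else 0.0,
        "frameshift_fraction": counts.get("frameshift", 0) / n if n else 0.0,
        "unique_edits": unique,
    }


def calls_table(calls: Sequence[IndelCall]) -> pd.DataFrame:
    rows = [{
        "read_id": c.read_id, "kind": c.kind, "left_pos": c.left_pos,
        "length": c.length, "inserted": c.inserted,
        "ambiguity_start": c.ambiguity[0], "ambiguity_end": c.ambiguity[1],
        "in_frame": c.in_frame,
    } for c in calls]
    return pd.DataFrame(rows, columns=["read_id", "kind", "left_pos", "length", "inserted",
                                       "ambiguity_start", "ambiguity_end", "in_frame"])
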