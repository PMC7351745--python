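"""Transposition-site preference and library-coverage analytics.

Mu transposition duplicates a 5-bp target window, so the sequence
preference of the transposase is summarized as a 5x4 position weight
matrix built from the 5-mer surrounding every detected single-triplet
deletion.  Because the transposon's own orientation is unknown, each
5-mer enters the matrix together with its reverse complement, each at
half weight; per-variant weights are read counts normalized for
sequencing depth and already divided across each InDel's ambiguity
interval (redundancy normalization).

The consensus string reports, per position, the most specific IUPAC
class among A/C/G/T, R (purine), Y (pyrimidine), S (G/C), W (A/T) whose
summed proportion reaches the calling threshold, else N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from triad.genemodel import TargetGene, revcomp
from triad.indelcaller import CountTable

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: IUPAC classes considered for consensus calls, most specific first.
_CONSENSUS_CLASSES: list[tuple[str, tuple[int, ...]]] = [
    ("A", (0,)), ("C", (1,)), ("G", (2,)), ("T", (3,)),
    ("R", (0, 2)), ("Y", (1, 3)), ("S", (1, 2)), ("W", (0, 3)),
]


@dataclass
class SitePWM:
    """Per-position nucleotide proportions of the 5-bp transposition site."""

    matrix: np.ndarray  # 5 x 4, rows sum to 1
    total_weight: float
    consensus: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list("ACGT"),
                            index=[f"pos{i + 1}" for i in range(5)])


def consensus_from_matrix(matrix: np.ndarray, threshold: float = 0.75) -> str:
    """Call the smallest IUPAC class reaching ``threshold`` per position."""
    out = []
    for row in matrix:
        call = "N"
        for sym, idx in _CONSENSUS_CLASSES:
            if row[list(idx)].sum() >= threshold:
                call = sym
                break
        out.append(call)
    return "".join(out)


def transposition_pwm(count_table: CountTable, gene: TargetGene,
                      threshold: float = 0.75,
                      deletion_length: int = 3) -> SitePWM:
    """PWM + consensus of the transposition site from -3 bp deletion calls.

    For each unique deletion with canonical window ``[p, p+3)`` the 5-mer
    ``gene.seq[p-1 : p+4]`` (the duplicated target window) and its reverse
    complement each receive half of the variant's depth-normalized
    weight.  Deletions whose window touches a sequence end are skipped.
    """
    seq = gene.seq
    df = count_table.edits
    dels = df[(df["kind"] == "deletion") & (df["length"] == deletion_length)]
    total_reads = count_table.total_raw()
    m = np.zeros((5, 4))
    skipped = 0
    total_w = 0.0
    for _, row in dels.iterrows():
        p = int(row["left_pos"])
        if p - 1 < 0 or p + 4 > len(seq):
            skipped += 1
            continue
        fivemer = seq[p - 1: p + 4]
        w = row["raw_count"] / total_reads if total_reads else 0.0
        for mer, half in ((fivemer, w / 2), (revcomp(fivemer), w / 2)):
            for i, b in enumerate(mer):
                m[i, _BASE_INDEX[b]] += half
        total_w += w
    if total_w > 0:
        m = m / m.sum(axis=1, keepdims=True)
    else:
        m = np.full((5, 4), 0.25)
    return SitePWM(matrix=m, total_weight=total_w,
                   consensus=consensus_from_matrix(m, threshold))


def gc_profile(gene: TargetGene, window: int = 19) -> np.ndarray:
    """Per-position GC fraction as a centered moving average.

    At the sequence ends the window is truncated to the available bases,
    so the profile has the same length as the gene.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = gene.seq
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    n = len(seq)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class CoverageSummary:
    """Positional coverage and abundance-histogram summary of one library."""

    position_coverage: float  # fraction of reference positions with weight > 0
    per_position_variants: np.ndarray  # distinct canonical edits per left position
    histogram: dict[str, int]  # reads-per-variant bins

    @property
    def histogram_fractions(self) -> dict[str, float]:
        tot = sum(self.histogram.values())
        return {k: (v / tot if tot else 0.0) for k, v in self.histogram.items()}


#: Reads-per-variant histogram bins used in coverage summaries.
HISTOGRAM_BINS = (("1-9", 1, 10), ("10-99", 10, 100), ("100-199", 100, 200),
                  (">=200", 200, np.inf))


def coverage_summary(count_table: CountTable, gene: TargetGene) -> CoverageSummary:
    """Fraction of positions reached, per-position variant counts, bins."""
    n = len(gene.seq)
    pos_cov = float((count_table.positional > 0).sum()) / n if n else 0.0
    per_pos = np.zeros(n, dtype=int)
    hist = {name: 0 for name, _, _ in HISTOGRAM_BINS}
    for _, row in count_table.edits.iterrows():
        p = int(row["left_pos"])
        if 0 <= p < n:
            per_pos[p] += 1
        c = int(row["raw_count"])
        for name, lo, hi in HISTOGRAM_BINS:
            if lo <= c < hi:
                hist[name] += 1
                break
    return CoverageSummary(position_coverage=pos_cov,
                           per_position_variants=per_pos, histogram=hist)
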