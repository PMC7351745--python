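"""Canonicalisation, redundancy collapse and diversity accounting.

Neighbouring transposition events can yield byte-identical mutant
sequences (e.g. deleting any one ``A`` from a homopolymer run).  Each edit
is therefore reduced to a canonical, VCF-style *left-aligned* form plus an
*ambiguity interval*: the contiguous set of start positions at which an
edit of the same kind would have produced the identical sequence.  All
downstream counting (unique-diversity totals, per-position attribution,
ambiguity-aware read weights) is built on this canonical form.

Protein-level consequences follow the classification used for in-frame
InDel libraries: a *clean* InDel inserts/deletes whole residues; a
*cross-codon* event additionally substitutes one flanking residue
("adjacent substitution"); inserted or shifted stop codons give
*truncation*; net changes not divisible by three give *frameshift*.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from triad.genemodel import TargetGene
from triad.mechanism import (
    EditSpec,
    INSERT_LEN,
    NET_CHANGE,
    Variant,
    enumerate_library,
    enumerate_sites,
    DEFAULT_ENUMERATION_CAP,
)

#: Naive per-position protein alphabet factor: 20 amino acids + stop.
PROTEIN_ALPHABET_FACTOR = 21


@dataclass(frozen=True)
class CanonicalEdit:
    """Left-aligned representative of all equivalent edit placements.

    ``ambiguity`` is the half-open interval of start positions (deletion
    start, or insertion point) at which an equivalent edit yields the
    identical mutant sequence; ``left_pos`` is its lower end.
    """

    kind: str
    left_pos: int
    length: int
    inserted: str
    ambiguity: tuple[int, int]

    @property
    def net_change(self) -> int:
        return len(self.inserted) - (self.length if not self.kind.startswith("ins") else 0)

    def key(self) -> tuple:
        return (self.kind, self.left_pos, self.length, self.inserted)


def _left_align_deletion(seq: str, start: int, length: int) -> tuple[int, int]:
    """Leftmost equivalent start and rightmost equivalent start."""
    p = start
    while p > 0 and seq[p - 1] == seq[p - 1 + length]:
        p -= 1
    r = start
    while r + length < len(seq) and seq[r] == seq[r + length]:
        r += 1
    return p, r


def _left_align_insertion(seq: str, point: int, ins: str) -> tuple[int, str, int]:
    """Leftmost equivalent insertion point, its rotated insert, rightmost point."""
    p, left_ins = point, ins
    while p > 0 and seq[p - 1] == left_ins[-1]:
        left_ins = left_ins[-1] + left_ins[:-1]
        p -= 1
    r, right_ins = point, ins
    while r < len(seq) and seq[r] == right_ins[0]:
        right_ins = right_ins[1:] + right_ins[0]
        r += 1
    return p, left_ins, r


def canonicalize_deletion(seq: str, start: int, length: int, kind: str = "deletion") -> CanonicalEdit:
    """Canonical form of deleting ``[start, start+length)`` from ``seq``."""
    p, r = _left_align_deletion(seq, start, length)
    return CanonicalEdit(kind=kind, left_pos=p, length=length, inserted="", ambiguity=(p, r + 1))


def canonicalize_insertion(seq: str, point: int, ins: str, kind: str = "insertion") -> CanonicalEdit:
    """Canonical form of inserting ``ins`` at inter-base position ``point``."""
    p, left_ins, r = _left_align_insertion(seq, point, ins)
    return CanonicalEdit(kind=kind, left_pos=p, length=len(ins), inserted=left_ins, ambiguity=(p, r + 1))


def canonicalize_edit(gene: TargetGene, edit: EditSpec, seq: str | None = None) -> CanonicalEdit:
    """Canonicalize a mechanism-level edit against its reference sequence.

    Substitution-bearing edits (sub3, or a deletion+insertion pair) are
    first reduced: shared bases between the deleted window and the inserted
    string are trimmed so that e.g. replacing ``CCG`` by ``CCG`` is the
    identity and replacing ``CCG`` by ``CTG`` is a 1-bp mismatch, kept as a
    substitution-run edit anchored at its own position.
    """
    if seq is None:
        seq = gene.context if (gene.left_flank or gene.right_flank) else gene.seq
    if edit.deleted_interval is not None and not edit.inserted:
        a, b = edit.deleted_interval
        return canonicalize_deletion(seq, a, b - a, kind=edit.kind)
    if edit.deleted_interval is None:
        assert edit.insert_point is not None
        return canonicalize_insertion(seq, edit.insert_point, edit.inserted, kind=edit.kind)
    # replacement (sub3): trim common prefix/suffix between window and insert
    a, b = edit.deleted_interval
    window, ins = seq[a:b], edit.inserted
    lo = 0
    while lo < min(len(window), len(ins)) and window[lo] == ins[lo]:
        lo += 1
    hi = 0
    while hi < min(len(window), len(ins)) - lo and window[-1 - hi] == ins[-1 - hi]:
        hi += 1
    core_ins = ins[lo:len(ins) - hi]
    core_a, core_b = a + lo, b - hi
    if core_a == core_b and not core_ins:
        return CanonicalEdit(kind="silent", left_pos=a, length=0, inserted="", ambiguity=(a, a + 1))
    if core_a == core_b:
        return canonicalize_insertion(seq, core_a, core_ins, kind=edit.kind)
    if not core_ins:
        return canonicalize_deletion(seq, core_a, core_b - core_a, kind=edit.kind)
    return CanonicalEdit(kind=edit.kind, left_pos=core_a, length=core_b - core_a,
                         inserted=core_ins, ambiguity=(core_a, core_a + 1))


def apply_canonical(seq: str, ce: CanonicalEdit, at: int | None = None) -> str:
    """Re-apply a canonical edit (optionally at another ambiguous position)."""
    p = ce.left_pos if at is None else at
    if ce.kind.startswith("ins") or (ce.inserted and ce.length == 0):
        ins = ce.inserted
        if at is not None and at != ce.left_pos:
            # rotate the insert to match the shifted placement
            ins = ce.inserted
            for q in range(ce.left_pos, at):
                ins = ins[1:] + ins[0]
        return seq[:p] + ins + seq[p:]
    return seq[:p] + ce.inserted + seq[p + ce.length:]


def collapse_unique(variants: Sequence[Variant], gene: TargetGene | None = None
                    ) -> list[tuple[str, CanonicalEdit, list[EditSpec]]]:
    """Group variants by identical mutant sequence.

    Returns one ``(mutant_seq, canonical_edit, origin_edits)`` triple per
    distinct sequence, in order of first appearance.  The group count is
    the accessible DNA diversity; origin edits are preserved so that
    transposition-bias analyses can still see every contributing site.

    Deletion and replacement edits cannot be canonicalized from the mutant
    sequence alone (the removed bases are gone), so ``gene`` must be given
    for them; pure insertions reconstruct their parent internally.
    """
    groups: dict[str, list[Variant]] = {}
    order: list[str] = []
    for v in variants:
        if v.seq not in groups:
            groups[v.seq] = []
            order.append(v.seq)
        groups[v.seq].append(v)
    out = []
    for s in order:
        vs = groups[s]
        e = vs[0].edit
        if gene is not None:
            seq = gene.context if (gene.left_flank or gene.right_flank) else gene.seq
            if len(s) - e.net_change != len(seq):
                raise ValueError("variant does not derive from the supplied gene")
            ce = canonicalize_edit(gene, e, seq=seq)
        elif e.deleted_interval is None:
            p, k = e.insert_point, len(e.inserted)
            parent = s[:p] + s[p + k:]
            ce = canonicalize_insertion(parent, p, e.inserted, kind=e.kind)
        else:
            raise ValueError("deletion/replacement variants require the parent gene")
        out.append((s, ce, [v.edit for v in vs]))
    return out


def collapse_unique_with_gene(gene: TargetGene, variants: Sequence[Variant]
                              ) -> list[tuple[str, CanonicalEdit, list[EditSpec]]]:
    """Alias of :func:`collapse_unique` with the parent gene supplied."""
    return collapse_unique(variants, gene=gene)


# -- theoretical diversity --------------------------------------------------


@dataclass
class DiversityBreakdown:
    """Counts at one accounting level, with protein-class breakdown."""

    kind: str
    level: str
    count: int
    estimated: bool = False
    class_counts: dict[str, int] | None = None


def theoretical_diversity(gene: TargetGene, kind: str, level: str = "dna_naive",
                          orientations: str = "A",
                          cap: int = DEFAULT_ENUMERATION_CAP) -> DiversityBreakdown:
    """Theoretical library diversity at DNA or protein level.

    ``dna_naive``
        positions x per-position variant count (1 per deletion, ``64**n``
        for n inserted triplets, 64 for sub3), no dedup — the back-of-
        envelope figure quoted for library design.
    ``dna_unique``
        distinct mutant DNA sequences after redundancy collapse
        (exhaustive below ``cap``, otherwise estimated from naive count).
    ``protein_unique``
        distinct mutant proteins; above ``cap`` the naive 21-fold
        protein-alphabet scaling from the next enumerable insertion size
        is used (20 amino acids + stop per extra triplet).
    """
    sites = enumerate_sites(gene, kind, orientations=orientations)
    per_pos = 4 ** INSERT_LEN[kind]
    naive = len(sites) * per_pos
    if level == "dna_naive":
        return DiversityBreakdown(kind, level, naive)
    if level == "dna_unique":
        if naive > cap:
            warnings.warn(f"{kind}: {naive} naive variants exceed cap {cap}; "
                          f"reporting naive count as an upper-bound estimate")
            return DiversityBreakdown(kind, level, naive, estimated=True)
        variants = enumerate_library(gene, kind, "full", orientations=orientations, cap=cap)
        return DiversityBreakdown(kind, level, len(collapse_unique_with_gene(gene, variants)))
    if level == "protein_unique":
        if naive > cap:
            smaller = {"ins9": "ins6", "ins6": "ins3"}.get(kind)
            if smaller is None:
                raise ValueError(f"cannot estimate protein diversity for {kind}")
            base = theoretical_diversity(gene, smaller, "protein_unique", orientations, cap)
            factor = PROTEIN_ALPHABET_FACTOR ** ((INSERT_LEN[kind] - INSERT_LEN[smaller]) // 3)
            return DiversityBreakdown(kind, level, base.count * factor, estimated=True)
        variants = enumerate_library(gene, kind, "full", orientations=orientations, cap=cap)
        proteins: dict[str, str] = {}
        classes: dict[str, int] = defaultdict(int)
        for v in variants:
            pc = protein_consequence(gene, v)
            if pc.mutant_protein not in proteins:
                proteins[pc.mutant_protein] = pc.klass
                classes[pc.klass] += 1
        return DiversityBreakdown(kind, level, len(proteins), class_counts=dict(classes))
    raise ValueError(f"unknown level {level!r}")


def per_position_diversity(gene: TargetGene, kind: str,
                           orientations: str = "A",
                           cap: int = DEFAULT_ENUMERATION_CAP) -> dict[int, int]:
    """Unique-variant count per canonical (leftmost) position.

    Every distinct mutant sequence contributes 1 to the position its
    canonical edit left-aligns to; the values therefore sum to the
    ``dna_unique`` total.
    """
    variants = enumerate_library(gene, kind, "full", orientations=orientations, cap=cap)
    counts: dict[int, int] = defaultdict(int)
    for _, ce, _ in collapse_unique_with_gene(gene, variants):
        counts[ce.left_pos] += 1
    return dict(counts)


# -- protein consequences ---------------------------------------------------


@dataclass
class ProteinConsequence:
    """Effect of one edit on the translated ORF."""

    klass: str  # in_frame_clean | in_frame_adjacent_sub | truncation | frameshift | silent
    n_residues_changed: int
    deleted_residues: str
    inserted_residues: str
    adjacent_substitution: tuple[str, int, str] | None
    mutant_protein: str


def _translate(dna: str) -> str:
    return str(Seq(dna[: len(dna) - len(dna) % 3]).translate())


def _mutant_orf(gene: TargetGene, variant: Variant) -> str:
    """Extract the ORF from the mutant sequence, mapping edited coordinates."""
    e = variant.edit
    use_flanks = bool(gene.left_flank or gene.right_flank)
    o0, o1 = gene.orf_in_context if use_flanks else (gene.orf_start, gene.orf_end)

    def map_pos(p: int) -> int:
        if e.deleted_interval is not None:
            a, b = e.deleted_interval
            ins = len(e.inserted)
            if p <= a:
                return p
            if p >= b:
                return p - (b - a) + ins
            return a  # inside the deleted window: collapse to its start
        assert e.insert_point is not None
        return p if p <= e.insert_point else p + len(e.inserted)

    m0 = map_pos(o0)
    # ORF end moves with the net change when the edit lies inside the ORF
    m1 = map_pos(o1)
    return variant.seq[m0:m1]


def protein_consequence(gene: TargetGene, variant: Variant) -> ProteinConsequence:
    """Classify an edit's effect on the translated ORF.

    Net DNA changes not divisible by 3 are frameshifts.  In-frame changes
    are diffed against the wild-type protein by longest common prefix and
    suffix; the differing middle defines the deleted/inserted residues.  A
    one-residue overhang on both sides marks a cross-codon event, reported
    as an adjacent amino-acid substitution.  A stop codon inside the
    mutant middle truncates the protein.
    """
    e = variant.edit
    if e.net_change % 3 != 0:
        mut_prot = _translate(_mutant_orf(gene, variant))
        stop = mut_prot.find("*")
        if stop >= 0:
            mut_prot = mut_prot[: stop + 1]
        return ProteinConsequence("frameshift", -1, "", "", None, mut_prot)
    wt = _translate(gene.orf_seq)
    mut = _translate(_mutant_orf(gene, variant))
    if mut == wt:
        return ProteinConsequence("silent", 0, "", "", None, mut)
    # longest common prefix, then suffix capped so P + S <= min length
    nmin = min(len(wt), len(mut))
    p = 0
    while p < nmin and wt[p] == mut[p]:
        p += 1
    s = 0
    while s < nmin - p and wt[-1 - s] == mut[-1 - s]:
        s += 1
    wt_mid = wt[p: len(wt) - s]
    mut_mid = mut[p: len(mut) - s]
    if "*" in mut_mid:
        return ProteinConsequence("truncation", len(wt) - p, wt_mid, mut_mid, None,
                                  mut[: p + mut_mid.find("*") + 1])
    k = abs(len(wt_mid) - len(mut_mid))
    if len(wt_mid) > len(mut_mid):  # deletion
        if len(mut_mid) == 0:
            return ProteinConsequence("in_frame_clean", k, wt_mid, "", None, mut)
        if len(mut_mid) == 1:
            # k deleted residues plus one flanking substitution
            sub = (wt_mid[0], p, mut_mid[0]) if wt_mid[0] != mut_mid[0] else (wt_mid[-1], p + k, mut_mid[0])
            return ProteinConsequence("in_frame_adjacent_sub", k + 1, wt_mid, mut_mid, sub, mut)
    elif len(mut_mid) > len(wt_mid):  # insertion
        if len(wt_mid) == 0:
            return ProteinConsequence("in_frame_clean", k, "", mut_mid, None, mut)
        if len(wt_mid) == 1:
            sub = (wt_mid[0], p, mut_mid[0])
            return ProteinConsequence("in_frame_adjacent_sub", k + 1, wt_mid, mut_mid, sub, mut)
    else:  # pure substitution run (sub3 / TriNEx)
        if len(wt_mid) == 1:
            return ProteinConsequence("in_frame_adjacent_sub", 1, wt_mid, mut_mid,
                                      (wt_mid[0], p, mut_mid[0]), mut)
    return ProteinConsequence("complex", max(len(wt_mid), len(mut_mid)), wt_mid, mut_mid, None, mut)
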