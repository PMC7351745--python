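"""Target-gene model, restriction-site validation and synthetic fixtures.

The TRIAD chemistry relies on three restriction enzymes — MlyI (GAGTC),
NotI (GCGGCCGC) and AcuI (CTGAAG) — cutting only inside the transposon or
shuttle cassettes.  A target gene (and its vector context) is therefore
only TRIAD-compatible if none of the three recognition sequences occurs on
either strand.  This module provides the validated :class:`TargetGene`
container, the site scanner used for validation, FASTA round-tripping and
a deterministic synthetic-gene generator used throughout the test and
simulation layers.

Coordinate convention: all positions are 0-based; intervals are half-open
``[start, end)``.  This holds for every module in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = frozenset("ACGT")

#: Recognition sequences whose presence (either strand) is incompatible
#: with the deletion/insertion cassette chemistry.
RECOGNITION_SITES: dict[str, str] = {
    "MlyI": "GAGTC",
    "NotI": "GCGGCCGC",
    "AcuI": "CTGAAG",
}

_STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """Raised for malformed or non-ACGT input sequences."""


class GenerationError(RuntimeError):
    """Raised when constrained sequence generation fails within its retry cap."""


@dataclass(frozen=True)
class RestrictionHit:
    """One occurrence of a forbidden recognition sequence.

    ``position`` is the 0-based start of the recognition sequence on the
    forward strand; ``strand`` is ``'+'`` when the motif itself matches and
    ``'-'`` when its reverse complement matches at that position.
    """

    enzyme: str
    position: int
    strand: str


def _check_alphabet(seq: str) -> None:
    for i, c in enumerate(seq):
        if c not in _DNA:
            raise SequenceError(f"non-ACGT character {c!r} at offset {i}")


def scan_restriction_sites(seq: str) -> list[RestrictionHit]:
    """Find every MlyI/NotI/AcuI recognition site on either strand.

    Returns hits sorted by position then enzyme.  An empty list means the
    sequence is TRIAD-compatible.  NotI is palindromic, so its reverse-
    complement occurrences coincide with forward ones and are reported
    once, on the ``'+'`` strand.
    """
    if not seq:
        raise SequenceError("empty sequence")
    _check_alphabet(seq)
    hits: list[RestrictionHit] = []
    for enzyme, motif in RECOGNITION_SITES.items():
        rc = revcomp(motif)
        for m in re.finditer(f"(?={motif})", seq):
            hits.append(RestrictionHit(enzyme, m.start(), "+"))
        if rc != motif:  # skip palindromes (NotI)
            for m in re.finditer(f"(?={rc})", seq):
                hits.append(RestrictionHit(enzyme, m.start(), "-"))
    hits.sort(key=lambda h: (h.position, h.enzyme, h.strand))
    return hits


@dataclass
class TargetGene:
    """A validated TRIAD target: gene sequence, ORF coordinates, flanks.

    The ORF interval ``[orf_start, orf_end)`` lies within ``seq`` and has a
    length divisible by three.  ``left_flank``/``right_flank`` carry vector
    context that transposition windows may consume; both may be empty.
    """

    id: str
    seq: str
    orf_start: int
    orf_end: int
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        for label, s in (("seq", self.seq), ("left_flank", self.left_flank), ("right_flank", self.right_flank)):
            if s:
                try:
                    _check_alphabet(s)
                except SequenceError as e:
                    raise SequenceError(f"{label}: {e}") from None
        if not self.seq:
            raise SequenceError("seq must be non-empty")
        if not (0 <= self.orf_start < self.orf_end <= len(self.seq)):
            raise ValueError(f"ORF interval [{self.orf_start}, {self.orf_end}) outside seq of length {len(self.seq)}")
        if (self.orf_end - self.orf_start) % 3:
            raise ValueError("ORF length must be divisible by 3")

    # -- context handling ---------------------------------------------------

    @property
    def context(self) -> str:
        """Flanked sequence ``left_flank + seq + right_flank``."""
        return self.left_flank + self.seq + self.right_flank

    @property
    def gene_interval(self) -> tuple[int, int]:
        """Interval of ``seq`` within :attr:`context`."""
        return len(self.left_flank), len(self.left_flank) + len(self.seq)

    @property
    def orf_in_context(self) -> tuple[int, int]:
        off = len(self.left_flank)
        return off + self.orf_start, off + self.orf_end

    @property
    def orf_seq(self) -> str:
        return self.seq[self.orf_start:self.orf_end]

    def validate(self) -> None:
        """Raise ``ValueError`` if any forbidden restriction site is present."""
        hits = scan_restriction_sites(self.context)
        if hits:
            detail = "; ".join(f"{h.enzyme}@{h.position}{h.strand}" for h in hits[:5])
            raise ValueError(f"target contains {len(hits)} forbidden restriction site(s): {detail}")

    def is_valid(self) -> bool:
        return not scan_restriction_sites(self.context)


# -- synthetic fixture generation ------------------------------------------


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=3, p=p))


def generate_synthetic_target(length: int, gc: float = 0.5, seed: int = 0,
                              max_retries: int = 1000) -> TargetGene:
    """Generate a deterministic TRIAD-compatible synthetic ORF.

    The output is a full-length ORF: it starts with ATG, ends with a stop
    codon, contains no internal in-frame stop and no MlyI/NotI/AcuI site on
    either strand.  Constraint violations are repaired by rejection
    sampling: offending codons are redrawn until clean or ``max_retries``
    is exhausted.

    Parameters
    ----------
    length : total length in bp; must be divisible by 3 and at least 30.
    gc : target GC fraction in (0, 1), achieved approximately.
    seed : seed for the deterministic PRNG stream.
    """
    if length % 3 or length < 30:
        raise ValueError("length must be divisible by 3 and >= 30")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_codons = length // 3
    for _ in range(max_retries):
        codons = ["ATG"]
        for _ in range(n_codons - 2):
            c = _random_codon(rng, gc)
            while c in _STOP_CODONS:
                c = _random_codon(rng, gc)
            codons.append(c)
        stops = [s for s in _STOP_CODONS if abs((s.count("G") + s.count("C")) / 3 - gc) < 0.6]
        codons.append(str(rng.choice(stops or list(_STOP_CODONS))))
        seq = "".join(codons)
        # repair forbidden sites codon-locally rather than rejecting whole draws
        ok = True
        for _ in range(max_retries):
            hits = scan_restriction_sites(seq)
            if not hits:
                break
            h = hits[0]
            ci = max(1, min(n_codons - 2, h.position // 3))
            c = _random_codon(rng, gc)
            while c in _STOP_CODONS:
                c = _random_codon(rng, gc)
            seq = seq[: ci * 3] + c + seq[ci * 3 + 3:]
        else:
            ok = False
        if ok and not scan_restriction_sites(seq):
            return TargetGene(id=f"synthetic_{length}bp_seed{seed}", seq=seq,
                              orf_start=0, orf_end=length)
    raise GenerationError(f"could not satisfy constraints within {max_retries} retries")


# -- FASTA I/O --------------------------------------------------------------

_ORF_RE = re.compile(r"orf=(\d+)\.\.(\d+)")


def write_fasta(gene: TargetGene, path: str | Path) -> None:
    """Write a TargetGene as FASTA with ``orf=start..end`` in the description."""
    rec = SeqRecord(Seq(gene.seq), id=gene.id, description=f"orf={gene.orf_start}..{gene.orf_end}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> TargetGene:
    """Read a TargetGene from FASTA.

    ORF coordinates are taken from an ``orf=start..end`` tag (0-based,
    half-open) in the description; without the tag the whole sequence is
    used as the ORF (its length must then be divisible by 3).
    """
    rec = next(SeqIO.parse(str(path), "fasta"))
    seq = str(rec.seq).upper()
    m = _ORF_RE.search(rec.description)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
    else:
        start, end = 0, len(seq)
    return TargetGene(id=rec.id, seq=seq, orf_start=start, orf_end=end)
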