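"""Exact sequence outcomes of the TRIAD transposition/cassette chemistry.

A Mu transposition event duplicates 5 bp of target DNA at the insertion
point.  Downstream restriction digests and ligations convert each event
into exactly one short edit.  With the 5-bp duplicated window written
``N4 N5 N6 N7 N8`` for deletion libraries (``N1..N5`` for insertion
libraries) and ``s`` the 0-based index of its first base, the windows are:

================  =============================================
library           edit on the target sequence
================  =============================================
del3              delete ``[s+1, s+4)``      (N5 N6 N7)
del6 (orient A)   delete ``[s-2, s+4)``      (N2..N7)
del6 (orient B)   delete ``[s+1, s+7)``      (N5..N10)
del9              delete ``[s-2, s+7)``      (N2..N10)
ins3/6/9 (A)      insert the randomized triplet(s) at ``s+5``
ins3/6/9 (B)      insert at ``s``
sub3              replace ``[s+1, s+4)`` with one NNN triplet
================  =============================================

Orientation ``B`` models the mirror-image outcome of a cassette or
transposon ligated in the opposite direction; del3, del9 and sub3 windows
are orientation-symmetric and enumerate one orientation only.  The strict
single-orientation behaviour is available via ``orientations='A'``.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from triad.genemodel import TargetGene

Kind = Literal["del3", "del6", "del9", "ins3", "ins6", "ins9", "sub3"]

KINDS: tuple[str, ...] = ("del3", "del6", "del9", "ins3", "ins6", "ins9", "sub3")

#: Net length change per library kind (bp).
NET_CHANGE: dict[str, int] = {
    "del3": -3, "del6": -6, "del9": -9,
    "ins3": 3, "ins6": 6, "ins9": 9,
    "sub3": 0,
}

#: Number of randomized bases inserted per kind.
INSERT_LEN: dict[str, int] = {
    "del3": 0, "del6": 0, "del9": 0,
    "ins3": 3, "ins6": 6, "ins9": 9,
    "sub3": 3,
}

#: Kinds whose A/B outcomes differ, hence enumerated in both orientations.
TWO_ORIENTATION_KINDS = frozenset({"del6", "ins3", "ins6", "ins9"})

DEFAULT_ENUMERATION_CAP = 5_000_000


class SiteError(ValueError):
    """Edit window falls outside the available sequence."""


class EditSpecError(ValueError):
    """Inserted bases inconsistent with the requested library kind."""


class LibrarySizeError(ValueError):
    """Full enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class TranspositionSite:
    """A transposition event: ``s`` indexes the first duplicated base."""

    s: int
    orientation: str = "A"


@dataclass(frozen=True)
class EditSpec:
    """One TRIAD edit fully resolved to target coordinates.

    ``deleted_interval`` is half-open on the coordinate system the edit was
    applied in (gene, or flanked context when flanks are in use); it is
    ``None`` for pure insertions.  ``insert_point`` is the 0-based
    inter-base position for insertions, ``None`` otherwise.
    """

    kind: str
    site: TranspositionSite
    inserted: str = ""
    deleted_interval: tuple[int, int] | None = None
    insert_point: int | None = None

    @property
    def net_change(self) -> int:
        deleted = (self.deleted_interval[1] - self.deleted_interval[0]
                   if self.deleted_interval else 0)
        return len(self.inserted) - deleted


@dataclass(frozen=True)
class Variant:
    """A single library member: the edit plus the full mutant sequence."""

    edit: EditSpec
    seq: str


def _edit_window(kind: str, s: int) -> tuple[int, int] | None:
    """Deleted interval for deletion-bearing kinds, None for insertions."""
    if kind == "del3" or kind == "sub3":
        return (s + 1, s + 4)
    if kind == "del9":
        return (s - 2, s + 7)
    return None


def _del6_window(s: int, orientation: str) -> tuple[int, int]:
    return (s - 2, s + 4) if orientation == "A" else (s + 1, s + 7)


def _insert_point(s: int, orientation: str) -> int:
    return s + 5 if orientation == "A" else s


def _working_sequence(gene: TargetGene, use_flanks: bool | None = None) -> tuple[str, int, int]:
    """Sequence the edits apply to, plus the gene interval within it."""
    if use_flanks is None:
        use_flanks = bool(gene.left_flank or gene.right_flank)
    if use_flanks:
        g0, g1 = gene.gene_interval
        return gene.context, g0, g1
    return gene.seq, 0, len(gene.seq)


def _site_windows(kind: str, site: TranspositionSite) -> tuple[tuple[int, int] | None, int | None]:
    s, o = site.s, site.orientation
    if kind in ("del3", "sub3"):
        return (s + 1, s + 4), None
    if kind == "del6":
        return _del6_window(s, o), None
    if kind == "del9":
        return (s - 2, s + 7), None
    # insertions
    return None, _insert_point(s, o)


def site_is_valid(gene: TargetGene, kind: str, site: TranspositionSite,
                  use_flanks: bool | None = None) -> bool:
    """True when both the 5-bp duplication window and the edit window fit."""
    seq, _, _ = _working_sequence(gene, use_flanks)
    n = len(seq)
    s = site.s
    if not (0 <= s and s + 5 <= n):
        return False
    interval, point = _site_windows(kind, site)
    if interval is not None:
        a, b = interval
        return 0 <= a and b <= n
    assert point is not None
    return 0 <= point <= n


def enumerate_sites(gene: TargetGene, kind: Kind,
                    use_flanks: bool | None = None,
                    orientations: str = "AB") -> list[TranspositionSite]:
    """All transposition sites producing an in-range edit of ``kind``.

    For orientation-symmetric kinds (del3, del9, sub3) one site per
    position is returned; del6 and insertions list both cassette
    orientations unless ``orientations='A'`` restricts to the
    single-orientation model.  When flanks are present, edit windows may
    consume flank bases but must touch the gene interval.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown library kind {kind!r}")
    seq, g0, g1 = _working_sequence(gene, use_flanks)
    orients = ["A"] if kind not in TWO_ORIENTATION_KINDS else list(orientations)
    out: list[TranspositionSite] = []
    for s in range(len(seq) - 4):
        for o in orients:
            site = TranspositionSite(s, o)
            if not site_is_valid(gene, kind, site, use_flanks):
                continue
            interval, point = _site_windows(kind, site)
            if interval is not None:
                a, b = interval
                if b <= g0 or a >= g1:  # edit entirely inside a flank
                    continue
            else:
                assert point is not None
                if point < g0 or point > g1:
                    continue
            out.append(site)
    return out


def apply_edit(gene: TargetGene, kind: Kind, site: TranspositionSite,
               inserted: str = "", use_flanks: bool | None = None) -> Variant:
    """Build the exact mutant sequence produced by one transposition event."""
    if kind not in KINDS:
        raise ValueError(f"unknown library kind {kind!r}")
    need = INSERT_LEN[kind]
    if len(inserted) != need:
        raise EditSpecError(f"{kind} requires {need} inserted bases, got {len(inserted)}")
    if not site_is_valid(gene, kind, site, use_flanks):
        raise SiteError(f"site {site} out of range for {kind}")
    seq, _, _ = _working_sequence(gene, use_flanks)
    interval, point = _site_windows(kind, site)
    if interval is not None:
        a, b = interval
        mutant = seq[:a] + inserted + seq[b:]
        edit = EditSpec(kind, site, inserted, deleted_interval=(a, b))
    else:
        assert point is not None
        mutant = seq[:point] + inserted + seq[point:]
        edit = EditSpec(kind, site, inserted, insert_point=point)
    return Variant(edit=edit, seq=mutant)


def _triplet_space(n_triplets: int) -> Iterator[str]:
    for tup in itertools.product("ACGT", repeat=3 * n_triplets):
        yield "".join(tup)


def library_size(gene: TargetGene, kind: Kind, use_flanks: bool | None = None,
                 orientations: str = "AB") -> int:
    """Number of variants a full enumeration would produce (before dedup)."""
    n_sites = len(enumerate_sites(gene, kind, use_flanks, orientations))
    return n_sites * (4 ** INSERT_LEN[kind])


def enumerate_library(gene: TargetGene, kind: Kind,
                      insert_alphabet_mode: str = "full",
                      use_flanks: bool | None = None,
                      orientations: str = "AB",
                      cap: int = DEFAULT_ENUMERATION_CAP) -> list[Variant]:
    """Enumerate (or sample) every variant of one TRIAD library.

    ``insert_alphabet_mode`` is ``"full"`` for exhaustive enumeration of
    the randomized triplet space, or ``"sampled:<n>:<seed>"`` to draw ``n``
    variants uniformly over (site, orientation, triplet) combinations.
    Full mode refuses to build more than ``cap`` variants.  Output order is
    deterministic: sites ascending, orientation A before B, triplets in
    lexicographic order (full mode) or PRNG order (sampled mode).
    """
    sites = enumerate_sites(gene, kind, use_flanks, orientations)
    k = INSERT_LEN[kind]
    if insert_alphabet_mode == "full":
        total = len(sites) * (4 ** k)
        if total > cap:
            raise LibrarySizeError(
                f"full enumeration of {kind} would produce {total} variants (cap {cap}); "
                f"use sampled:<n>:<seed> mode")
        out: list[Variant] = []
        for site in sites:
            if k == 0:
                out.append(apply_edit(gene, kind, site, "", use_flanks))
            else:
                for trip in _triplet_space(k // 3):
                    out.append(apply_edit(gene, kind, site, trip, use_flanks))
        return out
    if insert_alphabet_mode.startswith("sampled:"):
        try:
            _, n_str, seed_str = insert_alphabet_mode.split(":")
            n, seed = int(n_str), int(seed_str)
        except ValueError:
            raise ValueError(f"bad sampled mode spec {insert_alphabet_mode!r}; "
                             f"expected sampled:<n>:<seed>") from None
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        out = []
        site_idx = rng.integers(0, len(sites), size=n)
        for i in site_idx:
            trip = "".join(rng.choice(bases, size=k)) if k else ""
            out.append(apply_edit(gene, kind, sites[int(i)], trip, use_flanks))
        return out
    raise ValueError(f"unknown insert_alphabet_mode {insert_alphabet_mode!r}")


def variant_id(v: Variant) -> str:
    """Stable short identifier from the mutant sequence digest."""
    e = v.edit
    h = hashlib.md5(v.seq.encode()).hexdigest()[:10]
    return f"{e.kind}_s{e.site.s}{e.site.orientation}_{h}"


def variant_table(variants: Sequence[Variant]):
    """Variants as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for v in variants:
        e = v.edit
        a, b = e.deleted_interval if e.deleted_interval else (-1, -1)
        rows.append({
            "variant_id": variant_id(v),
            "kind": e.kind,
            "site": e.site.s,
            "orientation": e.site.orientation,
            "deleted_start": a,
            "deleted_len": (b - a) if a >= 0 else 0,
            "insert_point": e.insert_point if e.insert_point is not None else -1,
            "inserted": e.inserted,
            "seq_md5": hashlib.md5(v.seq.encode()).hexdigest(),
        })
    return pd.DataFrame(rows)
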