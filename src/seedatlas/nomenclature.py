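"""Anchored coordinate system and isomiR/seed nomenclature for homologous
pre-miRNA hairpins.

The miR-290-295 (mouse) / miR-371-373 (human) cluster family carries two
deeply conserved sequence blocks: ``ACUCAAA`` on the 5' strand of every
hairpin stem and ``AAAGUGC`` on the 3' strand.  The first base of each block
defines the reference positions ``5p0`` and ``3p0``.  Mature miRNAs whose 5'
ends are shifted N nucleotides toward the hairpin 3' end are written
``5p+N``/``3p+N`` (negative N for shifts toward the hairpin 5' end).  Because
the seed of a miRNA is its positions 2-7 (6mer) or 2-8 (7mer), every 5' shift
renames the seed; seeds are coded by the block positions they retain plus the
flanking bases that complete them, e.g. ``(3p)3-7CG`` for the 7mer seed of a
3p+1 isomiR whose block is followed by ``CG``.

All coordinates are 0-based half-open internally; rendered names use the
5p0/3p0/±N convention.  DNA input is converted to RNA on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .errors import (
    AlphabetError,
    CodeUndefinedError,
    NoAnchorError,
    OutOfBoundsError,
    ParseError,
)

BLOCK_5P = "ACUCAAA"
BLOCK_3P = "AAAGUGC"
BLOCK_LEN = 7

Arm = Literal["5p", "3p"]
SeedDefinition = Literal["mer6", "mer7"]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID_RNA = frozenset("ACGU")


def to_rna(sequence: str) -> str:
    """Uppercase, T->U, and validate against the ACGU alphabet."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _VALID_RNA
    if bad:
        raise AlphabetError(
            f"sequence contains non-ACGU/T characters: {sorted(bad)}"
        )
    return seq


def to_dna(sequence: str) -> str:
    """Uppercase, U->T, and validate against the ACGT alphabet."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - frozenset("ACGT")
    if bad:
        raise AlphabetError(
            f"sequence contains non-ACGT/U characters: {sorted(bad)}"
        )
    return seq


def revcomp_rna(sequence: str) -> str:
    return to_rna(sequence).translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(sequence: str) -> str:
    return to_dna(revcomp_rna(sequence))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def anchor_hairpin(sequence: str, max_mismatch: int = 2) -> tuple[int, int]:
    """Locate the 5p0/3p0 anchors on a hairpin sequence.

    Returns the offset pair ``(anchor_5p0, anchor_3p0)`` minimizing the total
    Hamming distance to (ACUCAAA, AAAGUGC), subject to each block distance
    being at most ``max_mismatch`` and the 5p block ending before the 3p
    block starts.  Ties break to the leftmost 5p offset, then the leftmost 3p
    offset.  Raises :class:`NoAnchorError` (reporting the best total distance
    found, if any) when no pair is within tolerance.
    """
    seq = to_rna(sequence)
    if len(seq) < 40:
        raise ValueError(f"hairpin too short to anchor ({len(seq)} < 40 nt)")
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")

    n = len(seq)
    d5 = [hamming(seq[i:i + BLOCK_LEN], BLOCK_5P) for i in range(n - BLOCK_LEN + 1)]
    d3 = [hamming(seq[i:i + BLOCK_LEN], BLOCK_3P) for i in range(n - BLOCK_LEN + 1)]

    best: tuple[int, int, int] | None = None  # (total, a5, a3)
    best_any: int | None = None
    for a5, dist5 in enumerate(d5):
        for a3 in range(a5 + BLOCK_LEN, len(d3)):
            total = dist5 + d3[a3]
            if best_any is None or total < best_any:
                best_any = total
            if dist5 > max_mismatch or d3[a3] > max_mismatch:
                continue
            cand = (total, a5, a3)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise NoAnchorError(
            "no anchor pair within tolerance "
            f"(max_mismatch={max_mismatch}, best total distance found: {best_any})",
            best_distance=best_any,
        )
    return best[1], best[2]


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA hairpin with anchored 5p0/3p0 coordinates.

    ``anchor_5p0``/``anchor_3p0`` are 0-based offsets of the first base of
    the conserved ACUCAAA and AAAGUGC blocks.
    """

    id: str
    sequence: str
    anchor_5p0: int
    anchor_3p0: int
    cluster_id: str = ""
    species: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        if not (0 <= self.anchor_5p0 < self.anchor_3p0 < len(self.sequence)):
            raise ValueError(
                f"{self.id}: anchors must satisfy 0 <= 5p0 < 3p0 < length "
                f"(got {self.anchor_5p0}, {self.anchor_3p0}, "
                f"len={len(self.sequence)})"
            )

    @classmethod
    def from_sequence(cls, id: str, sequence: str, cluster_id: str = "",
                      species: str = "", max_mismatch: int = 2) -> "Hairpin":
        a5, a3 = anchor_hairpin(sequence, max_mismatch=max_mismatch)
        return cls(id=id, sequence=to_rna(sequence), anchor_5p0=a5,
                   anchor_3p0=a3, cluster_id=cluster_id, species=species)

    def anchor(self, arm: Arm) -> int:
        if arm == "5p":
            return self.anchor_5p0
        if arm == "3p":
            return self.anchor_3p0
        raise ValueError(f"arm must be '5p' or '3p', got {arm!r}")

    def block_distances(self) -> tuple[int, int]:
        s = self.sequence
        return (
            hamming(s[self.anchor_5p0:self.anchor_5p0 + BLOCK_LEN], BLOCK_5P),
            hamming(s[self.anchor_3p0:self.anchor_3p0 + BLOCK_LEN], BLOCK_3P),
        )

    def validate_blocks(self, max_mismatch: int = 2) -> None:
        d5, d3 = self.block_distances()
        if d5 > max_mismatch or d3 > max_mismatch:
            raise ValueError(
                f"{self.id}: anchored blocks deviate from consensus by "
                f"({d5}, {d3}) > {max_mismatch} mismatches"
            )


_NAME_RE = re.compile(r"^(?P<hairpin>.+)-(?P<arm>5p|3p)(?P<shift>0|[+-]\d+)$")


@dataclass(frozen=True, order=True)
class IsomiRDesignation:
    """A mature miRNA isoform named relative to its hairpin's anchors."""

    hairpin_id: str
    arm: Arm
    shift: int
    length: int = 21

    @property
    def name(self) -> str:
        shift = "0" if self.shift == 0 else format(self.shift, "+d")
        return f"{self.hairpin_id}-{self.arm}{shift}"

    @classmethod
    def parse(cls, name: str, length: int = 21) -> "IsomiRDesignation":
        m = _NAME_RE.match(name)
        if not m:
            raise ParseError(f"cannot parse isomiR name {name!r}")
        return cls(hairpin_id=m.group("hairpin"), arm=m.group("arm"),
                   shift=int(m.group("shift")), length=length)


@dataclass(frozen=True)
class Seed:
    """A miRNA seed: positions 2-7 (mer6) or 2-8 (mer7) of the mature miRNA,
    together with its block-relative code (``None`` if undefined)."""

    sequence: str
    definition: SeedDefinition
    code: str | None = None

    def __post_init__(self):
        expected = 6 if self.definition == "mer6" else 7
        if self.definition not in ("mer6", "mer7"):
            raise ValueError(f"unknown seed definition {self.definition!r}")
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.definition} seed must be {expected} nt, "
                f"got {self.sequence!r}"
            )


def mature_sequence(h: Hairpin, d: IsomiRDesignation) -> str:
    """The mature miRNA window: ``length`` nt starting at anchor(arm)+shift."""
    start = h.anchor(d.arm) + d.shift
    end = start + d.length
    if start < 0 or end > len(h.sequence):
        raise OutOfBoundsError(
            f"{d.name}: mature window [{start}, {end}) outside hairpin "
            f"{h.id} (length {len(h.sequence)})"
        )
    return h.sequence[start:end]


def _seed_window(h: Hairpin, d: IsomiRDesignation, seed_len: int) -> str:
    # Seeds depend only on the 5' end, so only the seed window itself must
    # lie inside the hairpin (the mature 3' end may be clipped by callers).
    start = h.anchor(d.arm) + d.shift + 1
    end = start + seed_len
    if start < 0 or end > len(h.sequence):
        raise OutOfBoundsError(
            f"{d.name}: seed window [{start}, {end}) outside hairpin {h.id}"
        )
    return h.sequence[start:end]


def seed_code(h: Hairpin, d: IsomiRDesignation,
              definition: SeedDefinition = "mer7") -> str:
    """Render the block-relative seed code, e.g. ``(3p)3-7CG``.

    The code lists the conserved-block positions (1-based within the 7-nt
    block) that remain inside the seed window, preceded/followed by the
    window bases outside the block.  Raises :class:`CodeUndefinedError` when
    the window no longer overlaps the block.
    """
    seed_len = 6 if definition == "mer6" else 7
    anchor = h.anchor(d.arm)
    w_start = anchor + d.shift + 1
    w_end = w_start + seed_len - 1  # inclusive
    b_start, b_end = anchor, anchor + BLOCK_LEN - 1
    first_bp = max(b_start, w_start) - anchor + 1
    last_bp = min(b_end, w_end) - anchor + 1
    if first_bp > last_bp:
        raise CodeUndefinedError(
            f"{d.name}: seed window does not overlap the conserved block"
        )
    if w_start < 0 or w_end >= len(h.sequence):
        raise OutOfBoundsError(
            f"{d.name}: seed window outside hairpin {h.id}"
        )
    leading = h.sequence[w_start:b_start] if w_start < b_start else ""
    trailing = h.sequence[b_end + 1:w_end + 1] if w_end > b_end else ""
    return f"({d.arm}){leading}{first_bp}-{last_bp}{trailing}"


def derive_seed(h: Hairpin, d: IsomiRDesignation,
                definition: SeedDefinition = "mer7") -> Seed:
    """Extract the seed of a designated isomiR.

    ``sequence`` is mature positions 2-7 (mer6) or 2-8 (mer7); ``code`` is
    the block-relative rendering (``None`` when the window has drifted off
    the block entirely).
    """
    seed_len = 6 if definition == "mer6" else 7
    seq = _seed_window(h, d, seed_len)
    try:
        code = seed_code(h, d, definition)
    except CodeUndefinedError:
        code = None
    return Seed(sequence=seq, definition=definition, code=code)


@dataclass(frozen=True)
class ParsedSeedCode:
    arm: Arm
    shift: int
    leading: str
    trailing: str
    definition: SeedDefinition

    @property
    def bases(self) -> str:
        return self.leading + self.trailing


_CODE_RE = re.compile(
    r"^\((?P<arm>5p|3p)\)(?P<lead>[ACGU]*)(?P<first>\d+)-(?P<last>\d+)"
    r"(?P<trail>[ACGU]*)$"
)


def parse_seed_code(code: str) -> ParsedSeedCode:
    """Invert :func:`seed_code`: recover (arm, shift, flanking bases, seed
    definition).  ``parse_seed_code(seed_code(h, d, defn))`` reproduces
    ``d.arm``, ``d.shift`` and ``defn`` for every designation whose window
    overlaps the block."""
    m = _CODE_RE.match(code.strip().replace("T", "U"))
    if not m:
        raise ParseError(f"malformed seed code {code!r}")
    first, last = int(m.group("first")), int(m.group("last"))
    lead, trail = m.group("lead"), m.group("trail")
    matches = []
    for definition, seed_len in (("mer6", 6), ("mer7", 7)):
        for s in range(-(seed_len + BLOCK_LEN), BLOCK_LEN + 1):
            w_start, w_end = s + 1, s + seed_len
            fb = max(0, w_start) + 1
            lb = min(BLOCK_LEN - 1, w_end) + 1
            if fb > lb:
                continue
            n_lead = max(0, -w_start)
            n_trail = max(0, w_end - (BLOCK_LEN - 1))
            if (fb, lb, n_lead, n_trail) == (first, last, len(lead), len(trail)):
                matches.append((definition, s))
    if len(matches) != 1:
        raise ParseError(
            f"seed code {code!r} does not correspond to a unique designation"
        )
    definition, shift = matches[0]
    return ParsedSeedCode(arm=m.group("arm"), shift=shift, leading=lead,
                          trailing=trail, definition=definition)


def designation_table(hairpins: Iterable[Hairpin],
                      shifts: Iterable[int] = (-1, 0, 1, 2),
                      arms: Iterable[Arm] = ("5p", "3p"),
                      length: int = 21) -> pd.DataFrame:
    """Tabulate seeds and codes for a grid of designations on each hairpin.

    Designations whose windows fall outside a hairpin are skipped.  Columns:
    hairpin_id, arm, shift, length, seed6, seed7, code6, code7.
    """
    rows = []
    for h in hairpins:
        for arm in arms:
            for shift in shifts:
                d = IsomiRDesignation(h.id, arm, shift, length)
                try:
                    s6 = derive_seed(h, d, "mer6")
                    s7 = derive_seed(h, d, "mer7")
                except OutOfBoundsError:
                    continue
                rows.append({
                    "hairpin_id": h.id, "arm": arm, "shift": shift,
                    "length": length, "seed6": s6.sequence,
                    "seed7": s7.sequence, "code6": s6.code, "code7": s7.code,
                })
    return pd.DataFrame(rows, columns=["hairpin_id", "arm", "shift", "length",
                                       "seed6", "seed7", "code6", "code7"])
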