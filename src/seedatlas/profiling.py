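"""Read-to-hairpin placement and 5'-end frequency profiles.

Short-RNA reads are placed on the hairpin sense strand at every offset where
the Hamming distance is minimal and within tolerance (no indels; small-RNA
libraries are stranded and assumed adapter-trimmed).  Reads that tie across
paralogous hairpins -- inevitable in clusters sharing the conserved blocks --
receive fractional weight 1/k so totals are conserved, or are discarded in
unique-only mode.  Per hairpin, the weighted 5'-end counts are normalized to
sum to 1, giving the end profile from which candidate isomiRs are called.
A hairpin attracting less than a configurable fraction of all cluster reads
(default 0.5%) is flagged as noise-level: its profile is typically dominated
by non-specific degradation products rather than miRNA processing.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import MalformedRecordError
from .nomenclature import Hairpin, IsomiRDesignation, to_rna

DEFAULT_LEN_RANGE = (18, 26)
DEFAULT_WINDOW = (-2, 3)
DEFAULT_CALL_THRESHOLD = 0.10
DEFAULT_NOISE_FLOOR = 0.005


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    hairpin_id: str
    start_offset: int
    mismatches: int
    weight: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def map_reads(reads: Iterable[tuple[str, str]],
              hairpins: Sequence[Hairpin],
              max_mismatch: int = 1,
              len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
              unique_only: bool = False) -> list[ReadAssignment]:
    """Place reads on hairpins at all minimum-distance offsets.

    ``reads`` yields ``(read_id, sequence)`` pairs.  Reads outside
    ``len_range`` are dropped; retained reads are placed at every offset
    achieving the global minimum Hamming distance (if <= ``max_mismatch``)
    and weighted 1/k over the k tied placements.  With ``unique_only`` the
    multi-placed reads are discarded instead.
    """
    reads = list(reads)
    if not reads:
        warnings.warn("map_reads: empty read input", stacklevel=2)
        return []
    lo, hi = len_range
    encoded = [(h.id, _encode(h.sequence), len(h.sequence)) for h in hairpins]

    # Collapse identical sequences: simulated and real small-RNA libraries
    # are highly redundant, so placement is computed once per distinct read.
    by_seq: dict[str, list[str]] = defaultdict(list)
    for i, rec in enumerate(reads):
        try:
            read_id, seq = rec
            seq = to_rna(seq)
        except Exception as exc:
            raise MalformedRecordError(
                f"malformed read record at index {i}: {exc}", record_index=i
            ) from exc
        if lo <= len(seq) <= hi:
            by_seq[seq].append(read_id)

    assignments: list[ReadAssignment] = []
    for seq in by_seq:
        arr = _encode(seq)
        L = arr.size
        placements: list[tuple[int, str, int]] = []  # (dist, hairpin, offset)
        best = max_mismatch + 1
        for hid, harr, hlen in encoded:
            if hlen < L:
                continue
            dists = (sliding_window_view(harr, L) != arr).sum(axis=1)
            m = int(dists.min())
            if m <= best:
                for off in np.flatnonzero(dists == m):
                    placements.append((m, hid, int(off)))
                best = min(best, m)
        placements = [p for p in placements if p[0] == best]
        if not placements or best > max_mismatch:
            continue
        if unique_only and len(placements) > 1:
            continue
        w = 1.0 / len(placements)
        for read_id in by_seq[seq]:
            for dist, hid, off in placements:
                assignments.append(ReadAssignment(read_id, hid, off, dist, w))
    return assignments


@dataclass
class EndProfile:
    """Normalized 5'-end frequency distribution for one hairpin.

    ``freq`` maps hairpin offset -> frequency; frequencies sum to 1 whenever
    ``n_reads`` (the weighted read count) is positive.  ``cluster_fraction``
    is this hairpin's weighted share of all cluster-assigned reads (``None``
    when the cluster total is unknown).
    """

    hairpin_id: str
    freq: dict[int, float] = field(default_factory=dict)
    n_reads: float = 0.0
    cluster_fraction: float | None = None


def end_profile(assignments: Iterable[ReadAssignment], hairpin: Hairpin,
                total_weight: float | None = None) -> EndProfile:
    counts: dict[int, float] = defaultdict(float)
    total = 0.0
    for a in assignments:
        if a.hairpin_id != hairpin.id:
            continue
        counts[a.start_offset] += a.weight
        total += a.weight
    if total == 0.0:
        return EndProfile(hairpin.id, {}, 0.0,
                          0.0 if total_weight else None)
    freq = {off: w / total for off, w in sorted(counts.items())}
    frac = total / total_weight if total_weight else None
    return EndProfile(hairpin.id, freq, total, frac)


def profile_cluster(assignments: Sequence[ReadAssignment],
                    hairpins: Sequence[Hairpin]) -> dict[str, EndProfile]:
    """End profiles for every hairpin, with cluster fractions filled in."""
    total = sum(a.weight for a in assignments)
    return {h.id: end_profile(assignments, h, total_weight=total or None)
            for h in hairpins}


@dataclass(frozen=True)
class IsomiRCall:
    designation: IsomiRDesignation
    support_fraction: float
    noise_flag: bool = False


def call_isomirs(profile: EndProfile, hairpin: Hairpin,
                 window: tuple[int, int] = DEFAULT_WINDOW,
                 call_threshold: float = DEFAULT_CALL_THRESHOLD,
                 noise_floor: float = DEFAULT_NOISE_FLOOR,
                 length: int = 21) -> list[IsomiRCall]:
    """Call candidate isomiRs from an end profile.

    One call is emitted per position within ``window`` shifts of an anchor
    whose frequency is at least ``call_threshold``; the arm is set by the
    nearer anchor.  When the hairpin's share of cluster reads is below
    ``noise_floor`` the calls are still emitted but carry ``noise_flag``.
    """
    noise = (profile.cluster_fraction is not None
             and profile.cluster_fraction < noise_floor)
    lo, hi = window
    calls = []
    for offset, f in sorted(profile.freq.items()):
        if f < call_threshold:
            continue
        s5 = offset - hairpin.anchor_5p0
        s3 = offset - hairpin.anchor_3p0
        in5 = lo <= s5 <= hi
        in3 = lo <= s3 <= hi
        if not (in5 or in3):
            continue
        if in5 and in3:  # only possible for very wide windows
            arm, shift = ("5p", s5) if abs(s5) <= abs(s3) else ("3p", s3)
        elif in5:
            arm, shift = "5p", s5
        else:
            arm, shift = "3p", s3
        d = IsomiRDesignation(hairpin.id, arm, shift, length)
        calls.append(IsomiRCall(d, support_fraction=f, noise_flag=noise))
    return calls


def strand_bias(profile: EndProfile, hairpin: Hairpin,
                window: tuple[int, int] = DEFAULT_WINDOW) -> float | None:
    """Fraction of anchored 5'-end mass on the 3p arm.

    Returns (3p-window mass) / (5p-window + 3p-window mass), or ``None``
    when both windows are empty.
    """
    lo, hi = window
    m5 = sum(f for off, f in profile.freq.items()
             if lo <= off - hairpin.anchor_5p0 <= hi)
    m3 = sum(f for off, f in profile.freq.items()
             if lo <= off - hairpin.anchor_3p0 <= hi)
    if m5 + m3 == 0.0:
        return None
    return m3 / (m5 + m3)
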