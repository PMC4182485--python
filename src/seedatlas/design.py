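"""Reporter target-site design and a discrete base-pairing validator.

Four site classes are supported, mirroring the standard miRNA-reporter
toolkit: *perfect* sites (one site, fully Watson-Crick complementary, read
out through catalytic slicing), *seed-only* sites (pairing restricted to
miRNA positions 2-8, four tandem copies for robust repression), *bulge*
sites (pairing at positions 2-8 and 13-end with a central mismatch bubble at
9-12, which blocks slicing while keeping 3'-supplementary pairing), and
*position-2 mismatch controls* that destroy seed pairing at its most
sensitive position.

Mismatched positions are built as identity mismatches: the target base is set
equal to the miRNA base, which can neither Watson-Crick nor G:U pair with
itself, so the intended non-pairing is guaranteed for any miRNA.  Cassettes
are emitted as DNA, sense strand of the 3'UTR insert.  Pairing geometry is
checked by :func:`validate_site`, a discrete stand-in for duplex structure
prediction: every designed site must reproduce its intended class verdict.

Seed matching supports the G:U wobble at seed position 8, through which a
2-7U-seed miRNA can silence the target sites of an otherwise distinct 2-7C
seed -- the mechanism by which seed repertoires overlap without seed
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nomenclature import Seed, revcomp_dna, to_dna, to_rna

SITE_CLASSES = ("perfect", "seed_only", "bulge", "mismatch_control")
DEFAULT_SPACER = "ACCA"
DEFAULT_BULGE_RANGE = (9, 12)

# fixed non-complementary padding used when the full mature sequence is not
# known at design time
_LEFT_PAD = "TCATTC"
_RIGHT_PAD = "TCA"


def _pair_state(mirna_base: str, target_base: str) -> str:
    """Classify one opposed base pair: WC, wobble (G:U/U:G) or mismatch."""
    m = mirna_base
    t = target_base.replace("T", "U")
    if (m, t) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return "WC"
    if (m, t) in (("G", "U"), ("U", "G")):
        return "wobble"
    return "mismatch"


@dataclass
class TargetSite:
    """One reporter cassette: ``n_tandem`` copies of ``unit`` joined by
    ``spacer`` (DNA, sense strand of the UTR insert).

    ``pos1_index`` is the unit index opposite miRNA position 1; miRNA
    position i faces unit index ``pos1_index - (i - 1)`` (the miRNA runs
    antiparallel to the target).  ``pairing_map`` stores the intended
    per-position pairing when the designing miRNA was known.
    """

    site_class: str
    unit: str
    pos1_index: int
    n_tandem: int = 1
    spacer: str = ""
    bulge_range: tuple[int, int] | None = None
    pairing_map: dict[int, str] = field(default_factory=dict)

    @property
    def cassette(self) -> str:
        return self.spacer.join([self.unit] * self.n_tandem)

    @property
    def seed_window(self) -> str:
        """The 7 target bases opposite miRNA positions 8..2 (5'->3')."""
        return self.unit[self.pos1_index - 7:self.pos1_index]


def design_perfect(mature: str) -> TargetSite:
    """A single site perfectly complementary to the mature miRNA."""
    m = to_rna(mature)
    if not 18 <= len(m) <= 25:
        raise ValueError(f"mature length {len(m)} outside 18-25 nt")
    unit = revcomp_dna(m)
    return TargetSite(
        site_class="perfect", unit=unit, pos1_index=len(unit) - 1,
        n_tandem=1, spacer="",
        pairing_map={i: "WC" for i in range(1, len(m) + 1)},
    )


def _seed_sequence(seed) -> str:
    if isinstance(seed, Seed):
        if seed.definition != "mer7":
            raise ValueError("site design requires a 7mer seed")
        return seed.sequence
    s = to_rna(seed)
    if len(s) != 7:
        raise ValueError(f"expected a 7mer seed, got {len(s)} nt")
    return s


def design_seed_only(seed, n_tandem: int = 4, spacer: str = DEFAULT_SPACER,
                     mature: str | None = None) -> TargetSite:
    """A site pairing Watson-Crick to miRNA positions 2-8 only.

    When ``mature`` is supplied (RNA, positions 2-8 must equal the seed),
    the flanks opposite positions 1 and 9..end are identity mismatches, so
    non-pairing outside the seed is guaranteed; otherwise fixed padding is
    used and incidental flank pairing is possible.
    """
    s = _seed_sequence(seed)
    core = revcomp_dna(s)
    pairing = {i: "WC" for i in range(2, 9)}
    if mature is not None:
        m = to_rna(mature)
        if m[1:8] != s:
            raise ValueError("mature positions 2-8 do not match the seed")
        left = "".join(to_dna(m[p - 1]) for p in range(len(m), 8, -1))
        right = to_dna(m[0]) + _RIGHT_PAD
        pairing[1] = "mismatch"
        pairing.update({p: "mismatch" for p in range(9, len(m) + 1)})
    else:
        left, right = _LEFT_PAD, _RIGHT_PAD
    unit = left + core + right
    return TargetSite(site_class="seed_only", unit=unit,
                      pos1_index=len(left) + 7, n_tandem=n_tandem,
                      spacer=spacer, pairing_map=pairing)


def design_bulge(mature: str, seed_end: int = 8,
                 bulge_range: tuple[int, int] = DEFAULT_BULGE_RANGE,
                 n_tandem: int = 4, spacer: str = DEFAULT_SPACER) -> TargetSite:
    """A bulge/bubble-mismatch site: WC at 2..seed_end and after the bulge,
    identity mismatches inside ``bulge_range`` (inclusive), position 1 left
    unpaired."""
    m = to_rna(mature)
    if len(m) < 16:
        raise ValueError(f"mature length {len(m)} < 16 nt")
    lo, hi = (bulge_range if bulge_range else (1, 0))
    bases = []
    pairing = {}
    for p in range(len(m), 0, -1):  # target built 5'->3'
        b = m[p - 1]
        if p == 1 or lo <= p <= hi:
            bases.append(to_dna(b))
            pairing[p] = "mismatch"
        else:
            bases.append(revcomp_dna(b))
            pairing[p] = "WC"
    unit = "".join(bases)
    return TargetSite(site_class="bulge", unit=unit, pos1_index=len(unit) - 1,
                      n_tandem=n_tandem, spacer=spacer,
                      bulge_range=bulge_range if bulge_range else None,
                      pairing_map=pairing)


def design_position2_control(seed, mature: str | None = None,
                             n_tandem: int = 4, spacer: str = DEFAULT_SPACER,
                             avoid_seeds=()) -> TargetSite:
    """A mismatch control: the cognate seed-only site with the target base
    opposite miRNA position 2 set to an identity mismatch.

    ``avoid_seeds`` lists seeds that must not match the mutated window; if
    one does, position 3 is identity-mutated as well.
    """
    s = _seed_sequence(seed)
    site = design_seed_only(s, n_tandem=n_tandem, spacer=spacer, mature=mature)
    unit = list(site.unit)
    unit[site.pos1_index - 1] = to_dna(s[0])  # opposite position 2
    window = "".join(unit[site.pos1_index - 7:site.pos1_index])
    if any(match_seed_to_target(t, window) for t in avoid_seeds):
        unit[site.pos1_index - 2] = to_dna(s[1])  # opposite position 3
    site.unit = "".join(unit)
    site.site_class = "mismatch_control"
    site.pairing_map = dict(site.pairing_map)
    site.pairing_map[2] = "mismatch"
    return site


def pairing_map(mature: str, site: TargetSite) -> dict[int, str]:
    """Recompute the per-position pairing of ``mature`` against ``site`` in
    the site's intended register."""
    m = to_rna(mature)
    states = {}
    for p in range(1, len(m) + 1):
        j = site.pos1_index - (p - 1)
        if 0 <= j < len(site.unit):
            states[p] = _pair_state(m[p - 1], site.unit[j])
        else:
            states[p] = "unpaired"
    return states


def classify_pairing(states: dict[int, str],
                     bulge_range: tuple[int, int] | None = None) -> str:
    """Class verdict from a pairing map: perfect / bulge / seed_only / none."""
    L = max(states)
    lo, hi = bulge_range or DEFAULT_BULGE_RANGE
    seed_ok = (all(states.get(p) == "WC" for p in range(2, 8))
               and states.get(8) in ("WC", "wobble"))
    if all(states.get(p) == "WC" for p in range(1, L + 1)):
        return "perfect"
    if not seed_ok:
        return "none"
    bulge_ok = (hi >= lo
                and all(states.get(p) == "mismatch"
                        for p in range(lo, min(hi, L) + 1))
                and all(states.get(p) == "WC" for p in range(hi + 1, L + 1))
                and hi < L)
    if bulge_ok:
        return "bulge"
    # seed-only: no substantial 3'-supplementary duplex
    run = best = 0
    for p in range(9, L + 1):
        run = run + 1 if states.get(p) == "WC" else 0
        best = max(best, run)
    if best < 4:
        return "seed_only"
    return "none"


def validate_site(mature: str, site: TargetSite) -> tuple[dict[int, str], str]:
    """Recompute the pairing map of ``mature`` vs ``site`` and classify it.

    Returns ``(pairing_map, verdict)``; a design is consistent when the
    verdict equals the site's intended class (mismatch controls validate as
    'none': their seed pairing is intentionally broken).
    """
    states = pairing_map(mature, site)
    return states, classify_pairing(states, site.bulge_range)


def match_seed_to_target(seed, site_seed_window: str,
                         allow_wobble_pos8: bool = True) -> bool:
    """Does a 7mer seed recognize a 7-nt target seed window?

    ``site_seed_window`` is the target segment opposite miRNA positions 8..2,
    given 5'->3' (i.e. ``revcomp(cognate seed)``).  True iff positions 2-7
    all pair Watson-Crick and position 8 pairs Watson-Crick or, when
    allowed, by G:U wobble.
    """
    s = _seed_sequence(seed)
    w = to_rna(site_seed_window)
    if len(w) != 7:
        raise ValueError("site seed window must be 7 nt")
    for pos in range(2, 9):
        state = _pair_state(s[pos - 2], w[8 - pos])
        if state == "WC":
            continue
        if pos == 8 and allow_wobble_pos8 and state == "wobble":
            continue
        return False
    return True


def screen_cross_reactivity(site: TargetSite, repertoire_seeds,
                            intended_seed=None,
                            allow_wobble: bool = True) -> list[tuple[str, int]]:
    """Report unintended 7mer seed matches (wobble-aware) in a cassette.

    Scans every 7-nt window of the cassette against each repertoire seed,
    skipping the intended seed.  Violations are returned, never repaired.
    """
    cassette = site.cassette
    intended = _seed_sequence(intended_seed) if intended_seed else None
    hits = []
    for t in repertoire_seeds:
        seq = _seed_sequence(t)
        if intended and seq == intended:
            continue
        for off in range(len(cassette) - 6):
            if match_seed_to_target(seq, cassette[off:off + 7], allow_wobble):
                hits.append((seq, off))
    return sorted(set(hits))
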