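"""Curated in-package fixtures for the mouse miR-290-295 and human
miR-371-373 clusters.

The hairpin sequences here are SYNTHETIC reconstructions, not genomic
sequences: each is a fixed scaffold carrying the conserved ACUCAAA/AAAGUGC
blocks at known offsets plus the seed-determining flanking bases of the
published active-seed table (position 8 and beyond of the 3p isomiRs,
position 8 of the 5p isomiRs).  Every quantity the package derives from
them -- seeds, seed codes, repertoire counts -- depends only on the blocks
and those flanks, which is exactly what the reconstructions preserve.

The reporter panels and outcome matrices transcribe the qualitative
silencing results of the underlying reporter study: which reporters were
silenced in wild-type versus cluster-knockout cells, and how silencing
responded to full-cluster, delta-hairpin and single-hairpin rescues.
Repression ratios are representative values on either side of the 0.5
binarization threshold, not measured luminescence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .activity import OutcomeMatrix, Reporter
from .nomenclature import Hairpin, IsomiRDesignation

_FILLER5 = "AUGGUUCUUCGCA"
_LOOP = "CUGUGUUC"
_FILLER3 = "AUUCAUGAUACGU"

# 3p seed extensions (positions 8-10 downstream of the AAAGUGC block).
# Position 8 fixes the 3p0 7mer seed; positions 9/10 fix the shifted seeds.
_MOUSE_EXT3 = {
    "miR-290": "CGA",
    "miR-291a": "UUC",
    "miR-291b": "AUC",
    "miR-292": "CGC",
    "miR-293": "CGC",
    "miR-294": "UCA",
    "miR-295": "UAC",
}
_HUMAN_EXT3 = {
    "miR-371": "CGC",
    "miR-372": "UGC",
    "miR-373": "UCU",
}

ANCHOR_5P0 = 2
ANCHOR_3P0 = 31


def _build_hairpin(hid: str, ext3: str, cluster_id: str,
                   species: str) -> Hairpin:
    seq = ("GG" + "ACUCAAA" + "C" + _FILLER5 + _LOOP
           + "AAAGUGC" + ext3 + _FILLER3)
    return Hairpin(id=hid, sequence=seq, anchor_5p0=ANCHOR_5P0,
                   anchor_3p0=ANCHOR_3P0, cluster_id=cluster_id,
                   species=species)


def mouse_hairpins() -> list[Hairpin]:
    """Synthetic reconstructions of the seven mouse cluster hairpins."""
    return [_build_hairpin(hid, ext3, "miR-290-295", "mus-mus")
            for hid, ext3 in _MOUSE_EXT3.items()]


def human_hairpins() -> list[Hairpin]:
    """Synthetic reconstructions of the three human cluster hairpins."""
    return [_build_hairpin(hid, ext3, "miR-371-373", "hom-sap")
            for hid, ext3 in _HUMAN_EXT3.items()]


def _d(hid: str, arm: str, shift: int) -> IsomiRDesignation:
    return IsomiRDesignation(hid, arm, shift)


def mouse_candidates() -> list[IsomiRDesignation]:
    """Sequencing-implied candidate isomiRs for the mouse cluster: every
    5p0 species (all seven perfect 5p reporters were assayed), the 3p0
    species, and the shifted 3p isoforms supported by end profiles."""
    cands = [_d(h, "5p", 0) for h in _MOUSE_EXT3]
    cands += [_d(h, "3p", 0) for h in _MOUSE_EXT3 if h != "miR-293"]
    cands += [_d("miR-292", "3p", 1), _d("miR-293", "3p", 2),
              _d("miR-295", "3p", 1)]
    return cands


def human_candidates() -> list[IsomiRDesignation]:
    return [_d("miR-371", "5p", 0), _d("miR-372", "5p", 0),
            _d("miR-373", "5p", 0),
            _d("miR-371", "3p", 0), _d("miR-371", "3p", 1),
            _d("miR-371", "3p", 2),
            _d("miR-372", "3p", 0), _d("miR-372", "3p", 1),
            _d("miR-373", "3p", 0)]


def _load_tsv(name: str):
    return resources.files("seedatlas.data") / name


@dataclass
class StudyFixture:
    cluster_id: str
    hairpins: list[Hairpin]
    reporters: list[Reporter]
    outcomes: OutcomeMatrix
    candidates: list[IsomiRDesignation]


def mouse_study() -> StudyFixture:
    from .io import read_outcomes_tsv, read_reporters_tsv
    return StudyFixture(
        cluster_id="miR-290-295",
        hairpins=mouse_hairpins(),
        reporters=read_reporters_tsv(_load_tsv("mouse_reporters.tsv")),
        outcomes=read_outcomes_tsv(_load_tsv("mouse_outcomes.tsv")),
        candidates=mouse_candidates())


def human_study() -> StudyFixture:
    from .io import read_outcomes_tsv, read_reporters_tsv
    return StudyFixture(
        cluster_id="miR-371-373",
        hairpins=human_hairpins(),
        reporters=read_reporters_tsv(_load_tsv("human_reporters.tsv")),
        outcomes=read_outcomes_tsv(_load_tsv("human_outcomes.tsv")),
        candidates=human_candidates())
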