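"""Synthetic study generator: hairpin clusters with planted conserved
blocks, short-RNA read sets with known 5'-end structure, and reporter
outcome matrices derived from a ground-truth set of active isomiRs.

The generator emulates the features the analysis depends on and nothing
more: hairpins are conserved-block scaffolds with randomized flanks (no
secondary structure is enforced, since no downstream stage consumes
structure); reads are drawn from anchored 5' ends with configurable shift
distributions plus a uniform degradation background and per-base sequencing
error; outcome matrices reproduce the experiment grid (WT, KO+empty,
KO+full-cluster, KO+delta-hairpin, KO+single-hairpin) with silencing decided
by seed matching -- including position-8 wobble cross-silencing when enabled
-- and optional per-entry flip noise.

Everything is deterministic under a fixed ``rng_seed`` (byte-identical
outputs), and every simulation returns a truth record alongside its data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .activity import (
    Condition,
    KO_EMPTY,
    KO_FULL,
    OutcomeMatrix,
    Reporter,
    WT_NONE,
    delta,
    single,
)
from .design import design_position2_control, match_seed_to_target
from .nomenclature import (
    BLOCK_3P,
    BLOCK_5P,
    Hairpin,
    IsomiRDesignation,
    derive_seed,
    hamming,
    revcomp_rna,
)

_BASES = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the empirical structure of the cluster family: reads
    concentrate at the anchored 5p0/3p0 positions with minor shifted
    isoforms, the 3p arm dominates loading, a ~0.1% degradation background
    mimics a noise-level hairpin, and position-8 flanking bases cycle
    through C/U/A/G to realize the distinct 7mer seed variants.
    """

    rng_seed: int = 0
    n_hairpins: int = 7
    arm_weights: dict = field(default_factory=lambda: {"5p": 0.2, "3p": 0.8})
    shift_dist: dict = field(default_factory=lambda: {
        "5p": {0: 1.0},
        "3p": {-1: 0.05, 0: 0.70, 1: 0.20, 2: 0.05},
    })
    read_len_dist: dict = field(default_factory=lambda: {20: 0.2, 21: 0.5,
                                                         22: 0.3})
    n_reads: int = 10000
    background_rate: float = 0.001
    error_rate: float = 0.001
    flip_noise: float = 0.0
    wobble_cross_silencing: bool = True
    pos8_palette: tuple = ("C", "U", "A", "G")
    block_mismatches: int = 0
    hairpin_weights: Sequence[float] | None = None
    mature_length: int = 21

    def validate(self) -> None:
        for name, probs in [("arm_weights", self.arm_weights),
                            ("read_len_dist", self.read_len_dist),
                            *[(f"shift_dist[{a}]", d)
                              for a, d in self.shift_dist.items()]]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate must be in [0, 1)")
        if self.hairpin_weights is not None:
            if len(self.hairpin_weights) != self.n_hairpins:
                raise ValueError("hairpin_weights length != n_hairpins")
            if abs(sum(self.hairpin_weights) - 1.0) > 1e-9:
                raise ValueError("hairpin_weights must sum to 1")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed) % (2 ** 31), stream])


def _random_bases(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate_block(block: str, n_mut: int, rng) -> str:
    if n_mut == 0:
        return block
    positions = rng.choice(len(block), size=n_mut, replace=False)
    out = list(block)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGU" if b != out[p]])
    return "".join(out)


def simulate_cluster(config: SimulationConfig) -> tuple[list[Hairpin], dict]:
    """Generate a cluster of hairpins with planted (optionally mutated)
    conserved blocks and recorded anchors.

    Layout per hairpin: 5' flank, ACUCAAA block, 5p seed extension, stem
    filler, loop, AAAGUGC block, 3p seed extension (position-8 base drawn
    from ``pos8_palette``), 3' tail.  Fillers are resampled if they ever
    recreate an exact block copy, so the planted anchors are the unique
    distance minimum.
    """
    config.validate()
    rng = _rng(config, 1)
    hairpins, truth = [], {"hairpins": {}, "config": asdict(config)}
    for i in range(config.n_hairpins):
        hid = f"hp{i + 1:02d}"
        pos8 = config.pos8_palette[i % len(config.pos8_palette)]
        block5 = _mutate_block(BLOCK_5P, config.block_mismatches, rng)
        block3 = _mutate_block(BLOCK_3P, config.block_mismatches, rng)
        while True:
            flank5 = _random_bases(rng, 4)
            ext5 = "C" + _random_bases(rng, 12)
            loop = _random_bases(rng, 8)
            ext3 = pos8 + _random_bases(rng, 2)
            tail = _random_bases(rng, 14)
            seq = flank5 + block5 + ext5 + loop + block3 + ext3 + tail
            a5 = len(flank5)
            a3 = a5 + 7 + len(ext5) + len(loop)
            # keep the planted anchors the unique distance optimum: every
            # other offset must be strictly worse than the planted blocks
            mm = config.block_mismatches
            ok = all(
                hamming(seq[off:off + 7], block) > mm
                for block, planted in ((BLOCK_5P, a5), (BLOCK_3P, a3))
                for off in range(len(seq) - 6) if off != planted)
            if ok:
                break
        h = Hairpin(id=hid, sequence=seq, anchor_5p0=a5, anchor_3p0=a3,
                    cluster_id="sim", species="synthetic")
        hairpins.append(h)
        truth["hairpins"][hid] = {
            "anchor_5p0": a5, "anchor_3p0": a3, "pos8_3p": pos8,
            "seed7_3p0": seq[a3 + 1:a3 + 8], "seed7_5p0": seq[a5 + 1:a5 + 8],
        }
    return hairpins, truth


def simulate_reads(hairpins: Sequence[Hairpin], truth: dict,
                   config: SimulationConfig) -> tuple[list[tuple[str, str]], dict]:
    """Draw reads with anchored 5' ends plus a uniform degradation
    background and per-base sequencing error."""
    config.validate()
    rng = _rng(config, 2)
    weights = (np.asarray(config.hairpin_weights, dtype=float)
               if config.hairpin_weights is not None
               else np.full(len(hairpins), 1.0 / len(hairpins)))
    arms = sorted(config.arm_weights)
    arm_p = np.array([config.arm_weights[a] for a in arms])
    lens = sorted(config.read_len_dist)
    len_p = np.array([config.read_len_dist[x] for x in lens])

    reads, read_truth = [], {"reads": {}, "generating": {
        "arm_weights": config.arm_weights,
        "shift_dist": config.shift_dist,
        "background_rate": config.background_rate,
    }}
    for j in range(config.n_reads):
        rid = f"read{j:06d}"
        hi = int(rng.choice(len(hairpins), p=weights))
        h = hairpins[hi]
        if rng.random() < config.background_rate:
            L = int(rng.choice(lens, p=len_p))
            start = int(rng.integers(0, len(h.sequence) - L + 1))
            info = {"hairpin": h.id, "background": True, "start": start}
        else:
            arm = str(rng.choice(arms, p=arm_p))
            shifts = sorted(config.shift_dist[arm])
            shift = int(rng.choice(shifts,
                                   p=[config.shift_dist[arm][s]
                                      for s in shifts]))
            L = int(rng.choice(lens, p=len_p))
            start = h.anchor(arm) + shift
            L = min(L, len(h.sequence) - start)
            info = {"hairpin": h.id, "background": False, "arm": arm,
                    "shift": shift, "start": start}
        seq = list(h.sequence[start:start + L])
        if config.error_rate > 0:
            errs = np.flatnonzero(rng.random(len(seq)) < config.error_rate)
            for p in errs:
                seq[p] = str(rng.choice([b for b in "ACGU" if b != seq[p]]))
        reads.append((rid, "".join(seq)))
        read_truth["reads"][rid] = info
    return reads, read_truth


# --------------------------------------------------------------------------
# reporter outcomes
# --------------------------------------------------------------------------

def default_reporter_panel(hairpins: Sequence[Hairpin],
                           candidates: Sequence[IsomiRDesignation]
                           ) -> list[Reporter]:
    """A reporter panel covering a candidate set: one perfect reporter per
    candidate strand, and one bulge reporter (plus its position-2 mismatch
    control) per distinct candidate 7mer seed."""
    hp = {h.id: h for h in hairpins}
    reporters = []
    for hid, arm in sorted({(d.hairpin_id, d.arm) for d in candidates}):
        reporters.append(Reporter(
            id=f"{hid}-{arm}-P", site_class="perfect",
            cognate_designation=IsomiRDesignation(hid, arm, 0), n_tandem=1))
    all_seeds = sorted({derive_seed(hp[d.hairpin_id], d, "mer7").sequence
                        for d in candidates})
    seen = set()
    for d in sorted(set(candidates), key=lambda d: d.name):
        s7 = derive_seed(hp[d.hairpin_id], d, "mer7").sequence
        if s7 in seen:
            continue
        seen.add(s7)
        ctrl = design_position2_control(s7, avoid_seeds=all_seeds)
        reporters.append(Reporter(
            id=f"{s7}-B", site_class="bulge", cognate_designation=d,
            cognate_seed=s7, n_tandem=4, control_id=f"{s7}-Bc"))
        reporters.append(Reporter(
            id=f"{s7}-Bc", site_class="mismatch_control", n_tandem=4,
            site_window=ctrl.seed_window))
    return reporters


def _available(truth_active, cond: Condition):
    if cond.cluster_present:
        return list(truth_active)
    if cond.construct == "delta_hairpin":
        return [d for d in truth_active if d.hairpin_id != cond.target]
    if cond.construct == "single_hairpin":
        return [d for d in truth_active if d.hairpin_id == cond.target]
    return []


def _reporter_silenced(r: Reporter, available, hp, wobble: bool) -> bool:
    if r.site_class == "perfect":
        cog = r.cognate_designation
        return any(d.hairpin_id == cog.hairpin_id and d.arm == cog.arm
                   for d in available)
    window = r.seed_window()
    if window is None:
        return False
    return any(match_seed_to_target(
        derive_seed(hp[d.hairpin_id], d, "mer7").sequence, window,
        allow_wobble_pos8=wobble) for d in available)


def simulate_outcomes(truth_active: Sequence[IsomiRDesignation],
                      reporters: Sequence[Reporter],
                      config: SimulationConfig,
                      hairpins: Sequence[Hairpin]
                      ) -> tuple[OutcomeMatrix, dict]:
    """Generate an outcome matrix over the standard experiment grid.

    A reporter is silenced under a condition iff some truth-active isomiR
    available in that condition matches its site (perfect sites by hairpin
    strand, seed-class sites by 7mer seed with optional wobble).  Ratios are
    drawn from disjoint silenced/unsilenced bands; ``flip_noise`` flips the
    binary outcome per entry before the ratio is drawn.
    """
    config.validate()
    rng = _rng(config, 3)
    hp = {h.id: h for h in hairpins}
    conditions = [WT_NONE, KO_EMPTY, KO_FULL]
    for hid in sorted({d.hairpin_id for d in truth_active} |
                      {r.cognate_designation.hairpin_id for r in reporters
                       if r.cognate_designation is not None}):
        conditions += [delta(hid), single(hid)]
    entries = {}
    truth = {"active": [d.name for d in truth_active], "entries": {}}
    for r in sorted(reporters, key=lambda x: x.id):
        for cond in conditions:
            sil = _reporter_silenced(r, _available(truth_active, cond), hp,
                                     config.wobble_cross_silencing)
            if config.flip_noise > 0 and rng.random() < config.flip_noise:
                sil = not sil
            ratio = (rng.uniform(0.1, 0.4) if sil
                     else rng.uniform(0.8, 1.2))
            entries[(r.id, cond)] = ratio
            truth["entries"][f"{r.id}|{cond.label()}"] = bool(sil)
    return OutcomeMatrix(entries), truth


def expected_activity(truth_active: Sequence[IsomiRDesignation],
                      candidates: Sequence[IsomiRDesignation],
                      hairpins: Sequence[Hairpin],
                      wobble: bool = True) -> dict[str, str]:
    """The status the rule engine should recover from a noise-free outcome
    matrix: truth members are ``active`` (``redundant_source`` when an
    active isomiR from another hairpin also matches their target sites,
    e.g. by wobble), everything else ``inactive``."""
    hp = {h.id: h for h in hairpins}
    seeds = {d: derive_seed(hp[d.hairpin_id], d, "mer7").sequence
             for d in set(truth_active) | set(candidates)}
    expected = {}
    for d in candidates:
        if d not in truth_active:
            expected[d.name] = "inactive"
            continue
        window = revcomp_rna(seeds[d])
        redundant = any(
            o.hairpin_id != d.hairpin_id
            and match_seed_to_target(seeds[o], window,
                                     allow_wobble_pos8=wobble)
            for o in truth_active)
        expected[d.name] = "redundant_source" if redundant else "active"
    return expected
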