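"""Rule-based assignment of functionally active isomiRs from reporter
silencing outcomes.

The experimental design this engine encodes: luciferase reporters carrying
miRNA target sites are assayed across genetic backgrounds (wild-type cells,
cluster-knockout cells) and rescue constructs (the full cluster, the cluster
with one hairpin deleted, a single hairpin, an empty vector).  Repression
ratios are normalized to a no-site control (1 = no silencing) and binarized
at a configurable threshold.

Evidence is combined per candidate isomiR designation:

* Perfect-site reporters are specific for their cognate hairpin strand, so
  they give *strand-level* evidence: silencing under a cluster-present
  condition that disappears in the knockout establishes cluster-dependent
  activity of that strand; absence of silencing rules the strand out.
* Seed-only and bulge reporters give *isoform-level* evidence via their
  7mer seed window, with optional G:U wobble recognition at seed position 8.
  A silenced seed reporter whose position-2 mismatch control is not silenced
  confirms seed-mediated repression.  A negative bulge outcome is conclusive;
  a negative seed-only outcome is not (seed-only sites can fail for seeds
  that bulged sites readily detect), and leaves the candidate unresolved.
* Delta-hairpin / single-hairpin rescues attribute activity: silencing by the
  single hairpin that is lost on its deletion attributes the isoform solely
  to that hairpin; silencing retained after deletion marks the hairpin as a
  redundant source (e.g. wobble cross-silencing by paralogs); a single
  hairpin that fails to silence its cognate reporter rules the isoform out
  for that hairpin.

Conflicting evidence yields status ``unresolved`` rather than a majority
vote.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .design import match_seed_to_target
from .errors import MissingConditionError
from .nomenclature import (
    Hairpin,
    IsomiRDesignation,
    Seed,
    derive_seed,
    revcomp_rna,
)

DEFAULT_SILENCING_THRESHOLD = 0.5

BACKGROUNDS = ("WT", "KO")
CONSTRUCTS = ("none", "empty_vector", "full_cluster", "delta_hairpin",
              "single_hairpin")

ACTIVE_STATUSES = frozenset({"active", "redundant_source"})


@dataclass(frozen=True, order=True)
class Condition:
    """A genetic background plus transfected construct.

    ``target`` names the hairpin for delta_hairpin / single_hairpin
    constructs and is empty otherwise.
    """

    background: str
    construct: str = "none"
    target: str = ""

    def __post_init__(self):
        if self.background not in BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.construct in ("delta_hairpin", "single_hairpin") and not self.target:
            raise ValueError(f"{self.construct} requires a target hairpin")

    @property
    def cluster_present(self) -> bool:
        """Full cluster expression available (WT cells or full rescue)."""
        return (self.background == "WT" and self.construct == "none") or \
            self.construct == "full_cluster"

    @property
    def cluster_absent(self) -> bool:
        return self.background == "KO" and self.construct in ("none",
                                                              "empty_vector")

    def label(self) -> str:
        s = f"{self.background}+{self.construct}"
        return f"{s}({self.target})" if self.target else s


WT_NONE = Condition("WT", "none")
KO_EMPTY = Condition("KO", "empty_vector")
KO_FULL = Condition("KO", "full_cluster")


def delta(hairpin_id: str) -> Condition:
    return Condition("KO", "delta_hairpin", hairpin_id)


def single(hairpin_id: str) -> Condition:
    return Condition("KO", "single_hairpin", hairpin_id)


@dataclass(frozen=True)
class Reporter:
    """One luciferase reporter.

    ``cognate_designation`` is required for perfect sites (they are hairpin/
    strand specific); seed-class reporters carry ``cognate_seed`` (7mer) and
    optionally the designation they were built to detect.  ``site_window``
    overrides the seed window (used for mismatch controls, whose window is
    deliberately broken); by default it is ``revcomp(cognate_seed)``.
    ``control_id`` links a reporter to its position-2 mismatch control.
    """

    id: str
    site_class: str
    cognate_designation: IsomiRDesignation | None = None
    cognate_seed: str | None = None
    n_tandem: int = 1
    control_id: str | None = None
    site_window: str | None = None

    def seed_window(self) -> str | None:
        if self.site_window:
            return self.site_window
        if self.cognate_seed:
            return revcomp_rna(self.cognate_seed)
        return None


class OutcomeMatrix:
    """Sparse (reporter, condition) -> repression ratio matrix.

    Ratios are firefly/Renilla activities normalized to the no-site control,
    so 1 means no silencing and values near 0 mean strong silencing.
    """

    def __init__(self, entries: Mapping[tuple[str, Condition], float]):
        self.entries = dict(entries)
        for (rid, cond), ratio in self.entries.items():
            if ratio <= 0:
                raise ValueError(
                    f"repression ratio must be positive: {rid} {cond.label()}"
                )

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "OutcomeMatrix":
        """Build from (reporter_id, background, construct, target, ratio)."""
        entries = {}
        for rid, background, construct, target, ratio in records:
            cond = Condition(background, construct, target or "")
            entries[(rid, cond)] = float(ratio)
        return cls(entries)

    def ratio(self, reporter_id: str, cond: Condition) -> float | None:
        return self.entries.get((reporter_id, cond))

    def silenced(self, reporter_id: str, cond: Condition,
                 threshold: float = DEFAULT_SILENCING_THRESHOLD) -> bool | None:
        r = self.ratio(reporter_id, cond)
        return None if r is None else classify_silenced(r, threshold)

    def conditions(self, reporter_id: str) -> list[Condition]:
        return sorted(c for rid, c in self.entries if rid == reporter_id)

    def reporter_ids(self) -> list[str]:
        return sorted({rid for rid, _ in self.entries})


def classify_silenced(ratio: float,
                      threshold: float = DEFAULT_SILENCING_THRESHOLD) -> bool:
    """Binarize a repression ratio; the boundary is inclusive (ratio ==
    threshold counts as silenced)."""
    if ratio <= 0:
        raise ValueError("repression ratio must be positive")
    return ratio <= threshold


@dataclass
class ActivityCall:
    designation: IsomiRDesignation
    status: str  # active | inactive | redundant_source | unresolved
    evidence: list[str] = field(default_factory=list)
    attributed_to: str | None = None
    seed7: str | None = None

    @property
    def is_active(self) -> bool:
        return self.status in ACTIVE_STATUSES


@dataclass
class _ReporterSummary:
    reporter: Reporter
    positive: bool  # silenced under a cluster-present condition
    negative: bool  # measured but unsilenced under every present condition
    background_silenced: bool  # silenced with the cluster absent
    control_clean: bool | None  # mismatch control unsilenced where main silenced
    has_data: bool


def _summarize_reporter(r: Reporter, outcomes: OutcomeMatrix,
                        threshold: float) -> _ReporterSummary:
    conds = outcomes.conditions(r.id)
    present = [c for c in conds if c.cluster_present]
    absent = [c for c in conds if c.cluster_absent]
    pos_conds = [c for c in present if outcomes.silenced(r.id, c, threshold)]
    positive = bool(pos_conds)
    negative = bool(present) and not positive
    background = any(outcomes.silenced(r.id, c, threshold) for c in absent)
    control_clean: bool | None = None
    if r.control_id and pos_conds:
        states = [outcomes.silenced(r.control_id, c, threshold)
                  for c in pos_conds]
        states = [s for s in states if s is not None]
        if states:
            control_clean = not any(states)
    return _ReporterSummary(r, positive, negative, background, control_clean,
                            has_data=bool(conds))


def assign_activity(reporters: Sequence[Reporter], outcomes: OutcomeMatrix,
                    hairpins: Iterable[Hairpin],
                    candidates: Sequence[IsomiRDesignation] | None = None,
                    threshold: float = DEFAULT_SILENCING_THRESHOLD,
                    allow_wobble: bool = True,
                    strict: bool = False) -> list[ActivityCall]:
    """Infer an activity status for every candidate isomiR designation.

    ``candidates`` defaults to the cognate designations of the supplied
    reporters.  The result is sorted by designation name and independent of
    the input ordering.  With ``strict`` a candidate with no usable evidence
    raises :class:`MissingConditionError` instead of returning unresolved.
    """
    hp = {h.id: h for h in hairpins}
    reporters = sorted(reporters, key=lambda r: r.id)
    if candidates is None:
        candidates = [r.cognate_designation for r in reporters
                      if r.cognate_designation is not None
                      and r.site_class != "mismatch_control"]
    candidates = sorted(set(candidates), key=lambda d: d.name)
    strand_counts = Counter((d.hairpin_id, d.arm) for d in candidates)

    perfect = [r for r in reporters if r.site_class == "perfect"
               and r.cognate_designation is not None]
    seed_reps = [r for r in reporters
                 if r.site_class in ("seed_only", "bulge")
                 and r.seed_window() is not None]
    summaries = {r.id: _summarize_reporter(r, outcomes, threshold)
                 for r in reporters}

    calls = []
    for d in candidates:
        if d.hairpin_id not in hp:
            raise KeyError(f"candidate {d.name} references unknown hairpin")
        h = hp[d.hairpin_id]
        seed7 = derive_seed(h, d, "mer7").sequence
        tags: set[str] = set()
        conflict = False
        inactive_reason = None

        # --- strand-level evidence from perfect-site reporters -----------
        strand = "unknown"
        strand_reps = [r for r in perfect
                       if r.cognate_designation.hairpin_id == d.hairpin_id
                       and r.cognate_designation.arm == d.arm]
        for r in strand_reps:
            s = summaries[r.id]
            if not s.has_data:
                continue
            if s.background_silenced:
                tags.add("background_silencing")
                conflict = True
            if s.positive:
                strand = "positive"
                tags.add("cluster_dependent")
                if outcomes.silenced(r.id, KO_FULL, threshold):
                    tags.add("rescue_confirmed")
                # attribution carried by hairpin-specific perfect sites
                sng = outcomes.silenced(r.id, single(d.hairpin_id), threshold)
                dlt = outcomes.silenced(r.id, delta(d.hairpin_id), threshold)
                if sng and dlt is False:
                    tags.add("single_hairpin_rescue")
            elif s.negative and strand != "positive":
                strand = "negative"

        # --- isoform-level evidence from seed-class reporters ------------
        exact_pos = wobble_pos = False
        seed_only_negative = bulge_negative = False
        attributed = redundant = single_negative = False
        for r in seed_reps:
            window = r.seed_window()
            exact = (r.cognate_seed is not None
                     and r.cognate_seed.replace("T", "U").upper() == seed7)
            if not exact and not (allow_wobble
                                  and match_seed_to_target(seed7, window, True)):
                continue
            s = summaries[r.id]
            if not s.has_data:
                continue
            if s.background_silenced:
                tags.add("background_silencing")
                conflict = True
                continue
            if s.positive:
                if s.control_clean is False:
                    tags.add("control_silenced")
                    conflict = True
                    continue
                if s.control_clean:
                    tags.add("seed_mediated")
                if exact:
                    exact_pos = True
                else:
                    wobble_pos = True
                    tags.add("wobble_evidence")
                sng = outcomes.silenced(r.id, single(d.hairpin_id), threshold)
                dlt = outcomes.silenced(r.id, delta(d.hairpin_id), threshold)
                if sng and dlt is False:
                    attributed = True
                    tags.add("single_hairpin_rescue")
                if dlt:
                    redundant = True
                    tags.add("delta_retained")
                if sng is False:
                    single_negative = True
                    tags.add("not_produced_by_hairpin")
            elif s.negative and exact:
                if r.site_class == "bulge":
                    bulge_negative = True
                    tags.add("bulge_reporter_negative")
                else:
                    seed_only_negative = True
                    tags.add("seed_only_negative")

        # --- combine ------------------------------------------------------
        if conflict:
            status = "unresolved"
        elif strand == "negative":
            status = "inactive"
            tags.add("perfect_reporter_negative")
        elif single_negative:
            status = "inactive"
        elif exact_pos or wobble_pos:
            status = "redundant_source" if redundant and not attributed \
                else "active"
        elif bulge_negative:
            status = "inactive"
        elif strand == "positive":
            if seed_only_negative:
                status = "unresolved"
            elif strand_counts[(d.hairpin_id, d.arm)] == 1:
                status = "active"
            else:
                status = "unresolved"
                tags.add("shared_strand_evidence_only")
        else:
            if seed_only_negative:
                status = "unresolved"
            else:
                missing = [(r.id, c.label()) for r in strand_reps
                           for c in (WT_NONE, KO_EMPTY, KO_FULL)] or \
                          [(d.name, c.label())
                           for c in (WT_NONE, KO_EMPTY, KO_FULL)]
                if strict:
                    raise MissingConditionError(
                        f"no usable evidence for {d.name}", missing=missing)
                status = "unresolved"
                tags.add("no_evidence")

        attributed_to = d.hairpin_id if (
            status in ACTIVE_STATUSES
            and (attributed
                 or (strand == "positive"
                     and "single_hairpin_rescue" in tags)
                 or (status == "active" and strand == "positive"
                     and strand_counts[(d.hairpin_id, d.arm)] == 1))
        ) and not redundant else None

        calls.append(ActivityCall(designation=d, status=status,
                                  evidence=sorted(tags),
                                  attributed_to=attributed_to, seed7=seed7))
    return calls


def active_seed_set(calls: Iterable[ActivityCall],
                    hairpins: Iterable[Hairpin],
                    definition: str = "mer7",
                    arm: str | None = None) -> list[Seed]:
    """Distinct seeds of the active (including redundant-source) calls,
    ordered by seed code; optionally restricted to one arm."""
    hp = {h.id: h for h in hairpins}
    seen: dict[str, Seed] = {}
    for call in sorted(calls, key=lambda c: c.designation.name):
        if not call.is_active:
            continue
        if arm is not None and call.designation.arm != arm:
            continue
        seed = derive_seed(hp[call.designation.hairpin_id], call.designation,
                           definition)
        seen.setdefault(seed.sequence, seed)
    return sorted(seen.values(), key=lambda s: (s.code or "", s.sequence))
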