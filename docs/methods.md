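# Methods

## The anchored coordinate system

The cluster family is defined by two conserved blocks, `ACUCAAA` on the 5′
arm and `AAAGUGC` on the 3′ arm of each pre-miRNA stem.  `anchor_hairpin`
finds the offset pair minimizing the total Hamming distance to the two
blocks, subject to the 5p block ending before the 3p block starts and to a
per-block mismatch tolerance (default 2; some lineages deviate from the
consensus, e.g. a UG variant of the CG extension in Afrotherian clusters).
Ties break to the leftmost 5p offset, then the leftmost 3p offset, so
anchoring is deterministic.  Matching is Hamming-only: the blocks are 7 nt,
and indel placement inside them would be under-determined.  Coordinates are
0-based half-open internally; display names use the 5p0/3p0/±N convention.

A designation's mature sequence is the `length`-nt window (default 21 nt)
starting at `anchor(arm) + shift`.  Seeds are mature positions 2–7 (6mer)
or 2–8 (7mer) and never depend on the 3′ end, so `length` only gates
window-bounds checks.  Seed codes render the block positions retained in
the seed window plus the flanking bases that complete it: shift +1, 7mer →
`(3p)3-7CG`.  For negative shifts the window retains block positions from 1
and is preceded by |shift|−1 bases 5′ of the block (at shift −1 the window
starts exactly at the block); such codes are our generalization — only
non-negative shifts occur in the published tables — and are constrained by
the round-trip property `parse_seed_code(seed_code(d)) == d`, which holds
for every window that still overlaps a block.

## 5′-end profiling

Reads (assumed adapter-trimmed, 18–26 nt by default) are placed on the
hairpin sense strand at every offset achieving the minimum Hamming distance
(≤ 1 mismatch by default, no indels).  Paralogous hairpins share the
conserved blocks, so multi-mapping is inevitable; tied placements receive
fractional weight 1/k (totals are conserved), with a unique-only mode as an
option.  Identical read sequences are collapsed before placement, which
makes the scan linear in distinct sequences.

Per hairpin, weighted 5′-end counts are normalized to sum to 1.  Candidate
isomiRs are called at positions within −2…+3 of an anchor whose frequency
is ≥ 0.10; both values are configuration, chosen because empirical end
profiles concentrate the large majority of mass on one or two positions per
arm, so a 10% floor separates processing products from scatter.  A hairpin
attracting < 0.5% of all cluster-assigned reads is flagged noise-level: at
that abundance the end distribution varies between libraries and is
dominated by non-specific degradation (the empirical motivation is a
cluster member observed at ~0.1% of cluster reads with library-dependent
end profiles).  Strand bias is the 3p-window share of anchored mass,
reported as missing when both windows are empty.

## The activity rule engine

Reporter experiments are encoded as a sparse (reporter, condition) →
repression-ratio matrix, ratios normalized to a no-site control (1 = no
silencing) and binarized at ratio ≤ 0.5.  The published contrasts are
large, so binarization loses little and makes the inference testable; the
threshold is configurable and the boundary is inclusive.

Evidence is combined per candidate isomiR designation (candidates come from
sequencing-implied end profiles, or default to the reporters' cognates):

1. **Strand evidence** (perfect-complementarity sites, which are specific
   for their cognate hairpin strand): silencing under a cluster-present
   condition (wild type, or knockout + full-cluster rescue) that is absent
   under a cluster-absent condition establishes the strand; a measured
   negative rules every isomiR of that strand out.  Silencing with the
   cluster absent is a conflict ("background silencing") and the call is
   left unresolved.
2. **Isoform evidence** (seed-only and bulge sites, matched to candidates
   by their 7mer seed, including position-8 G:U wobble recognition when
   enabled): a silenced reporter whose position-2 mismatch control is clean
   confirms seed-mediated repression.  Negative bulge outcomes are
   conclusive; negative seed-only outcomes are not — seed-only sites
   demonstrably fail for seeds that bulged sites detect — and leave the
   candidate unresolved.
3. **Attribution** (Δ-hairpin / single-hairpin rescues): silencing by the
   single hairpin that disappears on its deletion attributes the isoform
   solely to that hairpin; silencing retained after deletion marks the
   hairpin a `redundant_source` (paralogs, possibly via wobble, reach the
   same sites); a single hairpin that fails to silence the cognate reporter
   rules the isoform out for that hairpin even when the reporter is
   otherwise silenced.

Cluster-present positives are required for activity in all cases
(heterologous rescue experiments have no wild-type arm, so "cluster
present" includes the full-cluster rescue).  When several candidates share
a strand and only strand evidence exists, none of them can be singled out
and they are left unresolved rather than voted on — this is what keeps the
two sequencing-implied +1 isoforms with non-conserved position-8 bases
unresolved, matching the cautious published interpretation.  Conflicting
evidence always yields `unresolved` with the conflicting tags attached,
never a majority vote.  The engine is order-independent in its inputs, and
adding a consistent single-hairpin observation never demotes an active
call.

## Reporter design and the discrete pairing model

Thermodynamic duplex prediction is replaced by a discrete base-pairing
model: positions pair Watson–Crick, G:U wobble, or mismatch, in the fixed
register implied by the site design.  This is a deliberate simplification —
it cannot score pairing energies or alternative registers — but every
designed class is defined by *which* positions pair, not how strongly, so a
positional model suffices for design and validation; the limitation is that
validator verdicts on arbitrary (non-designed) sequences are approximate.

Mismatches are built as identity mismatches (target base := miRNA base),
which can neither WC- nor wobble-pair, so intended non-pairing is
guaranteed for any miRNA.  Perfect sites are single full reverse
complements.  Seed-only sites pair positions 2–8 only, with position 1 left
unpaired (no t1A convention is imposed) and, when the full mature sequence
is supplied, identity-mismatch flanks; four tandem copies joined by an
`ACCA` spacer are the default, since seed-restricted sites repress weakly
as single copies.  Bulge sites pair 2–8 and 13–end with identity
mismatches at 9–12, blocking cleavage-mode silencing while keeping
3′-supplementary pairing.  Position-2 controls are seed-only sites with the
base opposite position 2 identity-mutated (escalating to position 3 if a
listed seed still matches the mutated window).  The validator recomputes
the pairing map from sequences and classifies the site; designed sites must
reproduce their intended class, and a cross-reactivity screen reports —
never repairs — unintended 7mer matches in a cassette.  Overlapping isomiR
seeds inherently match shifted registers of each other's sites; the screen
surfaces this, which is precisely why position-2 controls exist.

## Repertoires and evolution

Repertoires are sets of seed sequences with provenance (contributing
designations and their status).  Comparison is plain set algebra; a private
seed whose sites are recognized by a shared seed through the position-8
wobble is reported as *bridged* but never merged into the shared set, since
seed identity and target-repertoire overlap are different claims.

Hairpin clustering uses a global Needleman–Wunsch alignment (match 0,
mismatch 1, gap 1, no affine term) and the p-distance
(mismatches + gaps) / alignment columns.  Among co-optimal alignments the
column count can differ, so the traceback deterministically prefers
diagonal over up over left.  A full progressive multiple alignment is not
reimplemented: the tree serves as an ordering of hairpins, not a
quantitative phylogeny, and pairwise distances preserve that intent without
wrapping an external aligner.  UPGMA is average-linkage with ties broken by
the lexicographically smallest leaf label; its output is ultrametric by
construction (tested to 1e-9) and reproduces ultrametric inputs exactly.

Seed gain/loss uses Fitch small parsimony for binary presence/absence
characters on a user-supplied rooted Newick tree; a 14-species placental
topology (Xenarthra + Afrotheria + Boreoeutheria) ships as the default
fixture.  On trees of ≤ 16 leaves all minimal ancestral labelings are
enumerated, so each gain/loss is placed on an edge with an explicit
"in all optima" flag; larger trees report a single minimal labeling
(parent-state preference).  Likelihood models, branch-length estimation and
hairpin duplication/deletion histories are out of scope — only the seed
presence/absence layer is reconstructed.

## Synthetic data

The generator emulates exactly the features the analysis consumes.
Hairpins are scaffolds — 5′ flank, 5p block, seed extension, stem filler,
loop, 3p block, 3p seed extension, tail (56 nt) — with position-8 bases
cycled through a C/U/A/G palette to realize distinct 7mer seed variants,
and fillers resampled until the planted anchors are the strict distance
optimum.  No secondary structure is enforced: no downstream stage consumes
structure.  Reads start at anchor + shift with a configurable per-arm shift
distribution (defaults: 3p-dominant arms at 0.8, shift mass 0.70/0.20/0.05/
0.05 on 0/+1/+2/−1), lengths 20–22 nt, a uniform-start degradation
background at rate 0.001 (mirroring the ~0.1% noise-level hairpin), and
per-base substitution errors at 0.001.  Outcome matrices cover the standard
experiment grid (WT, KO+empty, KO+full, KO+Δh, KO+single-h per hairpin);
silencing is decided by the same seed-matching rules the engine assumes,
with wobble cross-silencing switchable and optional per-entry flip noise.
Everything is deterministic under `rng_seed` (byte-identical outputs), with
truth records returned alongside the data.

What passing the closed-loop tests shows: mapping, profiling, calling and
the rule engine invert the generator exactly under its stated conditions
(weights ≥ 0.15, background ≤ 5%, error ≤ 1%, n = 10,000; noise-free
outcome matrices).  What it does not show: robustness to ligation/PCR bias,
crosslinking bias between arms, adapter artifacts or indel sequencing
errors, none of which are modeled.

## Fixtures and problem sizes

The packaged mouse/human study fixtures use synthetic hairpin
reconstructions (conserved blocks plus the published seed-determining
flanking bases at 3p positions 8–10 and 5p position 8) and outcome matrices
transcribing the qualitative silencing results, with representative ratios
on either side of the 0.5 threshold.  Counts derived from them — active 5p
species, distinct active 3p seeds, conserved seeds, per-hairpin
attributions, post-elimination seed brackets — depend only on the blocks,
the flanks and the outcome pattern, all of which the fixtures preserve.
Simulation-backed tests run at 3,000–10,000 reads and 2–10 hairpins, sizes
at which the recovery tolerances above are comfortably resolved while the
whole suite completes in well under a minute.
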