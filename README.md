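# seedatlas

Seed-repertoire analysis for clusters of homologous pre-miRNA hairpins of
the miR-290-295 (mouse) / miR-371-373 (human) family.

Every hairpin in this cluster family carries two deeply conserved sequence
blocks — `ACUCAAA` on the 5′ strand of the stem and `AAAGUGC` on the 3′
strand.  Because Drosha/Dicer cleavage sites drift between paralogs and
species, one hairpin can produce several overlapping mature miRNAs
(*isomiRs*) whose 5′ ends, and therefore whose seeds (positions 2–7, the
6mer, or 2–8, the 7mer), differ.  `seedatlas` makes this analyzable:

* **Anchored nomenclature** — the first base of each conserved block defines
  reference positions `5p0`/`3p0`; an isomiR shifted N nt toward the hairpin
  3′ end is `5p+N`/`3p+N`, and its seed gets a block-relative code such as
  `(3p)3-7CG` (block positions 3–7 retained, completed by the flanking
  bases `CG`).  Codes round-trip through a parser.
* **5′-end profiling** — Hamming placement of short-RNA reads on hairpins
  (fractional weights for multi-mappers), per-hairpin 5′-end frequency
  profiles normalized to 1, isomiR calling with a support threshold, strand
  bias, and noise flagging for hairpins below a cluster-share floor.
* **Functional assignment** — a rule engine that turns luciferase-reporter
  silencing outcomes across genetic backgrounds (wild type, cluster
  knockout) and rescue constructs (full cluster, Δ-hairpin, single hairpin)
  into per-isomiR activity calls: `active`, `inactive`,
  `redundant_source` (active, but other hairpins silence the same sites,
  e.g. through the position-8 G:U wobble) or `unresolved`.
* **Reporter design** — perfect, seed-only (4× tandem), bulge-mismatch and
  position-2 control target sites, with a discrete pairing validator that
  recomputes each site's class from sequence.
* **Repertoire evolution** — seed-set comparison with wobble-equivalence
  reporting, p-distance + UPGMA clustering of hairpins, and Fitch parsimony
  gain/loss reconstruction on a species tree (a placental-mammal topology
  ships with the package).
* **Synthetic data** — a deterministic generator for hairpin clusters,
  read sets and outcome matrices with full ground-truth records, used by
  the test suite for closed-loop recovery checks.

## Worked example

The package ships transcribed reporter-outcome fixtures for the mouse and
human clusters (synthetic hairpin reconstructions carry the conserved
blocks plus the seed-determining flanking bases).  Running the rule engine
and printing the non-inactive calls:

```python
import seedatlas as sa
from seedatlas.datasets import mouse_study, human_study

mouse = mouse_study()
calls = sa.assign_activity(mouse.reporters, mouse.outcomes,
                           mouse.hairpins, mouse.candidates)
for c in calls:
    if c.status != "inactive":
        print(c.designation.name, c.status, c.seed7)
```

```
isomiR            status            seed (7mer)  code
miR-290-5p0       active            CUCAAAC      (5p)2-7C
miR-291a-3p0      active            AAGUGCU      (3p)2-7U
miR-292-3p+1      active            AGUGCCG      (3p)3-7CG
miR-292-3p0       redundant_source  AAGUGCC      (3p)2-7C
miR-292-5p0       active            CUCAAAC      (5p)2-7C
miR-293-3p+2      active            GUGCCGC      (3p)4-7CGC
miR-294-3p0       active            AAGUGCU      (3p)2-7U
miR-295-3p+1      unresolved        AGUGCUA      (3p)3-7UA
miR-295-3p0       active            AAGUGCU      (3p)2-7U
```

Two 5p isomiRs are active and share one seed; four distinct 3p seeds are
active.  `miR-292-3p0` is active but a *redundant source*: deleting its
hairpin leaves its reporters silenced, because 2-7U-seed miRNAs recognize
the same sites through a G:U wobble at seed position 8.  `miR-295-3p+1`
stays unresolved — its seed-only reporter was negative, and seed-only
sites are unreliable for exactly this seed class.  Comparing the mouse and
human active 3p repertoires:

```python
m = sa.Repertoire.from_calls("miR-290-295", calls, mouse.hairpins, arm="3p")
# ... same for the human study ...
cmp_ = sa.compare_repertoires(m, h)
```

```
shared 3p seeds:   AAGUGCU, AGUGCCG, GUGCCGC
mouse-only:        AAGUGCC
wobble-bridged:    AAGUGCC -> AAGUGCU
```

Three active 3p seeds are conserved; the mouse-only `AAGUGCC` seed does not
expand the target repertoire because the shared `AAGUGCU` seed reaches its
sites via the wobble.

A CLI mirrors the stages (`seedatlas anchor | profile | assign | design |
evolve | simulate`); `seedatlas simulate --seed 5 --out-dir sim/` writes a
synthetic cluster FASTA, a FASTQ read set and a JSON truth record.

## Layout

```
src/seedatlas/
  nomenclature.py   anchors, isomiR names, seed derivation and codes
  profiling.py      read mapping, end profiles, isomiR calls, strand bias
  activity.py       outcome matrices and the activity rule engine
  design.py         target-site design + discrete pairing validator
  evolution.py      repertoires, p-distance, UPGMA, Fitch parsimony
  simulate.py       synthetic clusters/reads/outcomes with truth records
  datasets.py       in-package mouse/human study fixtures
  io.py             FASTA/FASTQ/TSV/JSON surfaces
  cli.py            click command group
docs/methods.md     model, parameters, assumptions and limitations
```
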