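"""Readers and writers for the package's file surfaces.

Standard formats go through established libraries: FASTA/FASTQ via
Bio.SeqIO, trees via dendropy (see :mod:`seedatlas.evolution`), tabular
data via pandas.  Hairpin FASTA ids may encode ``cluster|species|hairpin``;
a configurable regex extracts the fields.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .activity import ActivityCall, OutcomeMatrix, Reporter
from .errors import MalformedRecordError
from .nomenclature import Hairpin, IsomiRDesignation, anchor_hairpin, to_rna
from .profiling import EndProfile, IsomiRCall

DEFAULT_ID_PATTERN = r"^(?:(?P<cluster>[^|]*)\|(?P<species>[^|]*)\|)?(?P<hairpin>.+)$"


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_reads(path) -> list[tuple[str, str]]:
    """Read a FASTA or FASTQ file of short-RNA reads (format by suffix)."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(p), fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str]], path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_hairpins(path, id_pattern: str = DEFAULT_ID_PATTERN,
                  max_mismatch: int = 2) -> list[Hairpin]:
    """Read hairpins from FASTA and anchor each one."""
    pattern = re.compile(id_pattern)
    hairpins = []
    for i, (rid, seq) in enumerate(read_fasta(path)):
        m = pattern.match(rid)
        if not m:
            raise MalformedRecordError(
                f"hairpin id {rid!r} does not match id pattern",
                record_index=i)
        groups = m.groupdict()
        a5, a3 = anchor_hairpin(seq, max_mismatch=max_mismatch)
        hairpins.append(Hairpin(
            id=groups.get("hairpin") or rid, sequence=to_rna(seq),
            anchor_5p0=a5, anchor_3p0=a3,
            cluster_id=groups.get("cluster") or "",
            species=groups.get("species") or ""))
    return hairpins


def anchors_to_dataframe(hairpins: Sequence[Hairpin]) -> pd.DataFrame:
    rows = [{"hairpin_id": h.id, "cluster_id": h.cluster_id,
             "species": h.species, "anchor_5p0": h.anchor_5p0,
             "anchor_3p0": h.anchor_3p0,
             "block5_mismatches": h.block_distances()[0],
             "block3_mismatches": h.block_distances()[1]}
            for h in hairpins]
    return pd.DataFrame(rows)


def profiles_to_dataframe(profiles: dict[str, EndProfile],
                          hairpins: Sequence[Hairpin]) -> pd.DataFrame:
    hp = {h.id: h for h in hairpins}
    rows = []
    for hid, prof in sorted(profiles.items()):
        h = hp[hid]
        for offset, freq in sorted(prof.freq.items()):
            rel5 = offset - h.anchor_5p0
            rel3 = offset - h.anchor_3p0
            rel = rel5 if abs(rel5) <= abs(rel3) else rel3
            arm = "5p" if abs(rel5) <= abs(rel3) else "3p"
            rows.append({"hairpin_id": hid, "offset": offset,
                         "nearest_anchor": arm,
                         "offset_relative_to_nearest_anchor": rel,
                         "freq": freq})
    return pd.DataFrame(rows, columns=["hairpin_id", "offset",
                                       "nearest_anchor",
                                       "offset_relative_to_nearest_anchor",
                                       "freq"])


def calls_to_dataframe(calls: Iterable[IsomiRCall]) -> pd.DataFrame:
    rows = [{"isomir": c.designation.name,
             "hairpin_id": c.designation.hairpin_id,
             "arm": c.designation.arm, "shift": c.designation.shift,
             "support_fraction": c.support_fraction,
             "noise_flag": c.noise_flag} for c in calls]
    return pd.DataFrame(rows, columns=["isomir", "hairpin_id", "arm",
                                       "shift", "support_fraction",
                                       "noise_flag"])


def read_reporters_tsv(path) -> list[Reporter]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    reporters = []
    for _, row in df.iterrows():
        cog = None
        if row.get("cognate_hairpin"):
            cog = IsomiRDesignation(row["cognate_hairpin"],
                                    row["cognate_arm"],
                                    int(row["cognate_shift"]))
        reporters.append(Reporter(
            id=row["reporter_id"], site_class=row["site_class"],
            cognate_designation=cog,
            cognate_seed=row.get("cognate_seed") or None,
            n_tandem=int(row["n_tandem"]) if row.get("n_tandem") else 1,
            control_id=row.get("control_id") or None,
            site_window=row.get("site_window") or None))
    return reporters


def write_reporters_tsv(reporters: Sequence[Reporter], path) -> None:
    rows = []
    for r in reporters:
        d = r.cognate_designation
        rows.append({
            "reporter_id": r.id, "site_class": r.site_class,
            "cognate_hairpin": d.hairpin_id if d else "",
            "cognate_arm": d.arm if d else "",
            "cognate_shift": d.shift if d else "",
            "cognate_seed": r.cognate_seed or "",
            "n_tandem": r.n_tandem, "control_id": r.control_id or "",
            "site_window": r.site_window or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_outcomes_tsv(path) -> OutcomeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"reporter_id": str,
                                            "background": str,
                                            "construct": str,
                                            "construct_target": str,
                                            "ratio": float})
    df["construct_target"] = df["construct_target"].fillna("")
    return OutcomeMatrix.from_records(
        df[["reporter_id", "background", "construct", "construct_target",
            "ratio"]].itertuples(index=False, name=None))


def write_outcomes_tsv(outcomes: OutcomeMatrix, path) -> None:
    rows = [{"reporter_id": rid, "background": c.background,
             "construct": c.construct, "construct_target": c.target,
             "ratio": ratio}
            for (rid, c), ratio in sorted(outcomes.entries.items(),
                                          key=lambda kv: (kv[0][0], kv[0][1]))]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def activity_calls_to_dataframe(calls: Iterable[ActivityCall]) -> pd.DataFrame:
    rows = [{"isomir": c.designation.name, "status": c.status,
             "attributed_to": c.attributed_to or "",
             "seed7": c.seed7 or "",
             "evidence": ";".join(c.evidence)} for c in calls]
    return pd.DataFrame(rows, columns=["isomir", "status", "attributed_to",
                                       "seed7", "evidence"])


def repertoire_to_json(repertoire, path=None) -> str:
    payload = {
        "schema": "seedatlas.repertoire/1",
        "cluster_id": repertoire.cluster_id,
        "definition": repertoire.definition,
        "seeds": [{"sequence": s.sequence, "code": s.code,
                   "definition": s.definition,
                   "provenance": [
                       {"isomir": name, "status": status}
                       for name, status in
                       repertoire.provenance.get(s.sequence, [])]}
                  for s in sorted(repertoire.seeds.values(),
                                  key=lambda s: (s.code or "", s.sequence))],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def repertoire_from_json(path):
    from .evolution import Repertoire
    from .nomenclature import Seed
    payload = json.loads(Path(path).read_text())
    rep = Repertoire(cluster_id=payload["cluster_id"])
    for entry in payload["seeds"]:
        seed = Seed(sequence=entry["sequence"],
                    definition=entry["definition"], code=entry.get("code"))
        rep.seeds[seed.sequence] = seed
        rep.provenance[seed.sequence] = [
            (p["isomir"], p["status"]) for p in entry.get("provenance", [])]
    return rep
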