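"""Annotated reference protein database construction.

Venom-tissue proteins are labeled by their best similarity to a small set
of toxin-family representatives (E-value <= 0.1 by default, bit-score then
alphabetical family tie-breaks); records with no qualifying hit become
``other_toxin``.  The labeled venom set is then merged with the general
protein set, whose remaining records are labeled ``physiological``, so that
every record in the final database carries exactly one label.

Representatives ship as an editable FASTA with ``family=<name>`` header
tokens; the general/venom split is carried by ``source=general`` /
``source=venom_tissue`` tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from . import simsearch
from .seqcore import (LABEL_OTHER_TOXIN, LABEL_PHYSIOLOGICAL, toxin_label,
                      write_fasta)

SOURCE_GENERAL = "general"
SOURCE_VENOM = "venom_tissue"


class ReferenceDBError(ValueError):
    pass


@dataclass
class ProteinRecord:
    id: str
    seq: str
    source: str = SOURCE_GENERAL
    label: Optional[str] = None


@dataclass(frozen=True)
class FamilyRepresentative:
    family: str
    seq: str
    id: str = ""


@dataclass
class ReferenceDB:
    """Labeled protein records plus the family-representative set."""

    records: list[ProteinRecord]
    representatives: list[FamilyRepresentative] = field(default_factory=list)
    build_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ReferenceDBError("duplicate record ids in reference DB")

    @property
    def by_id(self) -> dict[str, ProteinRecord]:
        return {r.id: r for r in self.records}

    @property
    def total_residues(self) -> int:
        return sum(len(r.seq) for r in self.records)


def label_by_representatives(venom_set: list[ProteinRecord],
                             reps: list[FamilyRepresentative],
                             max_evalue: float = 1e-1,
                             scheme: Optional[simsearch.ScoringScheme] = None
                             ) -> list[ProteinRecord]:
    """Assign each venom-tissue record the family of its best representative
    hit, or ``other_toxin`` when no hit reaches ``max_evalue``.

    "Best" is lowest E-value, then highest bit score, then alphabetically
    first family name.
    """
    if not reps:
        raise ReferenceDBError("representative set is empty")
    scheme = scheme or simsearch.ScoringScheme.protein()
    rep_db = [(f"{r.family}#{i}", r.seq) for i, r in enumerate(reps)]
    family_of_rep = {rid: rep.family for (rid, _), rep in zip(rep_db, reps)}
    labeled: list[ProteinRecord] = []
    for rec in venom_set:
        if rec.source != SOURCE_VENOM:
            raise ReferenceDBError(
                f"record {rec.id!r} is not a venom_tissue record")
        hits = simsearch.search((rec.id, rec.seq), rep_db, scheme,
                                max_evalue=max_evalue, max_hits=None)
        if hits:
            hits.sort(key=lambda h: (h.evalue, -h.bit_score,
                                     family_of_rep[h.subject_id]))
            label = toxin_label(family_of_rep[hits[0].subject_id])
        else:
            label = LABEL_OTHER_TOXIN
        labeled.append(ProteinRecord(rec.id, rec.seq, rec.source, label))
    return labeled


def merge(general_set: list[ProteinRecord],
          labeled_venom_set: list[ProteinRecord]) -> ReferenceDB:
    """Merge the general set with the labeled venom set by record id.

    Records present in both take the venom-set label; general-only records
    become physiological.  Conflicting sequences under one id are an error.
    """
    by_id: dict[str, ProteinRecord] = {}
    for rec in general_set:
        by_id[rec.id] = ProteinRecord(rec.id, rec.seq, rec.source,
                                      LABEL_PHYSIOLOGICAL)
    for rec in labeled_venom_set:
        if rec.label is None:
            raise ReferenceDBError(f"venom record {rec.id!r} is unlabeled")
        if rec.id in by_id and by_id[rec.id].seq != rec.seq:
            raise ReferenceDBError(
                f"conflicting sequences for id {rec.id!r} during merge")
        by_id[rec.id] = ProteinRecord(rec.id, rec.seq, SOURCE_VENOM,
                                      rec.label)
    records = [by_id[k] for k in sorted(by_id)]
    log: dict[str, int] = {}
    for rec in records:
        log[rec.label] = log.get(rec.label, 0) + 1
    return ReferenceDB(records=records, build_log=log)


def build(general_set: list[ProteinRecord],
          venom_set: list[ProteinRecord],
          reps: list[FamilyRepresentative],
          max_evalue: float = 1e-1) -> ReferenceDB:
    """Full database build: label the venom set, then merge."""
    labeled = label_by_representatives(venom_set, reps, max_evalue)
    db = merge(general_set, labeled)
    db.representatives = list(reps)
    return db


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\b(\w+)=([^\s]+)")


def _header_tokens(description: str) -> dict[str, str]:
    return dict(_TOKEN.findall(description))


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA with ``source=general|venom_tissue`` tokens."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _header_tokens(rec.description)
        source = tokens.get("source", SOURCE_GENERAL)
        if source not in (SOURCE_GENERAL, SOURCE_VENOM):
            raise ReferenceDBError(
                f"{path}: record {rec.id!r}: unknown source {source!r}")
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), source))
    return records


def read_representatives(path) -> list[FamilyRepresentative]:
    """Read a representatives FASTA with ``family=<name>`` tokens."""
    reps = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _header_tokens(rec.description)
        if "family" not in tokens:
            raise ReferenceDBError(
                f"{path}: record {rec.id!r} lacks a family=<name> token")
        reps.append(FamilyRepresentative(family=tokens["family"],
                                         seq=str(rec.seq).upper(),
                                         id=rec.id))
    per_family: dict[str, int] = {}
    for r in reps:
        per_family[r.family] = per_family.get(r.family, 0) + 1
    for fam, n in per_family.items():
        if not 1 <= n <= 4:
            raise ReferenceDBError(
                f"family {fam!r} has {n} representatives (expected 1-4)")
    return reps


def write_db(db: ReferenceDB, out_dir) -> None:
    """Serialize as FASTA plus a tab-separated label table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.id, r.seq) for r in db.records], out / "reference.fasta",
                descriptions={r.id: f"source={r.source}" for r in db.records})
    with open(out / "labels.tsv", "w") as fh:
        fh.write("id\tsource\tlabel\n")
        for r in db.records:
            fh.write(f"{r.id}\t{r.source}\t{r.label}\n")
    if db.representatives:
        write_fasta([(r.id or f"rep{i}", r.seq)
                     for i, r in enumerate(db.representatives)],
                    out / "representatives.fasta",
                    descriptions={(r.id or f"rep{i}"): f"family={r.family}"
                                  for i, r in enumerate(db.representatives)})


def load_db(in_dir) -> ReferenceDB:
    """Load a database serialized by :func:`write_db`."""
    in_dir = Path(in_dir)
    labels: dict[str, tuple[str, str]] = {}
    with open(in_dir / "labels.tsv") as fh:
        next(fh)  # header
        for line in fh:
            rid, source, label = line.rstrip("\n").split("\t")
            labels[rid] = (source, label)
    records = []
    for rec in SeqIO.parse(str(in_dir / "reference.fasta"), "fasta"):
        source, label = labels[rec.id]
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), source,
                                     label))
    reps_path = in_dir / "representatives.fasta"
    reps = read_representatives(reps_path) if reps_path.exists() else []
    db = ReferenceDB(records=records, representatives=reps)
    for r in records:
        db.build_log[r.label] = db.build_log.get(r.label, 0) + 1
    return db
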