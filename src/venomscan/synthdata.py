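"""Deterministic paired-transcriptome simulator with planted ground truth.

Emulates the statistical structure the annotation pipeline assumes:

* housekeeping transcripts present in both telson and chela (optionally
  mutated in the chela copy to exercise the identity threshold);
* toxin transcripts only in the telson, each a planted signal-peptide
  leader plus a family-template mature peptide, back-translated with
  uniformly chosen synonymous codons, and highly similar (>= ~85% amino
  acid identity) to reference records of the same family;
* novel-family transcripts sharing a leader and cysteine scaffold within
  each family but absent from the reference and known-protein sets, with
  read counts forced above the high-expression selection threshold;
* noise transcripts: random nucleotides without planted structure.

A fixed seed makes every output byte-identical.  Before returning, the
generator verifies its own plants with the toolkit's search engine: every
toxin must hit its family's reference records at E <= 1e-5, novel members
must not, and planted leaders must be detected by the signal-peptide
heuristic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from . import seqcore, sigpep, simsearch
from .discover import KnownProtein
from .refdb import (SOURCE_GENERAL, SOURCE_VENOM, FamilyRepresentative,
                    ProteinRecord)
from .seqcore import Transcript, write_counts_table, write_fasta


class SynthDataError(RuntimeError):
    """A generated dataset failed its own plant verification."""


#: leaders with charged n-region, strong h-region and small -3/-1 residues,
#: detectable by the built-in signal-peptide heuristic by construction
DEFAULT_LEADER_POOL = (
    "MKVFLLLLVISAVMVSTAHG",
    "MKRLVVVLLIGLLFASSSHA",
    "MKAVLIVLLVTLAVCSPVGA",
    "MNKVLLAIFLVVLLVSESEA",
)

#: inter-cysteine gap templates; distinct cysteine counts (6, 4, 7, 3) keep
#: families from cross-linking during scaffold clustering
DEFAULT_SCAFFOLD_POOL = (
    (3, 6, 4, 6, 3),
    (6, 4, 8),
    (2, 5, 2, 5, 1, 3),
    (10, 3),
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_C = _AA20.replace("C", "")
_NT = "ACGT"


@dataclass
class SimConfig:
    """Generator settings; the defaults are the standard study conditions
    used across the test-bed."""

    seed: int = 1
    n_housekeeping: int = 20
    n_toxin_per_family: dict = field(
        default_factory=lambda: {"alpha-NaTx": 5, "alpha-KTx": 5})
    n_novel_families: int = 2
    novel_family_size: int = 3
    n_noise: int = 10
    mutation_rate_orthologue: float = 0.0
    read_lognormal_mean: float = 4.5
    read_lognormal_sigma: float = 1.0
    leader_pool: tuple = DEFAULT_LEADER_POOL
    scaffold_pool: tuple = DEFAULT_SCAFFOLD_POOL
    #: forced per-member coverage fraction for novel families (relative to
    #: the full telson coverage, hence a lower bound on the post-pipeline
    #: fraction); disable with force_novel_high=False to test the exclusion
    #: branch of the 0.5% selection rule
    novel_expression_fraction: float = 0.008
    force_novel_high: bool = True
    avg_read_len: int = 150
    verify: bool = True

    def __post_init__(self) -> None:
        needed = len(self.n_toxin_per_family) + self.n_novel_families
        if needed > len(self.leader_pool):
            raise ValueError(
                f"{needed} families requested but leader_pool has only "
                f"{len(self.leader_pool)} leaders")
        if needed > len(self.scaffold_pool):
            raise ValueError(
                f"{needed} families requested but scaffold_pool has only "
                f"{len(self.scaffold_pool)} scaffolds")
        for name in ("n_housekeeping", "n_novel_families",
                     "novel_family_size", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticDataset:
    telson: list[Transcript]
    chela: list[Transcript]
    reference: list[ProteinRecord]
    representatives: list[FamilyRepresentative]
    known: list[KnownProtein]
    manifest: dict


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

_BACKTABLE: Optional[dict[str, list[str]]] = None


def _backtable() -> dict[str, list[str]]:
    global _BACKTABLE
    if _BACKTABLE is None:
        std = CodonTable.unambiguous_dna_by_id[1]
        table: dict[str, list[str]] = {}
        for codon, aa in std.forward_table.items():
            table.setdefault(aa, []).append(codon)
        for aa in table:
            table[aa].sort()
        table["*"] = sorted(std.stop_codons)
        _BACKTABLE = table
    return _BACKTABLE


def back_translate(peptide: str, rng: np.random.Generator,
                   stop: bool = True) -> str:
    """Back-translate with uniformly chosen synonymous codons."""
    table = _backtable()
    codons = [table[aa][rng.integers(len(table[aa]))] for aa in peptide]
    if stop:
        codons.append(table["*"][rng.integers(3)])
    return "".join(codons)


def _random_peptide(rng: np.random.Generator, length: int,
                    alphabet: str = _AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet),
                                                     size=length))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[i] for i in rng.integers(4, size=length))


def make_scaffold_mature(rng: np.random.Generator, gaps: tuple,
                         head: int = 3, tail: int = 6) -> str:
    """A mature peptide carrying cysteines at the scaffold's spacing and
    no cysteine anywhere else."""
    parts = [_random_peptide(rng, head, _AA_NO_C), "C"]
    for g in gaps:
        parts.append(_random_peptide(rng, g, _AA_NO_C))
        parts.append("C")
    parts.append(_random_peptide(rng, tail, _AA_NO_C))
    return "".join(parts)


def mutate_peptide(peptide: str, rng: np.random.Generator,
                   n_mutations: int) -> str:
    """Substitute ``n_mutations`` non-cysteine positions with non-cysteine
    residues, preserving the cysteine scaffold exactly."""
    positions = [i for i, c in enumerate(peptide) if c != "C"]
    if not positions:
        return peptide
    chosen = rng.choice(len(positions), size=min(n_mutations, len(positions)),
                        replace=False)
    out = list(peptide)
    for k in np.sort(chosen):
        i = positions[int(k)]
        alternatives = _AA_NO_C.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def mutate_nt(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = _NT.replace(out[int(i)], "")
        out[int(i)] = alternatives[rng.integers(3)]
    return "".join(out)


def _draw_count(rng: np.random.Generator, cfg: SimConfig) -> int:
    return int(rng.lognormal(cfg.read_lognormal_mean,
                             cfg.read_lognormal_sigma)) + 1


def _coding_transcript(pep: str, rng: np.random.Generator,
                       max_utr3: int = 16, tries: int = 50) -> str:
    """Back-translate ``pep`` into a transcript whose longest ORF is the
    planted one.

    Synonymous codon choice occasionally creates a longer spurious ORF on
    the reverse strand (reverse reading frames of a random CDS often lack
    stop codons); such draws are rejected and redrawn, keeping the output
    deterministic for a fixed generator state.
    """
    for _ in range(tries):
        seq = back_translate(pep, rng) + _random_nt(
            rng, int(rng.integers(0, max_utr3)))
        orf = seqcore.longest_orf(
            seqcore.find_orfs(Transcript("tmp", seq, 1, "telson")))
        if orf is not None and orf.peptide == pep:
            return seq
    raise SynthDataError(
        f"could not embed peptide as the longest ORF after {tries} draws")


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate(cfg: Optional[SimConfig] = None) -> SyntheticDataset:
    """Generate one paired telson/chela study with ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    families = list(cfg.n_toxin_per_family)
    truth: dict[str, dict] = {}

    # family templates, representatives, reference venom records
    representatives: list[FamilyRepresentative] = []
    reference: list[ProteinRecord] = []
    known: list[KnownProtein] = []
    templates: dict[str, str] = {}
    leaders: dict[str, str] = {}
    for fi, fam in enumerate(families):
        gaps = cfg.scaffold_pool[fi]
        template = make_scaffold_mature(rng, gaps)
        templates[fam] = template
        leaders[fam] = cfg.leader_pool[fi]
        representatives.append(FamilyRepresentative(
            family=fam, seq=template, id=f"rep_{fam}"))
        for k in range(3):
            n_mut = int(rng.integers(1, max(2, len(template) // 12)))
            variant = mutate_peptide(template, rng, n_mut)
            reference.append(ProteinRecord(
                f"venomref_{fam}_{k}", variant, SOURCE_VENOM))
        known.append(KnownProtein(f"known_{fam}", template,
                                  f"Toxin {fam} precursor"))

    # housekeeping: shared between tissues
    telson: list[Transcript] = []
    chela: list[Transcript] = []
    for i in range(cfg.n_housekeeping):
        pep = "M" + _random_peptide(rng, int(rng.integers(119, 200)))
        cds = back_translate(pep, rng)
        utr5 = _random_nt(rng, int(rng.integers(0, 31)))
        utr3 = _random_nt(rng, int(rng.integers(0, 31)))
        seq = utr5 + cds + utr3
        count = _draw_count(rng, cfg)
        tid = f"telson_hk_{i}"
        telson.append(Transcript(tid, seq, count, "telson"))
        chela_seq = mutate_nt(seq, rng, cfg.mutation_rate_orthologue)
        chela.append(Transcript(f"chela_hk_{i}", chela_seq,
                                _draw_count(rng, cfg), "chela"))
        reference.append(ProteinRecord(f"genref_hk_{i}", pep, SOURCE_GENERAL))
        truth[tid] = {"true_class": "housekeeping", "leader_span": None,
                      "scaffold": None, "read_count": count,
                      "chela_orthologue": f"chela_hk_{i}"}

    # planted toxins (telson only)
    for fi, fam in enumerate(families):
        template, leader = templates[fam], leaders[fam]
        for i in range(cfg.n_toxin_per_family[fam]):
            n_mut = int(rng.integers(1, max(2, int(0.10 * len(template)))))
            mature = mutate_peptide(template, rng, n_mut)
            pep = leader + mature
            seq = _coding_transcript(pep, rng)
            count = max(_draw_count(rng, cfg),
                        int(np.ceil(8.0 * len(seq) / cfg.avg_read_len)))
            tid = f"telson_tox_{fam}_{i}"
            telson.append(Transcript(tid, seq, count, "telson"))
            truth[tid] = {
                "true_class": f"toxin:{fam}",
                "leader_span": [0, 3 * len(leader)],
                "scaffold": seqcore.cysteine_pattern(mature).spacing,
                "read_count": count}

    # novel families: shared leader + scaffold, absent from every database
    novel_seqs: list[tuple[str, str, str]] = []  # (id, peptide, mature)
    for j in range(cfg.n_novel_families):
        slot = len(families) + j
        leader = cfg.leader_pool[slot]
        gaps = cfg.scaffold_pool[slot]
        template = make_scaffold_mature(rng, gaps, head=4, tail=8)
        for i in range(cfg.novel_family_size):
            n_mut = int(rng.integers(0, max(2, int(0.06 * len(template)))))
            mature = mutate_peptide(template, rng, n_mut)
            pep = leader + mature
            seq = _coding_transcript(pep, rng)
            tid = f"telson_nov{j}_{i}"
            telson.append(Transcript(tid, seq, 1, "telson"))  # count set below
            novel_seqs.append((tid, pep, mature))
            truth[tid] = {
                "true_class": f"novel:{j}",
                "leader_span": [0, 3 * len(leader)],
                "scaffold": seqcore.cysteine_pattern(mature).spacing,
                "read_count": None}

    # noise: unstructured sequence
    for i in range(cfg.n_noise):
        seq = _random_nt(rng, int(rng.integers(200, 401)))
        count = _draw_count(rng, cfg)
        tid = f"telson_noise_{i}"
        telson.append(Transcript(tid, seq, count, "telson"))
        truth[tid] = {"true_class": "noise", "leader_span": None,
                      "scaffold": None, "read_count": count}

    # read counts for novel members: force above the selection threshold
    novel_ids = {tid for tid, _, _ in novel_seqs}
    base_cov = sum(cfg.avg_read_len * t.read_count / len(t.seq)
                   for t in telson if t.id not in novel_ids)
    k = len(novel_ids)
    f = cfg.novel_expression_fraction
    for t in telson:
        if t.id not in novel_ids:
            continue
        if cfg.force_novel_high:
            target_cov = f * base_cov / (1.0 - k * f)
            t.read_count = int(np.ceil(target_cov * len(t.seq)
                                       / cfg.avg_read_len))
        else:
            # low-expression branch: coverage ~3, well below both the
            # coverage cutoff (5) and the 0.5% selection rule
            t.read_count = max(1, int(np.ceil(3.0 * len(t.seq)
                                              / cfg.avg_read_len)))
        truth[t.id]["read_count"] = t.read_count

    # extra known-set distractors
    for i in range(3):
        known.append(KnownProtein(f"known_hyp_{i}",
                                  _random_peptide(rng, 80),
                                  "Hypothetical protein"))

    class_counts: dict[str, int] = {}
    for entry in truth.values():
        key = entry["true_class"].split(":")[0]
        class_counts[key] = class_counts.get(key, 0) + 1
    manifest = {
        "seed": cfg.seed,
        "class_counts": class_counts,
        "n_telson": len(telson),
        "n_chela": len(chela),
        "families": families,
        "novel_families": [f"novel:{j}" for j in
                           range(cfg.n_novel_families)],
        "transcripts": truth,
    }
    dataset = SyntheticDataset(telson=telson, chela=chela,
                               reference=reference,
                               representatives=representatives,
                               known=known, manifest=manifest)
    if cfg.verify:
        _verify(dataset, cfg)
    return dataset


def _verify(ds: SyntheticDataset, cfg: SimConfig) -> None:
    """Check the plants with the toolkit's own machinery before release."""
    scheme = simsearch.ScoringScheme.protein()
    ref_db = [(r.id, r.seq) for r in ds.reference]
    fam_of_ref = {r.id: r.id.split("_")[1] if r.id.startswith("venomref_")
                  else None for r in ds.reference}
    for t in ds.telson:
        entry = ds.manifest["transcripts"][t.id]
        cls = entry["true_class"]
        if cls.startswith("toxin:") or cls.startswith("novel:"):
            orf = seqcore.longest_orf(seqcore.find_orfs(t))
            if orf is None:
                raise SynthDataError(f"{t.id}: planted ORF not recovered")
            hits = simsearch.search((t.id, orf.peptide), ref_db, scheme,
                                    max_evalue=1e-5, max_hits=1)
            if cls.startswith("toxin:"):
                fam = cls.split(":", 1)[1]
                if not hits or fam_of_ref[hits[0].subject_id] != fam:
                    raise SynthDataError(
                        f"{t.id}: planted toxin does not hit its family")
            else:
                if hits:
                    raise SynthDataError(
                        f"{t.id}: novel member hits the reference database")
                if not sigpep.predict_signal(orf.peptide).present:
                    raise SynthDataError(
                        f"{t.id}: planted novel leader not detected")


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write all study inputs plus the ground-truth manifest to a directory.

    Returns the path of each artifact.  Output is byte-identical for a
    fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "telson": out / "telson.fasta",
        "telson_counts": out / "telson_counts.tsv",
        "chela": out / "chela.fasta",
        "chela_counts": out / "chela_counts.tsv",
        "reference": out / "reference.fasta",
        "representatives": out / "representatives.fasta",
        "known": out / "known.fasta",
        "manifest": out / "ground_truth.json",
    }
    write_fasta([(t.id, t.seq) for t in ds.telson], paths["telson"])
    write_counts_table({t.id: t.read_count for t in ds.telson},
                       paths["telson_counts"])
    write_fasta([(t.id, t.seq) for t in ds.chela], paths["chela"])
    write_counts_table({t.id: t.read_count for t in ds.chela},
                       paths["chela_counts"])
    write_fasta([(r.id, r.seq) for r in ds.reference], paths["reference"],
                descriptions={r.id: f"source={r.source}"
                              for r in ds.reference})
    write_fasta([(r.id, r.seq) for r in ds.representatives],
                paths["representatives"],
                descriptions={r.id: f"family={r.family}"
                              for r in ds.representatives})
    write_fasta([(k.id, k.seq) for k in ds.known], paths["known"],
                descriptions={k.id: k.description for k in ds.known})
    with open(paths["manifest"], "w") as fh:
        json.dump(ds.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
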