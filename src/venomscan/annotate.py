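"""The telson annotation pipeline and its composition reports.

Seven steps, applied in order to a telson (venom-gland) transcriptome with
its chela (pincer) control:

(i)    coverage normalization: ``avg_read_len * read_count / length``;
(ii)   background subtraction: telson transcripts whose best chela hit
       passes E <= 1e-50, identity >= 99% and query coverage >= 95% are
       removed as shared housekeeping orthologues;
(iii)  ORF prediction (ATG-only, six frames); transcripts with no ORF of at
       least ``orf_min_nt`` are dropped as partial/incomplete;
(iv)   annotation: each transcript's longest ORF is searched against the
       labeled reference database (E <= 1e-5, best hit only) and inherits
       the hit's label, else becomes ``unidentified``;
(v)    coverage cutoff: transcripts with coverage strictly below 5 are
       removed (coverage exactly 5 survives);
(vi)   orthology reconciliation: surviving transcripts recorded in the
       step-(ii) orthologue map are relabeled ``physiological``; the venom
       set is everything labeled with a toxin family or ``other_toxin``;
(vii)  validation: highly expressed toxins (>= 0.5% of total surviving
       coverage by default) get a signal-peptide prediction, advisory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from . import seqcore, sigpep, simsearch
from .refdb import ReferenceDB
from .seqcore import (LABEL_PHYSIOLOGICAL, LABEL_UNIDENTIFIED, Orf,
                      Transcript, is_venom_label, is_toxin_family_label,
                      toxin_family_of)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the pipeline (defaults as used throughout)."""

    avg_read_len: int = 150
    orthologue_max_evalue: float = 1e-50
    orthologue_min_identity_pct: float = 99.0
    orthologue_min_query_cov_pct: float = 95.0
    annotation_max_evalue: float = 1e-5
    coverage_cutoff: float = 5.0
    high_expression_fraction: float = 0.005
    orf_min_nt: int = 75
    # strict: the orthologue map holds only transcripts actually removed at
    # step (ii), making step (vi) a consistency re-assertion; loose: the map
    # also records sub-threshold best chela hits (E-value pass only), which
    # step (vi) then relabels physiological.
    strict_orthologue_relabel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("orthologue_max_evalue", "annotation_max_evalue",
                     "coverage_cutoff", "avg_read_len", "orf_min_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.high_expression_fraction < 1.0:
            raise ValueError("high_expression_fraction must be in (0, 1)")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class CompositionReport:
    """Per-label transcript counts and coverage fractions plus the
    step-by-step attrition log."""

    label_counts: dict[str, int]
    family_counts: dict[str, int]
    label_coverage: dict[str, float]
    label_coverage_frac: dict[str, float]
    family_coverage_frac: dict[str, float]
    total_coverage: float
    attrition: list[dict]


@dataclass
class PipelineResult:
    transcripts: list[Transcript]           # survivors, labeled
    report: CompositionReport
    orthologue_map: dict[str, str]
    orfs: dict[str, Orf]                    # per surviving transcript
    best_hits: dict[str, simsearch.AlignmentHit]
    signal_validation: list[dict]
    removed_orthologues: list[Transcript]
    dropped_no_orf: list[Transcript]
    dropped_low_coverage: list[Transcript]


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def compute_coverage(read_count: int, transcript_length: int,
                     avg_read_len: int = 150) -> float:
    """Normalized expression proxy: avg read length * count / length."""
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return avg_read_len * read_count / transcript_length


def compute_all_coverage(transcripts: list[Transcript],
                         avg_read_len: int = 150) -> None:
    for t in transcripts:
        t.coverage = compute_coverage(t.read_count, len(t.seq), avg_read_len)


def remove_chela_orthologues(telson: list[Transcript],
                             chela: list[Transcript],
                             cfg: PipelineConfig,
                             scheme: Optional[simsearch.ScoringScheme] = None,
                             ) -> tuple[list[Transcript], list[Transcript],
                                        dict[str, str]]:
    """Remove telson transcripts with a qualifying chela orthologue.

    A transcript is removed iff its best chela hit passes all three
    thresholds (E-value, identity, query coverage).  Returns
    (kept, removed, orthologue_map); map contents depend on
    ``cfg.strict_orthologue_relabel`` (see PipelineConfig).
    """
    scheme = scheme or simsearch.ScoringScheme.nucleotide()
    if not chela:
        return list(telson), [], {}
    db = [(t.id, t.seq) for t in chela]
    kept, removed = [], []
    orthologue_map: dict[str, str] = {}
    for t in telson:
        hits = simsearch.search((t.id, t.seq), db, scheme,
                                max_evalue=cfg.orthologue_max_evalue,
                                max_hits=1)
        best = hits[0] if hits else None
        qualifies = (
            best is not None
            and best.identity_pct >= cfg.orthologue_min_identity_pct
            and best.query_cov_pct >= cfg.orthologue_min_query_cov_pct)
        if qualifies:
            removed.append(t)
            orthologue_map[t.id] = best.subject_id
        else:
            kept.append(t)
            if best is not None and not cfg.strict_orthologue_relabel:
                orthologue_map[t.id] = best.subject_id
    return kept, removed, orthologue_map


def predict_orfs(transcripts: list[Transcript], cfg: PipelineConfig
                 ) -> tuple[list[Transcript], list[Transcript],
                            dict[str, Orf]]:
    """Step (iii): keep transcripts with an ORF >= orf_min_nt; attach the
    longest ORF of each."""
    kept, dropped = [], []
    orfs: dict[str, Orf] = {}
    for t in transcripts:
        orf = seqcore.longest_orf(seqcore.find_orfs(t, min_nt=cfg.orf_min_nt))
        if orf is None:
            dropped.append(t)
        else:
            orfs[t.id] = orf
            kept.append(t)
    return kept, dropped, orfs


def annotate_against_db(orf_peptides: dict[str, str], db: ReferenceDB,
                        cfg: PipelineConfig,
                        scheme: Optional[simsearch.ScoringScheme] = None,
                        ) -> tuple[dict[str, str],
                                   dict[str, simsearch.AlignmentHit]]:
    """Step (iv): label each peptide by its best reference hit.

    Returns (label per transcript id, best hit per transcript id); ids with
    no qualifying hit map to ``unidentified`` and have no hit entry.
    """
    if not db.records:
        raise ValueError("reference database is empty")
    scheme = scheme or simsearch.ScoringScheme.protein()
    record_db = [(r.id, r.seq) for r in db.records]
    label_of = {r.id: r.label for r in db.records}
    labels: dict[str, str] = {}
    best_hits: dict[str, simsearch.AlignmentHit] = {}
    for tid, peptide in orf_peptides.items():
        hits = simsearch.search((tid, peptide), record_db, scheme,
                                max_evalue=cfg.annotation_max_evalue,
                                max_hits=1)
        if hits:
            labels[tid] = label_of[hits[0].subject_id]
            best_hits[tid] = hits[0]
        else:
            labels[tid] = LABEL_UNIDENTIFIED
    return labels, best_hits


def apply_coverage_cutoff(transcripts: list[Transcript],
                          cutoff: float = 5.0
                          ) -> tuple[list[Transcript], list[Transcript]]:
    """Step (v): remove transcripts with coverage strictly below ``cutoff``."""
    kept = [t for t in transcripts if t.coverage >= cutoff]
    dropped = [t for t in transcripts if t.coverage < cutoff]
    return kept, dropped


def finalize_labels(transcripts: list[Transcript],
                    orthologue_map: dict[str, str]) -> list[Transcript]:
    """Step (vi): chela orthology overrides any similarity label."""
    for t in transcripts:
        if t.id in orthologue_map:
            t.label = LABEL_PHYSIOLOGICAL
    return transcripts


def venom_set(transcripts: list[Transcript]) -> list[Transcript]:
    return [t for t in transcripts if is_venom_label(t.label)]


def validate_toxin_signals(transcripts: list[Transcript],
                           orf_peptides: dict[str, str],
                           predictor: sigpep.Predictor = sigpep.predict_signal,
                           high_expression_fraction: float = 0.005
                           ) -> list[dict]:
    """Step (vii): advisory signal-peptide validation of highly expressed
    toxins; labels are never changed here."""
    total = sum(t.coverage for t in transcripts)
    rows = []
    for t in transcripts:
        if not is_venom_label(t.label):
            continue
        if total <= 0 or t.coverage / total < high_expression_fraction:
            continue
        pred = predictor(orf_peptides[t.id])
        rows.append({
            "id": t.id, "label": t.label, "coverage": t.coverage,
            "coverage_fraction": t.coverage / total,
            "signal_score": pred.score, "signal_band": pred.band,
            "validated": pred.present,
        })
    return rows


def composition_report(transcripts: list[Transcript],
                       attrition: list[dict]) -> CompositionReport:
    """Per-label counts and coverage fractions over the surviving set."""
    label_counts: dict[str, int] = {}
    family_counts: dict[str, int] = {}
    label_cov: dict[str, float] = {}
    for t in transcripts:
        label_counts[t.label] = label_counts.get(t.label, 0) + 1
        label_cov[t.label] = label_cov.get(t.label, 0.0) + t.coverage
        fam = toxin_family_of(t.label)
        if fam is not None:
            family_counts[fam] = family_counts.get(fam, 0) + 1
    total = sum(label_cov.values())
    label_frac = {k: (v / total if total else 0.0)
                  for k, v in label_cov.items()}
    fam_cov: dict[str, float] = {}
    for t in transcripts:
        fam = toxin_family_of(t.label)
        if fam is not None:
            fam_cov[fam] = fam_cov.get(fam, 0.0) + t.coverage
    fam_frac = {k: (v / total if total else 0.0) for k, v in fam_cov.items()}
    return CompositionReport(
        label_counts=label_counts, family_counts=family_counts,
        label_coverage=label_cov, label_coverage_frac=label_frac,
        family_coverage_frac=fam_frac, total_coverage=total,
        attrition=attrition)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(telson: list[Transcript], chela: list[Transcript],
                 db: ReferenceDB, cfg: Optional[PipelineConfig] = None,
                 predictor: sigpep.Predictor = sigpep.predict_signal
                 ) -> PipelineResult:
    """Execute steps (i)-(vii) in order and assemble the report."""
    cfg = cfg or PipelineConfig()
    attrition: list[dict] = []

    def log(step: str, n_in: int, n_out: int) -> None:
        attrition.append({"step": step, "in": n_in, "out": n_out,
                          "removed": n_in - n_out})

    # (i) coverage
    compute_all_coverage(telson, cfg.avg_read_len)
    compute_all_coverage(chela, cfg.avg_read_len)
    log("coverage", len(telson), len(telson))

    # (ii) chela orthologue subtraction
    kept, removed, ortho_map = remove_chela_orthologues(telson, chela, cfg)
    log("chela_orthologue_subtraction", len(telson), len(kept))

    # (iii) ORF prediction
    with_orf, no_orf, orfs = predict_orfs(kept, cfg)
    log("orf_prediction", len(kept), len(with_orf))
    peptides = {tid: orf.peptide for tid, orf in orfs.items()}

    # (iv) annotation against the reference database
    labels, best_hits = annotate_against_db(peptides, db, cfg)
    for t in with_orf:
        t.label = labels[t.id]
    log("annotation", len(with_orf), len(with_orf))

    # (v) coverage cutoff
    surviving, low_cov = apply_coverage_cutoff(with_orf, cfg.coverage_cutoff)
    log("coverage_cutoff", len(with_orf), len(surviving))

    # (vi) orthology reconciliation
    finalize_labels(surviving, ortho_map)
    log("finalize_labels", len(surviving), len(surviving))

    # (vii) signal validation of highly expressed toxins
    validation = validate_toxin_signals(
        surviving, peptides, predictor, cfg.high_expression_fraction)
    log("signal_validation", len(surviving), len(surviving))

    report = composition_report(surviving, attrition)
    return PipelineResult(
        transcripts=surviving, report=report, orthologue_map=ortho_map,
        orfs={t.id: orfs[t.id] for t in surviving},
        best_hits={t.id: best_hits[t.id] for t in surviving
                   if t.id in best_hits},
        signal_validation=validation,
        removed_orthologues=removed, dropped_no_orf=no_orf,
        dropped_low_coverage=low_cov)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the labeled transcript table, composition report and attrition
    log of a pipeline run."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "transcripts.tsv", "w") as fh:
        fh.write("id\tlength\tread_count\tcoverage\tlabel\tbest_hit\tevalue\n")
        for t in result.transcripts:
            hit = result.best_hits.get(t.id)
            fh.write("\t".join([
                t.id, str(len(t.seq)), str(t.read_count),
                f"{t.coverage:.4f}", t.label,
                hit.subject_id if hit else "-",
                f"{hit.evalue:.3e}" if hit else "-",
            ]) + "\n")
    rep = result.report
    with open(out / "composition.tsv", "w") as fh:
        fh.write("label\tcount\tcoverage\tcoverage_fraction\n")
        for label in sorted(rep.label_counts):
            fh.write("\t".join([
                label, str(rep.label_counts[label]),
                f"{rep.label_coverage[label]:.4f}",
                f"{rep.label_coverage_frac[label]:.6f}",
            ]) + "\n")
    with open(out / "attrition.json", "w") as fh:
        json.dump(rep.attrition, fh, indent=2)
        fh.write("\n")
    with open(out / "signal_validation.tsv", "w") as fh:
        fh.write("id\tlabel\tcoverage\tcoverage_fraction\tsignal_score"
                 "\tsignal_band\tvalidated\n")
        for row in result.signal_validation:
            fh.write("\t".join([
                row["id"], row["label"], f"{row['coverage']:.4f}",
                f"{row['coverage_fraction']:.6f}",
                f"{row['signal_score']:.3f}", row["signal_band"],
                str(row["validated"]),
            ]) + "\n")


def plot_composition(report: CompositionReport, path) -> None:
    """Optional bar chart of coverage fractions per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(report.label_coverage_frac)
    fracs = [100 * report.label_coverage_frac[k] for k in labels]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, fracs)
    ax.set_ylabel("% of total coverage")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
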