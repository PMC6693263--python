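"""Novel-toxin discovery over unidentified transcripts.

Highly expressed unidentified transcripts (>= 0.5% of total surviving
coverage) are the candidate pool.  Each candidate contributes the ORF whose
peptide has the best signal-peptide score (span, then canonical ORF order,
break ties).  Candidates are grouped by single linkage: two candidates link
when their cysteine scaffolds are compatible (same cysteine count, every
inter-cysteine gap differing by at most 2 residues) AND their
signal-peptide regions are at least 60% identical under global alignment.
Clusters are then expanded against the pooled telson transcriptomes
(E <= 1; recruits need a present signal peptide and coverage above 5),
aligned with a center-star MSA, searched against a known-protein set, and
classified with the rule-based novelty classifier.

Classification rules, applied in order:

1. best hit matches a configured toxin-family synonym -> new toxins in an
   existing family;
2. best hit description contains "antimicrobial" -> novel putative AMP;
3. conserved cysteine pattern across all members -> novel putative
   toxin family (novel putative toxin for singlets);
4. otherwise -> novel putative secreted protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import SeqIO

from . import seqcore, sigpep, simsearch
from .annotate import PipelineConfig, PipelineResult
from .seqcore import (LABEL_UNIDENTIFIED, Orf, Transcript, cysteine_pattern,
                      spacing_gaps)
from .sigpep import SignalPrediction

CAT_EXISTING_FAMILY = "new_toxins_in_existing_family"
CAT_NOVEL_FAMILY = "novel_putative_toxin_family"
CAT_NOVEL_TOXIN = "novel_putative_toxin"
CAT_SECRETED = "novel_putative_secreted_protein"
CAT_AMP = "novel_putative_amp"

HIT_FAMILY_MEMBER = "named_toxin_family_member"
HIT_TOXIN_OR_VENOM = "named_toxin_or_venom_peptide"
HIT_HYPOTHETICAL = "hypothetical_or_uncharacterized"
HIT_NONE = "no_hit"

#: substrings (case-insensitive) that mark a best hit as a member of a named
#: toxin family; editable to match the reference nomenclature in use
DEFAULT_FAMILY_SYNONYMS = (
    "natx", "ktx", "potassium channel toxin", "sodium channel toxin",
    "chlorotoxin", "calcium channel toxin", "catx", "kunitz",
    "theraphotoxin", "bradykinin", "bmka", "phospholipase", "buthitoxin",
    "meutx", "scorpine", "neurotoxin",
)

TOXIN_KEYWORDS = ("toxin", "venom peptide")
HYPOTHETICAL_KEYWORDS = ("hypothetical", "uncharacterized", "orphan",
                         "putative")


@dataclass
class DiscoverConfig:
    """Thresholds of the discovery stage."""

    high_expression_fraction: float = 0.005
    leader_min_identity_pct: float = 60.0
    scaffold_gap_tolerance: int = 2
    expansion_max_evalue: float = 1.0
    expansion_min_coverage: float = 5.0   # recruits need coverage ABOVE this
    expansion_max_hits: int = 50
    identify_max_evalue: float = 1e-5
    msa_gap_open: int = 10
    msa_gap_extend: int = 1
    conserved_col_identity: float = 0.8
    conserved_high: float = 0.5
    conserved_some: float = 0.25
    family_synonyms: tuple[str, ...] = DEFAULT_FAMILY_SYNONYMS


@dataclass
class Candidate:
    """One high-expressed unidentified transcript with its chosen ORF."""

    transcript: Transcript
    orf: Orf
    signal: SignalPrediction

    @property
    def id(self) -> str:
        return self.transcript.id

    @property
    def peptide(self) -> str:
        return self.orf.peptide


@dataclass
class CandidateFeatures:
    signal_band: Optional[str] = None
    has_conserved_c_pattern: Optional[bool] = None
    conserved_residue_band: Optional[str] = None
    best_hit_category: Optional[str] = None
    best_hit_description: str = ""

    def complete(self) -> bool:
        return None not in (self.signal_band, self.has_conserved_c_pattern,
                            self.conserved_residue_band,
                            self.best_hit_category)


@dataclass
class NoveltyCluster:
    id: str
    members: list[Candidate]
    seed_member: Candidate
    features: CandidateFeatures = field(default_factory=CandidateFeatures)
    msa: list[str] = field(default_factory=list)
    category: Optional[str] = None

    @property
    def is_singlet(self) -> bool:
        return len(self.members) == 1

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


@dataclass(frozen=True)
class KnownProtein:
    id: str
    seq: str
    description: str


def read_known_proteins(path) -> list[KnownProtein]:
    """Known-protein FASTA (a stand-in for NCBI nr); the description line
    after the id is the record's annotation text."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(KnownProtein(rec.id, str(rec.seq).upper(), desc))
    return records


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def select_high_expressed_unidentified(transcripts: list[Transcript],
                                       fraction: float = 0.005
                                       ) -> list[Transcript]:
    """Unidentified transcripts at >= ``fraction`` of total coverage."""
    total = sum(t.coverage for t in transcripts)
    if total <= 0:
        raise ValueError("total coverage is zero")
    return [t for t in transcripts
            if t.label == LABEL_UNIDENTIFIED
            and t.coverage / total >= fraction]


def pick_orf_with_best_signal(t: Transcript,
                              predictor: sigpep.Predictor =
                              sigpep.predict_signal,
                              min_nt: int = 75
                              ) -> Optional[tuple[Orf, SignalPrediction]]:
    """The ORF with the highest signal score; span then canonical ORF order
    break ties.  None when the transcript has no ORF."""
    orfs = seqcore.find_orfs(t, min_nt=min_nt)
    if not orfs:
        return None
    best, best_pred, best_key = None, None, None
    for rank, orf in enumerate(orfs):  # orfs already in canonical order
        pred = predictor(orf.peptide)
        key = (-pred.score, -orf.nt_span, rank)
        if best_key is None or key < best_key:
            best, best_pred, best_key = orf, pred, key
    return best, best_pred


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def scaffolds_compatible(pep_a: str, pep_b: str, gap_tolerance: int = 2
                         ) -> bool:
    """Same cysteine count and every inter-cysteine gap within tolerance."""
    pa, pb = cysteine_pattern(pep_a), cysteine_pattern(pep_b)
    if pa.count != pb.count:
        return False
    return all(abs(ga - gb) <= gap_tolerance
               for ga, gb in zip(spacing_gaps(pa), spacing_gaps(pb)))


def leader_identity_pct(a: Candidate, b: Candidate,
                        scheme: Optional[simsearch.ScoringScheme] = None
                        ) -> float:
    scheme = scheme or simsearch.ScoringScheme.protein()
    la = sigpep.leader_region(a.peptide, a.signal)
    lb = sigpep.leader_region(b.peptide, b.signal)
    return simsearch.global_align(la, lb, scheme).identity_pct


def cluster_candidates(candidates: Sequence[Candidate],
                       cfg: Optional[DiscoverConfig] = None
                       ) -> list[NoveltyCluster]:
    """Single-linkage grouping on scaffold compatibility plus leader
    identity; ungrouped candidates become singlets.

    Clusters are ordered by descending seed coverage (seed = the
    highest-coverage member), ties by id, and named cluster-1, cluster-2...
    with singlets named singlet-1, singlet-2...
    """
    cfg = cfg or DiscoverConfig()
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if not scaffolds_compatible(candidates[i].peptide,
                                        candidates[j].peptide,
                                        cfg.scaffold_gap_tolerance):
                continue
            if leader_identity_pct(candidates[i], candidates[j]) \
                    < cfg.leader_min_identity_pct:
                continue
            parent[find(i)] = find(j)

    groups: dict[int, list[Candidate]] = {}
    for i, cand in enumerate(candidates):
        groups.setdefault(find(i), []).append(cand)

    clusters = []
    for members in groups.values():
        members = sorted(members, key=lambda c: (-c.transcript.coverage,
                                                 c.id))
        clusters.append((members[0], members))
    clusters.sort(key=lambda sm: (-sm[0].transcript.coverage, sm[0].id))
    out: list[NoveltyCluster] = []
    n_cluster = n_singlet = 0
    for seed, members in clusters:
        if len(members) > 1:
            n_cluster += 1
            cid = f"cluster-{n_cluster}"
        else:
            n_singlet += 1
            cid = f"singlet-{n_singlet}"
        out.append(NoveltyCluster(id=cid, members=members, seed_member=seed))
    return out


# ---------------------------------------------------------------------------
# expansion against the pooled telson transcriptomes
# ---------------------------------------------------------------------------

def expand_clusters(clusters: list[NoveltyCluster],
                    pooled_telson: list[Transcript],
                    cfg: Optional[DiscoverConfig] = None,
                    predictor: sigpep.Predictor = sigpep.predict_signal,
                    orf_min_nt: int = 75) -> list[NoveltyCluster]:
    """Recruit lower-expressed homologues from the pooled telson sets.

    Each seed transcript is searched against the pool at E <= 1; a hit is
    recruited when its best-signal ORF has a present signal peptide and its
    coverage is above 5.  A hit qualifying for several clusters joins the
    one where its E-value is best.  Seeds and existing members are never
    removed.
    """
    cfg = cfg or DiscoverConfig()
    if not pooled_telson:
        return clusters
    scheme = simsearch.ScoringScheme.nucleotide()
    already = {m.id for cl in clusters for m in cl.members}
    pool = [(t.id, t.seq) for t in pooled_telson]
    by_id = {t.id: t for t in pooled_telson}
    # best (evalue, cluster order) per recruitable subject
    assignment: dict[str, tuple[float, int]] = {}
    for ci, cl in enumerate(clusters):
        seed = cl.seed_member.transcript
        hits = simsearch.search((seed.id, seed.seq), pool, scheme,
                                max_evalue=cfg.expansion_max_evalue,
                                max_hits=cfg.expansion_max_hits)
        for h in hits:
            if h.subject_id in already:
                continue
            key = (h.evalue, ci)
            if h.subject_id not in assignment or key < assignment[h.subject_id]:
                assignment[h.subject_id] = key
    for sid in sorted(assignment):
        _, ci = assignment[sid]
        t = by_id[sid]
        if t.coverage is None or t.coverage <= cfg.expansion_min_coverage:
            continue
        picked = pick_orf_with_best_signal(t, predictor, min_nt=orf_min_nt)
        if picked is None:
            continue
        orf, pred = picked
        if not pred.present:
            continue
        clusters[ci].members.append(Candidate(t, orf, pred))
    return clusters


# ---------------------------------------------------------------------------
# center-star MSA and conservation
# ---------------------------------------------------------------------------

def center_star_msa(peptides: Sequence[str], gap_open: int = 10,
                    gap_extend: int = 1) -> list[str]:
    """Center-star multiple alignment.

    The center is the peptide maximizing its summed pairwise global scores;
    every other peptide is aligned to the center and gaps are merged with
    the once-a-gap-always-a-gap rule.  Removing gap characters from any row
    reproduces its input.
    """
    if len(peptides) < 2:
        raise ValueError("center-star MSA needs at least 2 peptides")
    scheme = simsearch.ScoringScheme.protein(gap_open=gap_open,
                                             gap_extend=gap_extend)
    n = len(peptides)
    pair_scores = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            sc = simsearch.global_align(peptides[i], peptides[j], scheme).score
            pair_scores[i][j] = pair_scores[j][i] = sc
    sums = [sum(row) for row in pair_scores]
    center = max(range(n), key=lambda i: (sums[i], -i))

    master = peptides[center]        # center row with accumulated gaps
    rows: list[tuple[int, str]] = []  # (original index, aligned row)
    for i in range(n):
        if i == center:
            continue
        aln = simsearch.global_align(master.replace("-", ""), peptides[i],
                                     scheme)
        # re-insert master's accumulated gaps into the fresh pairwise rows;
        # col_map[j] = column of the previous master, or None for a new gap
        merged_center, merged_other, col_map = _merge_into_master(
            master, aln.aligned_a, aln.aligned_b)
        if len(merged_center) > len(master):
            rows = [(k, "".join(row[c] if c is not None else "-"
                                for c in col_map))
                    for k, row in rows]
        master = merged_center
        rows.append((i, merged_other))
    aligned = [""] * n
    aligned[center] = master
    for k, row in rows:
        aligned[k] = row
    return aligned


def _merge_into_master(master: str, aligned_center: str, aligned_other: str
                       ) -> tuple[str, str, list]:
    """Merge a pairwise alignment of the degapped center into the gapped
    master row (once a gap, always a gap).

    Returns the new master row, the other sequence's row, and a map from
    new columns to previous-master columns (None where a new gap column
    was inserted).
    """
    out_c: list[str] = []
    out_o: list[str] = []
    col_map: list = []
    mi = ai = 0
    while mi < len(master) or ai < len(aligned_center):
        m_char = master[mi] if mi < len(master) else None
        a_char = aligned_center[ai] if ai < len(aligned_center) else None
        if m_char == "-":
            out_c.append("-")       # pre-existing gap column of the master
            out_o.append("-")
            col_map.append(mi)
            mi += 1
        elif a_char == "-":
            out_c.append("-")       # gap newly introduced by this pairing
            out_o.append(aligned_other[ai])
            col_map.append(None)
            ai += 1
        else:
            out_c.append(m_char)
            out_o.append(aligned_other[ai])
            col_map.append(mi)
            mi += 1
            ai += 1
    return "".join(out_c), "".join(out_o), col_map


def conserved_residue_band(msa: Sequence[str],
                           cfg: Optional[DiscoverConfig] = None) -> str:
    """Band from the fraction of fully ungapped columns where >= 80% of
    rows carry the same residue.  Singlets band high by convention (a
    sequence is perfectly conserved against itself)."""
    cfg = cfg or DiscoverConfig()
    if not msa:
        raise ValueError("empty MSA")
    if len(msa) == 1:
        return sigpep.BAND_HIGH
    ncols = len(msa[0])
    full_cols = conserved = 0
    for j in range(ncols):
        column = [row[j] for row in msa]
        if "-" in column:
            continue
        full_cols += 1
        counts: dict[str, int] = {}
        for c in column:
            counts[c] = counts.get(c, 0) + 1
        if max(counts.values()) / len(column) >= cfg.conserved_col_identity:
            conserved += 1
    f = conserved / full_cols if full_cols else 0.0
    if f >= cfg.conserved_high:
        return sigpep.BAND_HIGH
    if f >= cfg.conserved_some:
        return sigpep.BAND_SOME
    return sigpep.BAND_LOW


def cluster_has_conserved_c_pattern(cluster: NoveltyCluster,
                                    gap_tolerance: int = 2) -> bool:
    """All members bridged and scaffold-compatible with the seed; singlets
    inherit their own bridged flag."""
    seed_pep = cluster.seed_member.peptide
    if not cysteine_pattern(seed_pep).bridged:
        return False
    return all(scaffolds_compatible(seed_pep, m.peptide, gap_tolerance)
               for m in cluster.members)


# ---------------------------------------------------------------------------
# identification against known proteins and classification
# ---------------------------------------------------------------------------

def categorize_description(description: str,
                           family_synonyms: Sequence[str] =
                           DEFAULT_FAMILY_SYNONYMS) -> str:
    """Map a best-hit description onto the best-hit category enum."""
    low = description.lower()
    if any(s in low for s in family_synonyms):
        return HIT_FAMILY_MEMBER
    if any(s in low for s in TOXIN_KEYWORDS):
        return HIT_TOXIN_OR_VENOM
    if any(s in low for s in HYPOTHETICAL_KEYWORDS):
        return HIT_HYPOTHETICAL
    return HIT_NONE


def identify_cluster(cluster: NoveltyCluster,
                     known_proteins: Sequence[KnownProtein],
                     cfg: Optional[DiscoverConfig] = None
                     ) -> tuple[str, str]:
    """Best-hit category for a cluster: the best hit over all member
    peptides against the known-protein set.  Empty set -> no hit."""
    cfg = cfg or DiscoverConfig()
    if not known_proteins:
        return HIT_NONE, ""
    db = [(k.id, k.seq) for k in known_proteins]
    desc_of = {k.id: k.description for k in known_proteins}
    scheme = simsearch.ScoringScheme.protein()
    best: Optional[simsearch.AlignmentHit] = None
    for m in cluster.members:
        hits = simsearch.search((m.id, m.peptide), db, scheme,
                                max_evalue=cfg.identify_max_evalue,
                                max_hits=1)
        if hits and (best is None or (hits[0].evalue, -hits[0].bit_score)
                     < (best.evalue, -best.bit_score)):
            best = hits[0]
    if best is None:
        return HIT_NONE, ""
    desc = desc_of[best.subject_id]
    return categorize_description(desc, cfg.family_synonyms), desc


def classify_cluster(features: CandidateFeatures, is_singlet: bool = False
                     ) -> str:
    """Apply the novelty rules (module docstring) to a feature set."""
    if not features.complete():
        raise ValueError("incomplete candidate features")
    if features.best_hit_category == HIT_FAMILY_MEMBER:
        return CAT_EXISTING_FAMILY
    if "antimicrobial" in features.best_hit_description.lower():
        return CAT_AMP
    if features.has_conserved_c_pattern:
        return CAT_NOVEL_TOXIN if is_singlet else CAT_NOVEL_FAMILY
    return CAT_SECRETED


# ---------------------------------------------------------------------------
# worked example: published cluster feature rows
# ---------------------------------------------------------------------------

#: Feature rows (best-hit description, signal band, conserved-C flag,
#: conserved-residue band, singlet?) transcribed from the novelty report of
#: a published six-species scorpion venom-gland study, with the category
#: its authors assigned.  Two rows print "No" / "N.A." in the C-pattern
#: cell yet carry the report's conserved-C-pattern footnote marker; the
#: footnote is followed here.  Used as a validation set for
#: :func:`classify_cluster`.
WORKED_EXAMPLE_ROWS = (
    # (name, best-hit description, signal, c_pattern, conserved, singlet,
    #  reported category)
    ("cluster-1", "Lamda-potassium channel toxin (ADT64271.1)", "some",
     True, "high", False, CAT_EXISTING_FAMILY),
    ("cluster-2", "Hypothetical secreted protein (ADY39531.1)", "high",
     True, "high", False, CAT_NOVEL_FAMILY),
    ("cluster-3", "U6-buthitoxin-Hj1a (ADY39519.1)", "high",
     True, "high", False, CAT_EXISTING_FAMILY),
    ("cluster-4", "Orphan peptide AbOp-11 (AIX87714.1)", "high",
     False, "high", False, CAT_SECRETED),
    ("cluster-5", "Hypothetical secreted protein (ADY39514.1)", "high",
     True, "high", False, CAT_NOVEL_FAMILY),
    ("cluster-6", "venom peptide HtC4Tx1 (AOF40173.1)", "low",
     True, "low", False, CAT_NOVEL_FAMILY),
    ("cluster-7", "hypothetical protein (WP_063562212.1)", "low",
     True, "low", False, CAT_NOVEL_FAMILY),   # footnoted C pattern
    ("cluster-8", "Orphan peptide AbOp-18 (AIX87708.1)", "high",
     False, "high", False, CAT_EXISTING_FAMILY),
    ("cluster-9", "Venom toxin meuTx23 (AMX81480.1)", "low",
     False, "high", False, CAT_EXISTING_FAMILY),
    ("cluster-10", "Hypothetical secreted protein (ADY39511.1)", "high",
     False, "low", False, CAT_SECRETED),
    ("cluster-11", "RNA-binding protein, putative (SCO66159.1)", "low",
     False, "some", False, CAT_SECRETED),
    ("cluster-12", "Uncharacterized protein (XP_023221782.1)", "high",
     True, "high", False, CAT_NOVEL_FAMILY),
    ("cluster-13", "Potassium channel toxin alpha-KTx 4.5 (Q5G8B6.1)",
     "low", True, "high", False, CAT_EXISTING_FAMILY),
    ("cluster-14", "Hypothetical protein (AEX09189.1)", "high",
     False, "some", False, CAT_SECRETED),
    ("cluster-15", "Hypothetical protein (GAU10035.1)", "low",
     True, "some", False, CAT_NOVEL_FAMILY),
    ("singlet-1", "", "low", False, "low", True, CAT_SECRETED),
    ("singlet-2", "", "low", False, "low", True, CAT_SECRETED),
    ("singlet-3", "Hypothetical protein (AEX09189.1)", "high",
     False, "some", True, CAT_SECRETED),
    ("singlet-4", "Orphan peptide AbOp-11 (AIX87714.1)", "high",
     False, "low", True, CAT_SECRETED),
    ("singlet-5", "Potassium channel toxin kappa-KTx (P0DJ41.1)", "some",
     True, "low", True, CAT_EXISTING_FAMILY),
    ("singlet-6", "Venom peptide Htgkr2 (AOF40260.1)", "some",
     False, "low", True, CAT_SECRETED),
    ("singlet-7", "", "low", True, "low", True, CAT_NOVEL_TOXIN),
    ("singlet-8", "SH3 domain and tetratricopeptide repeat-containing "
     "protein (XP_004574858.2)", "low", False, "low", True, CAT_SECRETED),
    ("singlet-9", "Putative antimicrobial peptide (AEX09192.1)", "high",
     False, "high", True, CAT_AMP),
)


def classify_worked_example(cfg: Optional[DiscoverConfig] = None
                            ) -> list[tuple[str, str, str]]:
    """Run the classifier over :data:`WORKED_EXAMPLE_ROWS`.

    Returns ``(name, predicted category, reported category)`` per row;
    the best-hit category of each row is derived from its description at
    run time so the full keyword path is exercised.
    """
    cfg = cfg or DiscoverConfig()
    out = []
    for name, desc, band, c_pat, cons, singlet, reported in \
            WORKED_EXAMPLE_ROWS:
        category = (HIT_NONE if not desc
                    else categorize_description(desc, cfg.family_synonyms))
        features = CandidateFeatures(
            signal_band=band, has_conserved_c_pattern=c_pat,
            conserved_residue_band=cons, best_hit_category=category,
            best_hit_description=desc)
        out.append((name, classify_cluster(features, singlet), reported))
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def discover_novel_toxins(result: PipelineResult,
                          pooled_telson: list[Transcript],
                          known_proteins: Sequence[KnownProtein] = (),
                          cfg: Optional[DiscoverConfig] = None,
                          predictor: sigpep.Predictor = sigpep.predict_signal,
                          orf_min_nt: int = 75) -> list[NoveltyCluster]:
    """Full discovery pass over an annotated pipeline result."""
    cfg = cfg or DiscoverConfig()
    selected = select_high_expressed_unidentified(
        result.transcripts, cfg.high_expression_fraction)
    candidates: list[Candidate] = []
    for t in selected:
        picked = pick_orf_with_best_signal(t, predictor, min_nt=orf_min_nt)
        if picked is None:
            continue
        orf, pred = picked
        if not pred.present:   # toxins are secreted; leaderless ORFs drop out
            continue
        candidates.append(Candidate(t, orf, pred))
    clusters = cluster_candidates(candidates, cfg)
    clusters = expand_clusters(clusters, pooled_telson, cfg, predictor,
                               orf_min_nt)
    for cl in clusters:
        if len(cl.members) >= 2:
            cl.msa = center_star_msa([m.peptide for m in cl.members],
                                     cfg.msa_gap_open, cfg.msa_gap_extend)
        else:
            cl.msa = [cl.seed_member.peptide]
        category, desc = identify_cluster(cl, known_proteins, cfg)
        cl.features = CandidateFeatures(
            signal_band=cl.seed_member.signal.band,
            has_conserved_c_pattern=cluster_has_conserved_c_pattern(
                cl, cfg.scaffold_gap_tolerance),
            conserved_residue_band=conserved_residue_band(cl.msa, cfg),
            best_hit_category=category,
            best_hit_description=desc)
        cl.category = classify_cluster(cl.features, cl.is_singlet)
    return clusters


def write_cluster_table(clusters: Sequence[NoveltyCluster], path) -> None:
    """Cluster summary table in the shape of the novelty report."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tn_members\tmembers\tsignal_band\tc_pattern"
                 "\tconserved_residues\tbest_hit_category"
                 "\tbest_hit_description\tcategory\n")
        for cl in clusters:
            f = cl.features
            fh.write("\t".join([
                cl.id, str(len(cl.members)), ",".join(cl.member_ids),
                f.signal_band or "-",
                "yes" if f.has_conserved_c_pattern else "no",
                f.conserved_residue_band or "-",
                f.best_hit_category or "-",
                f.best_hit_description or "-",
                cl.category or "-",
            ]) + "\n")


def write_cluster_msas(clusters: Sequence[NoveltyCluster], out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cl in clusters:
        with open(out / f"{cl.id}.aln.fasta", "w") as fh:
            for member, row in zip(cl.members, cl.msa):
                fh.write(f">{member.id}\n{row}\n")
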