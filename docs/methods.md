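# Methods

## Scope and model

`venomscan` operates downstream of assembly: its inputs are assembled
transcriptomes (FASTA) with per-transcript read counts, not reads.  The
underlying model of a venom-gland transcriptome is a mixture of

* housekeeping/physiological transcripts, shared with a venom-free
  control tissue (the chela) at near-identity;
* secreted toxin transcripts: an N-terminal signal peptide followed by a
  mature peptide whose cysteine scaffold is characteristic of its family
  (disulfide-bridged peptides, DBPs, have ≥ 2 cysteines; non-bridged
  NDBPs have fewer);
* transcripts with no reference counterpart, among which novel toxin
  families hide;
* assembly noise.

Expression is proxied by coverage `c = L̄·n/ℓ` (average read length ×
read count / transcript length).  `L̄` defaults to 150 and is
configurable; a sequencing design of 2 × 125 bp paired reads would
justify 125, and the constant deliberately stays a parameter rather than
being inferred from data.

## Similarity search

All similarity questions go through one engine: optimal Smith–Waterman
local alignment under affine gaps (a gap of length L costs
`gap_open + (L−1)·gap_extend`), with Karlin–Altschul statistics
`bit = (λS − ln K)/ln 2`, `E = m·n·2^(−bit)` where `m` is the query
length and `n` the total database residues.  Default schemes: BLOSUM62
with gaps 11/1 and published gapped constants λ = 0.267, K = 0.041
(protein); +2/−3 with gaps 5/2 and λ = 0.625, K = 0.41 (nucleotide).
Exact parity with BLAST statistics (edge-effect and composition
corrections, HSP tiling, translated search) is a non-goal; every
threshold in the toolkit is calibrated on these E-values.

Numerical/determinism choices:

* traceback ties prefer diagonal, then vertical (gap in subject), then
  horizontal; gap closure is preferred over extension on ties; the start
  cell is the first row-major maximum.  Reported alignments are
  therefore unique.
* search ranking: ascending E-value, then descending bit score, then
  ascending subject id.
* an exact k-mer prefilter (k = 11 nucleotide, k = 4 protein) skips
  subjects sharing no word with the query; `prefilter=False` forces
  exhaustive mode (used by the oracle tests).  At the thresholds the
  pipeline uses, any subject without a shared word would fail the
  E-value cut on the data scales involved.
* ambiguity symbols never score: X–X and N–N are 0, X–other is −1,
  N–other is the mismatch score.  Codons containing N translate to X.
* "percentage coverage" in the orthologue filter is *query* coverage
  (the aligned fraction of the telson transcript); with near-identical
  full-length orthologues the choice of query vs subject is immaterial,
  and query coverage is the deterministic reading.

## Annotation pipeline

Steps and their boundary conventions:

* orthologue subtraction removes a telson transcript iff its best chela
  hit passes all of `E ≤ 10⁻⁵⁰`, identity ≥ 99%, query coverage ≥ 95%.
  A 98%-identity pair is kept; ≥ 99% is removed.
* ORF prediction is ATG-only over six frames with a 75 nt minimum (a
  common ORF-finder default; the method itself does not pin one).  Every
  ATG-to-stop stretch is reported, nested starts included; ORFs hitting
  the transcript end without a stop are kept and flagged open-ended,
  since assemblies truncate 3′ ends.  "Longest ORF" ties break by frame
  order +1,+2,+3,−1,−2,−3 then leftmost start.  Transcripts with no
  qualifying ORF are dropped as partial.
* coverage cutoff removes `c < 5` strictly; `c = 5` survives.
* the orthologue map drives the later relabeling step.  In the default
  *strict* mode the map holds only transcripts actually removed by the
  subtraction, making the relabeling a consistency re-assertion; a
  *loose* mode additionally records sub-threshold best chela hits
  (E-value pass only) and relabels those survivors `physiological`.
  The double handling of orthology (removal and relabeling) admits both
  readings; strict is the conservative default.
* signal validation of highly expressed toxins is advisory: it never
  changes labels.
* internal coordinates are 0-based half-open on the forward strand;
  tabular reports print 1-based inclusive (outfmt-6 convention).

## Signal peptides

The built-in predictor scores the classic tripartite leader architecture
explicitly, combining three components with weights 0.2/0.5/0.3:

* n-region: any K/R in residues 2–6 (binary);
* h-region: a hard gate — 1 iff some 8-residue window starting in
  residues 3–20 has mean Kyte–Doolittle ≥ 1.6.  The hydrophobic core is
  the defining feature of a leader, so a peptide failing this gate can
  reach at most 0.5 and random peptides rarely cross the presence
  cutoff;
* c-region: small residues {A,G,S,C,T,V} at −3 and −1 of the best
  candidate cleavage site after residues 15–35 (half credit each); the
  cleavage position is the best-scoring site, undefined when the h-gate
  fails.

Peptides shorter than 15 residues score 0.  Presence means score ≥ 0.45;
bands are high ≥ 0.75, some ≥ 0.45, low otherwise.  The cutoffs are this
package's own calibration of the qualitative high/some/low vocabulary —
external predictors publish scores, not bands.  An adapter imports
external predictions (`id<TAB>score<TAB>cleavage_pos`) into the same
type, so the pipeline is backend-independent; no neural-network
predictor is reimplemented here.

## Novelty discovery

* Candidates: unidentified survivors at ≥ 0.5% of total surviving
  coverage, each represented by the ORF with the highest signal score
  (span, then canonical ORF order, break ties); candidates without a
  present signal peptide are excluded — toxins are secreted.
* Clustering is single linkage with an explicit, configurable metric:
  two candidates link iff their cysteine scaffolds are compatible (equal
  C count, every inter-C gap within ±2 residues) and their
  signal-peptide regions are ≥ 60% identical under global alignment.
  The published procedure groups "on signal peptide, C bridges and
  conserved domains" without defining a metric; this rule is the
  package's stand-in and is deliberately transparent.
* Expansion searches each seed's nucleotide transcript against the
  pooled telson transcriptomes at E ≤ 1 and recruits hits with a present
  signal peptide and coverage strictly above 5.  (The pipeline's own
  cutoff keeps coverage = 5; the expansion filter discards it.  The
  source procedure states the two bounds differently and the difference
  is preserved.)  A hit qualifying for several clusters joins the one
  with the best E-value.  The original step is a peptide-vs-nucleotide
  search; translated search is out of scope here, so the nucleotide
  transcript stands in for the seed — equivalent on the synonymous-coding
  data the generator produces, weaker on deeply diverged homologues.
* The center-star MSA picks the sequence maximizing summed pairwise
  global scores (gap 10/1), aligns all others to it and merges gaps by
  once-a-gap-always-a-gap; degapping any row reproduces its input
  exactly.
* Conserved-residue band: fraction f of fully ungapped columns with
  ≥ 80% residue agreement; high f ≥ 0.5, some f ≥ 0.25, else low;
  singlets band high (self-comparison).
* Classification rules, in order: (1) best known-protein hit matches a
  configured family-synonym list → new toxins in an existing family;
  (2) hit description contains "antimicrobial" → novel putative AMP;
  (3) conserved C pattern across all members → novel putative toxin
  family (novel putative toxin for singlets); (4) otherwise → novel
  putative secreted protein.  On the bundled 24-row published worked
  example this order reproduces 23 of 24 assigned labels and exactly the
  6 novel-family rows; the one disagreement is a cluster whose
  orphan-peptide hit was manually promoted to an existing family by the
  original authors, which no description-driven rule can reproduce.
  Disagreements are reported, never forced.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
housekeeping transcripts copied into both tissues (optionally mutated at
a configurable rate to exercise the identity threshold), family toxins as
leader + mutated family template (≥ ~85% identity to same-family
reference records), novel families sharing a leader and scaffold but
absent from every database, and unstructured noise.  Back-translation
uses uniform synonymous codons (codon bias is irrelevant to these
tests); a draw whose transcript's longest ORF is not the planted one —
reverse reading frames of a random CDS often lack stops — is rejected
and redrawn deterministically.  Read counts are log-normal; novel-family
counts are forced to ≥ 0.8% of total telson coverage so the 0.5%
selection rule is tested non-vacuously (a flag disables this to test the
exclusion branch; that branch plants coverage ≈ 3, below the pipeline
cutoff).  Default sizes are 20 housekeeping, 5+5 toxins in two families,
2 novel families × 3 members and 10 noise transcripts — small enough
that the full study, pipeline and discovery run in seconds on one CPU
while every decision branch is populated.  Before returning, the
generator verifies its own plants with the toolkit's search engine and
signal predictor and refuses to emit a dataset that fails.

What the simulator does *not* model: sequencing error, isoforms,
chimeric assemblies, codon bias, realistic divergence between reference
databases and the study species, and homology between distinct families.
Passing the planted-truth tests therefore demonstrates the pipeline's
rules operate as specified, not that real-data recall matches.

## Known limitations

* Expansion at E ≤ 1 is deliberately permissive (as the procedure
  prescribes) and can recruit an unrelated transcript that passes the
  signal and coverage filters by chance; one such recruit breaks the
  cluster's conserved-C-pattern flag and demotes a genuine novel family
  to "secreted protein".  The cluster table records members and features
  so such cases are visible for manual review.
* The signal-peptide heuristic is transparent but crude; ~10–15% of
  random ORFs pass the presence cutoff, which mirrors the false-positive
  load any sensitive predictor has at this step, but absolute scores are
  not comparable with external tools.
* E-values are uncorrected Karlin–Altschul values; thresholds tuned for
  BLAST output transfer only approximately.
* Coverage-based expression is a rough proxy; no normalization against
  housekeeping genes or across replicates is attempted.
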