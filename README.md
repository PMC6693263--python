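# venomscan

Annotation of venom-gland transcriptomes and discovery of novel toxin
candidates, built for venomics of scorpions and similar arachnids.

Scorpion venom is a mixture of peptides dominated by two structural
classes: disulfide-bridged peptides (DBPs — ion-channel toxins such as
NaTx, KTx, ClTx and CaTx families, held together by at least two
cysteines forming a bridge) and non-disulfide-bridged peptides (NDBPs —
antimicrobial and bradykinin-potentiating peptides among others).  Venom
glands sit in the telson (stinger); the chela (pincer) serves as a
venom-free control tissue.  Given an assembled telson transcriptome with
per-transcript read counts, a chela transcriptome, and a labeled
reference protein set, `venomscan` labels every transcript as
`physiological`, `toxin:<family>`, `other_toxin` or `unidentified`, then
mines the highly expressed unidentified transcripts for novel toxin
families using signal-peptide and cysteine-scaffold structure.

Everything runs offline: similarity search is a built-in Smith–Waterman
engine with Karlin–Altschul statistics, ORF prediction and
signal-peptide scoring are built in, and a deterministic simulator
generates full paired studies with planted ground truth.

## Method

**Annotation pipeline** (telson vs chela), seven steps:

1. coverage `c = L̄ · n / ℓ` per transcript (average read length `L̄ = 150`,
   read count `n`, transcript length `ℓ`);
2. chela orthologue subtraction: remove telson transcripts whose best
   chela hit passes `E ≤ 10⁻⁵⁰`, identity ≥ 99% and query coverage ≥ 95%;
3. six-frame ATG-only ORF prediction (min 75 nt); transcripts without an
   ORF are dropped as partial assemblies;
4. annotation: each longest ORF is searched against the labeled
   reference database (`E ≤ 10⁻⁵`, best hit) and inherits its label;
5. coverage cutoff: transcripts with `c < 5` are removed (`c = 5`
   survives);
6. chela orthology overrides any label to `physiological`; the venom set
   is every `toxin:<family>` plus `other_toxin`;
7. highly expressed toxins (≥ 0.5% of surviving coverage) get an
   advisory signal-peptide validation.

**Novelty discovery**: unidentified transcripts at ≥ 0.5% of total
coverage contribute the ORF with the best signal-peptide score; candidates
group by single linkage when cysteine scaffolds are compatible (equal C
count, inter-C gaps within ±2) and signal-peptide regions are ≥ 60%
identical.  Clusters expand against the pooled telson transcriptomes
(`E ≤ 1`; recruits need a present signal peptide and coverage > 5), get a
center-star MSA, are searched against a known-protein set, and are
classified: family-synonym hit → new toxins in an existing family;
"antimicrobial" hit → novel putative AMP; conserved C pattern → novel
putative toxin family (novel putative toxin for singlets); otherwise →
novel putative secreted protein.

The scoring schemes are BLOSUM62 with affine gaps 11/1 (protein,
λ = 0.267, K = 0.041) and +2/−3 with gaps 5/2 (nucleotide, λ = 0.625,
K = 0.41); `E = m·n·2^(−bit)` with `bit = (λ·S − ln K)/ln 2`.

## Worked example

Simulate a paired study (20 housekeeping transcripts shared with the
chela, 5 alpha-NaTx and 5 alpha-KTx toxins, two planted novel families of
3 members, 10 noise transcripts), then annotate and discover:

```sh
venomscan simulate --seed 1 --out run/data
mkdir run/db && cp run/data/{reference,representatives}.fasta run/db/
venomscan discover --telson run/data/telson.fasta \
    --counts run/data/telson_counts.tsv \
    --chela run/data/chela.fasta --chela-counts run/data/chela_counts.tsv \
    --db run/db --pooled run/data/telson.fasta \
    --known run/data/known.fasta --out run/out
```

The annotation stage prints the post-pipeline label counts:

```json
{
  "toxin:alpha-KTx": 5,
  "toxin:alpha-NaTx": 5,
  "unidentified": 15
}
```

— all 20 housekeeping transcripts were removed as chela orthologues,
every planted toxin received its planted family, and the 15 unidentified
survivors are the 6 novel-family members plus 9 noise transcripts.  The
discovery stage then prints one category per cluster:

```json
{
  "cluster-1": "novel_putative_toxin_family",
  "cluster-2": "novel_putative_toxin_family",
  "singlet-1": "novel_putative_toxin",
  "singlet-2": "novel_putative_secreted_protein",
  "singlet-3": "novel_putative_secreted_protein",
  "singlet-4": "novel_putative_secreted_protein",
  "singlet-5": "novel_putative_secreted_protein"
}
```

— the two planted novel families are recovered exactly (clusters 1–2);
the singlets are noise transcripts whose random ORFs happened to look
secreted, which is the expected false-positive mode of the selection
rules.  `run/out/` holds the labeled transcript table, composition
report, attrition log, cluster table and per-cluster alignments.

The same workflow is available as library calls
(`venomscan.generate`, `venomscan.run_pipeline`,
`venomscan.discover_novel_toxins`).

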