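"""Sequence records, FASTA I/O, translation, six-frame ORF finding and
cysteine-scaffold extraction.

Transcripts are assembled nucleotide sequences over {A,C,G,T,N} carrying a
read count, a tissue of origin (telson = venom gland, chela = control
pincer), a coverage value filled in by the annotation pipeline, and a
lifecycle label that only moves forward from ``unprocessed``.

Coordinates are 0-based half-open on the forward strand of the transcript
throughout; report writers convert to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: frame sort order used for deterministic tie-breaking
FRAME_ORDER = (1, 2, 3, -1, -2, -3)

TISSUES = ("telson", "chela")

LABEL_UNPROCESSED = "unprocessed"
LABEL_PHYSIOLOGICAL = "physiological"
LABEL_OTHER_TOXIN = "other_toxin"
LABEL_UNIDENTIFIED = "unidentified"
TOXIN_PREFIX = "toxin:"


def toxin_label(family: str) -> str:
    return TOXIN_PREFIX + family


def is_toxin_family_label(label: str) -> bool:
    return label.startswith(TOXIN_PREFIX)


def toxin_family_of(label: str) -> Optional[str]:
    """Family name of a ``toxin:<family>`` label, else None."""
    if is_toxin_family_label(label):
        return label[len(TOXIN_PREFIX):]
    return None


def is_venom_label(label: str) -> bool:
    """Venom set = named toxin families plus ``other_toxin``."""
    return is_toxin_family_label(label) or label == LABEL_OTHER_TOXIN


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, duplicate ids, ...)."""


@dataclass
class Transcript:
    """One assembled transcript with its read count and lifecycle label."""

    id: str
    seq: str
    read_count: int
    tissue: str
    coverage: Optional[float] = None
    label: str = LABEL_UNPROCESSED

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise SequenceError(f"transcript {self.id!r}: empty sequence")
        if self.read_count < 0:
            raise SequenceError(f"transcript {self.id!r}: negative read count")
        if self.tissue not in TISSUES:
            raise SequenceError(
                f"transcript {self.id!r}: unknown tissue {self.tissue!r}"
            )
        bad = _first_bad_char(self.seq, NT_ALPHABET)
        if bad is not None:
            raise SequenceError(
                f"transcript {self.id!r}: non-ACGTN character "
                f"{self.seq[bad]!r} at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a transcript.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand and
    include the closing stop codon when one exists; ``peptide`` never
    contains the stop symbol.  ``open_ended`` marks ORFs that run into the
    transcript end without a stop (common for 3'-truncated assemblies).
    """

    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    peptide: str
    open_ended: bool = False

    @property
    def nt_span(self) -> int:
        return self.nt_end - self.nt_start


@dataclass(frozen=True)
class CysteinePattern:
    """Cysteine scaffold of a peptide.

    ``spacing`` encodes the inter-cysteine residue gaps, e.g. three C's at
    indices 1, 5, 6 give ``"C-3-C-0-C"``.  ``bridged`` is the
    disulfide-bridged-peptide criterion: at least two cysteines available to
    pair.
    """

    positions: tuple[int, ...]
    count: int
    spacing: str
    bridged: bool


def _first_bad_char(seq: str, alphabet: frozenset) -> Optional[int]:
    for i, c in enumerate(seq):
        if c not in alphabet:
            return i
    return None


# ---------------------------------------------------------------------------
# FASTA and read-count I/O
# ---------------------------------------------------------------------------

_COUNT_TOKEN = re.compile(r"\bcount=(\d+)\b")


def read_counts_table(path) -> dict[str, int]:
    """Read a two-column ``id<TAB>read_count`` sidecar (header optional)."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            name, value = parts
            try:
                n = int(value)
            except ValueError:
                if lineno == 1:  # optional header row
                    continue
                raise SequenceError(
                    f"{path}: line {lineno}: non-integer read count {value!r}"
                ) from None
            if name in counts:
                raise SequenceError(f"{path}: duplicate id {name!r} in counts")
            counts[name] = n
    return counts


def read_fasta(path, tissue: str, counts=None) -> list[Transcript]:
    """Read a transcriptome FASTA into Transcript records.

    Read counts come from the ``counts`` sidecar table when given, otherwise
    from a ``count=<int>`` token in each FASTA header; a record with neither
    is an error.
    """
    table = read_counts_table(counts) if counts is not None else None
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate transcript id {rec.id!r}")
        seen.add(rec.id)
        if table is not None:
            if rec.id not in table:
                raise SequenceError(
                    f"{path}: id {rec.id!r} missing from counts table"
                )
            count = table[rec.id]
        else:
            m = _COUNT_TOKEN.search(rec.description)
            if not m:
                raise SequenceError(
                    f"{path}: record {rec.id!r} has no counts entry and no "
                    "count=<int> header token"
                )
            count = int(m.group(1))
        transcripts.append(
            Transcript(id=rec.id, seq=str(rec.seq).upper(), read_count=count,
                       tissue=tissue)
        )
    return transcripts


def write_fasta(records: Iterable[tuple[str, str]], path,
                descriptions: Optional[dict[str, str]] = None) -> None:
    """Write ``(id, seq)`` pairs as FASTA wrapped at 60 columns."""
    seqrecs = []
    for rid, seq in records:
        desc = (descriptions or {}).get(rid, "")
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def write_counts_table(counts: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for rid, n in counts.items():
            fh.write(f"{rid}\t{n}\n")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str, frame: int) -> str:
    """Translate ``seq`` in one of the six frames with the standard code.

    Codons containing N translate to X, stops to ``*``.  Negative frames
    translate the reverse complement.  Fewer than 3 nt after the frame
    offset yields an empty string.
    """
    if frame not in FRAME_ORDER:
        raise ValueError(f"frame must be one of {FRAME_ORDER}, got {frame}")
    s = seq if frame > 0 else reverse_complement(seq)
    s = s[abs(frame) - 1:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate())


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

_STOPS = frozenset(("TAA", "TAG", "TGA"))


def _frame_codons(seq: str, frame: int) -> tuple[str, int]:
    """Return (strand sequence trimmed to whole codons, offset) for a frame."""
    s = seq if frame > 0 else reverse_complement(seq)
    off = abs(frame) - 1
    s = s[off:]
    return s[: len(s) - len(s) % 3], off


def find_orfs(t: Transcript, min_nt: int = 75, policy: str = "atg_only"
              ) -> list[Orf]:
    """Predict ORFs in all six frames.

    Every ATG-to-next-in-frame-stop stretch whose nucleotide span (stop
    codon included) is at least ``min_nt`` is reported, nested starts
    included.  ORFs that reach the transcript end without a stop are kept
    and flagged ``open_ended``.  Output is sorted by descending span, then
    frame order +1,+2,+3,-1,-2,-3, then ascending start.
    """
    if policy != "atg_only":
        raise ValueError(f"unsupported start-codon policy {policy!r}")
    if min_nt < 6 or min_nt % 3:
        raise ValueError("min_nt must be >= 6 and divisible by 3")
    L = len(t.seq)
    orfs: list[Orf] = []
    for frame in FRAME_ORDER:
        s, off = _frame_codons(t.seq, frame)
        ncod = len(s) // 3
        codons = [s[3 * i: 3 * i + 3] for i in range(ncod)]
        stop_idx = [i for i, c in enumerate(codons) if c in _STOPS]
        for i, c in enumerate(codons):
            if c != "ATG":
                continue
            nxt = next((j for j in stop_idx if j >= i), None)
            if nxt is None:
                end_cod, open_ended = ncod, True
                pep_cods = codons[i:ncod]
            else:
                end_cod, open_ended = nxt + 1, False
                pep_cods = codons[i:nxt]
            span = (end_cod - i) * 3
            if span < min_nt:
                continue
            peptide = str(Seq("".join(pep_cods)).translate())
            # strand-local -> forward-strand half-open coordinates
            a, b = off + 3 * i, off + 3 * end_cod
            if frame < 0:
                a, b = L - b, L - a
            orfs.append(Orf(t.id, frame, a, b, peptide, open_ended))
    orfs.sort(key=lambda o: (-o.nt_span, FRAME_ORDER.index(o.frame),
                             o.nt_start))
    return orfs


def longest_orf(orfs: list[Orf]) -> Optional[Orf]:
    """First element of the canonical sort order, or None when empty."""
    return orfs[0] if orfs else None


# ---------------------------------------------------------------------------
# Cysteine scaffolds
# ---------------------------------------------------------------------------

def cysteine_pattern(peptide: str) -> CysteinePattern:
    """Extract the cysteine scaffold of a peptide."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    positions = tuple(i for i, c in enumerate(peptide) if c == "C")
    count = len(positions)
    if count == 0:
        spacing = ""
    elif count == 1:
        spacing = "C"
    else:
        gaps = [positions[k + 1] - positions[k] - 1 for k in range(count - 1)]
        spacing = "C-" + "-C-".join(str(g) for g in gaps) + "-C"
    return CysteinePattern(positions=positions, count=count, spacing=spacing,
                           bridged=count >= 2)


def spacing_gaps(pattern: CysteinePattern) -> tuple[int, ...]:
    """Inter-cysteine gap lengths of a scaffold."""
    return tuple(pattern.positions[k + 1] - pattern.positions[k] - 1
                 for k in range(pattern.count - 1))
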