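"""Shared fixtures: one synthetic study generated once per session, plus
independent brute-force oracles for the aligner and ORF finder."""

from __future__ import annotations

import pytest

import venomscan as vs
from venomscan import refdb


@pytest.fixture(scope="session")
def dataset() -> vs.SyntheticDataset:
    return vs.generate(vs.SimConfig(seed=1))


@pytest.fixture(scope="session")
def reference_db(dataset) -> vs.ReferenceDB:
    general = [r for r in dataset.reference if r.source == refdb.SOURCE_GENERAL]
    venom = [r for r in dataset.reference if r.source == refdb.SOURCE_VENOM]
    return refdb.build(general, venom, dataset.representatives)


@pytest.fixture(scope="session")
def pipeline_result(dataset, reference_db) -> vs.PipelineResult:
    return vs.run_pipeline(dataset.telson, dataset.chela, reference_db)


@pytest.fixture(scope="session")
def clusters(pipeline_result, dataset):
    return vs.discover_novel_toxins(pipeline_result, dataset.telson,
                                    dataset.known)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp_oracle(seq: str) -> str:
    return "".join(_COMPL[c] for c in reversed(seq))


def orf_oracle(seq: str, min_nt: int = 75) -> list[tuple]:
    """Enumerate every (frame, ATG index, next in-frame stop) triple.

    Returns tuples (frame, nt_start, nt_end, peptide, open_ended) in the
    canonical sort order, written independently of the implementation.
    """
    L = len(seq)
    found = []
    for frame in (1, 2, 3, -1, -2, -3):
        strand = seq if frame > 0 else revcomp_oracle(seq)
        off = abs(frame) - 1
        idx = [off + 3 * k for k in range((L - off) // 3)]
        for pos_i, start in enumerate(idx):
            if strand[start:start + 3] != "ATG":
                continue
            stop_at = None
            for j in idx[pos_i:]:
                if _CODE.get(strand[j:j + 3], "X") == "*":
                    stop_at = j
                    break
            if stop_at is None:
                end = idx[-1] + 3
                open_ended = True
                pep_nt = strand[start:end]
            else:
                end = stop_at + 3
                open_ended = False
                pep_nt = strand[start:stop_at]
            span = end - start
            if span < min_nt:
                continue
            pep = "".join(_CODE.get(pep_nt[k:k + 3], "X")
                          for k in range(0, len(pep_nt), 3))
            a, b = (start, end) if frame > 0 else (L - end, L - start)
            found.append((frame, a, b, pep, open_ended))
    order = (1, 2, 3, -1, -2, -3)
    found.sort(key=lambda o: (-(o[2] - o[1]), order.index(o[0]), o[1]))
    return found


def sw_linear_oracle(a: str, b: str, match: int, mismatch: int,
                     gap: int) -> int:
    """Quadratic Smith-Waterman with linear gap costs (cost = gap per
    residue), equal to the affine engine when gap_open == gap_extend."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] - gap,
                          H[i][j - 1] - gap)
            best = max(best, H[i][j])
    return best


def sw_exhaustive_oracle(a: str, b: str, match: int, mismatch: int,
                         gap_open: int, gap_extend: int) -> int:
    """Best local alignment score by exhaustive recursion over every
    gapped alignment of every substring pair (tiny inputs only)."""
    best = 0

    def recurse(i: int, j: int, score: int, state: str) -> None:
        nonlocal best
        best = max(best, score)  # alignment may end anywhere (local)
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            recurse(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = gap_extend if state == "I" else gap_open
            recurse(i + 1, j, score - cost, "I")
        if j < len(b):
            cost = gap_extend if state == "D" else gap_open
            recurse(i, j + 1, score - cost, "D")

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            recurse(i0, j0, 0, "M")
    return best
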