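"""Signal-peptide prediction.

Secreted scorpion toxins carry an N-terminal leader with the classic
tripartite architecture: a short positively charged n-region, a hydrophobic
h-region core, and a c-region ending in small residues at the -3/-1
positions of the cleavage site.  The built-in predictor scores these three
components explicitly (a transparent von-Heijne-style heuristic) and maps
the combined score onto the qualitative high/some/low bands used by the
novelty classifier.  An adapter hook imports externally computed
predictions (tab-separated ``id<TAB>score<TAB>cleavage_pos``) into the same
type, so downstream behavior is independent of the backend.

Component scores, combined with weights 0.2 / 0.5 / 0.3:

* n-region charge: 1 if any K/R occurs in residues 2-6;
* h-region hydrophobicity: 1 when the best 8-residue window starting
  within residues 3-20 reaches a mean Kyte-Doolittle of 1.6 (the detection
  threshold), 0 otherwise — a hydrophobic core is the defining feature of
  a leader, so this component is a hard gate rather than a graded score;
* c-region: small residues {A,G,S,C,T,V} at -3 and -1 of the best
  candidate cleavage site after residues 15-35 (half credit each).

The cleavage position is the best-scoring candidate site; it is undefined
when the h-region fails its threshold.  Peptides shorter than 15 residues
cannot hold the architecture and score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

BAND_HIGH = "high"
BAND_SOME = "some"
BAND_LOW = "low"

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

SMALL_RESIDUES = frozenset("AGSCTV")


@dataclass(frozen=True)
class SignalConfig:
    """Cutoffs and weights of the heuristic (all configurable)."""

    presence_cutoff: float = 0.45
    high_cutoff: float = 0.75
    some_cutoff: float = 0.45
    weight_n: float = 0.2
    weight_h: float = 0.5
    weight_c: float = 0.3
    h_window: int = 8
    h_min_kd: float = 1.6
    min_length: int = 15
    cleavage_lo: int = 15   # 1-based candidate cleavage range
    cleavage_hi: int = 35


DEFAULT_CONFIG = SignalConfig()


@dataclass(frozen=True)
class SignalPrediction:
    """Score in [0,1], cleavage position (1-based residue after which the
    leader is cleaved, or None) and qualitative band."""

    score: float
    cleavage_pos: Optional[int]
    band: str
    present: bool


#: adapter contract: anything mapping a peptide to a SignalPrediction
Predictor = Callable[[str], SignalPrediction]


def band_of(score: float, cfg: SignalConfig = DEFAULT_CONFIG) -> str:
    """Map a score onto the high / some / low bands."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score >= cfg.high_cutoff:
        return BAND_HIGH
    if score >= cfg.some_cutoff:
        return BAND_SOME
    return BAND_LOW


def predict_signal(peptide: str, cfg: SignalConfig = DEFAULT_CONFIG
                   ) -> SignalPrediction:
    """Score an N-terminal signal peptide on ``peptide``."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    if len(peptide) < cfg.min_length:
        return SignalPrediction(0.0, None, BAND_LOW, False)
    if not peptide.startswith("M"):
        warnings.warn(f"peptide does not start with M: {peptide[:10]!r}...",
                      stacklevel=2)

    # (a) n-region charge: K/R within residues 2-6
    n_score = 1.0 if any(c in "KR" for c in peptide[1:6]) else 0.0

    # (b) h-region: best 8-residue window starting within residues 3-20
    best_mean = None
    for start in range(2, min(20, len(peptide) - cfg.h_window + 1)):
        window = peptide[start:start + cfg.h_window]
        mean = sum(KYTE_DOOLITTLE[c] for c in window) / cfg.h_window
        if best_mean is None or mean > best_mean:
            best_mean = mean
    h_ok = best_mean is not None and best_mean >= cfg.h_min_kd
    h_score = 1.0 if h_ok else 0.0

    # (c) c-region: small residues at -3 and -1 of a candidate cleavage site
    c_score = 0.0
    cleavage: Optional[int] = None
    for p in range(cfg.cleavage_lo, min(cfg.cleavage_hi, len(peptide) - 1) + 1):
        site = 0.0
        if peptide[p - 3] in SMALL_RESIDUES:
            site += 0.5
        if peptide[p - 1] in SMALL_RESIDUES:
            site += 0.5
        if site > c_score:
            c_score, cleavage = site, p

    score = cfg.weight_n * n_score + cfg.weight_h * h_score \
        + cfg.weight_c * c_score
    score = min(1.0, max(0.0, score))
    return SignalPrediction(
        score=score,
        cleavage_pos=cleavage if h_ok else None,
        band=band_of(score, cfg),
        present=score >= cfg.presence_cutoff,
    )


def read_predictions(path, cfg: SignalConfig = DEFAULT_CONFIG
                     ) -> dict[str, SignalPrediction]:
    """Import external predictor output (``id<TAB>score<TAB>cleavage_pos``).

    ``cleavage_pos`` may be ``-`` or empty for no cleavage site.  Returns a
    mapping usable wherever the built-in predictor is.
    """
    preds: dict[str, SignalPrediction] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns")
            rid, score_s, cleave_s = parts
            score = float(score_s)
            cleavage = None if cleave_s in ("", "-") else int(cleave_s)
            preds[rid] = SignalPrediction(
                score=score, cleavage_pos=cleavage,
                band=band_of(score, cfg),
                present=score >= cfg.presence_cutoff)
    return preds


def leader_region(peptide: str, prediction: SignalPrediction,
                  fallback_len: int = 20) -> str:
    """The signal-peptide region of a peptide: up to the predicted cleavage
    site, or the first ``fallback_len`` residues when no site is defined."""
    if prediction.cleavage_pos is not None:
        return peptide[:prediction.cleavage_pos]
    return peptide[:fallback_len]
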