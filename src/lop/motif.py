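"""Position-weight-matrix handling and masked promoter scanning.

Scores are probability sums: the score of a window is the sum over positions
of the (pseudocounted, background-weighted) base probability, so every
column contributes a nonnegative term and "80% of the maximum score" is a
well-defined fractional threshold.  A match is a window whose score strictly
exceeds ``min_frac * max_score``.  Windows containing any masked base
(lowercase or N) are ineligible and excluded from the scanned-length
covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PWMRecord", "ScanResult", "build_pwm", "scan_region", "count_table",
    "assemble_dictionary", "filter_dictionary", "MIN_MOTIF_LENGTH",
]

BASES = "ACGT"
MIN_MOTIF_LENGTH = 4

# byte -> base code; uppercase ACGT get 0..3, everything else (N, lowercase
# soft-masking, ambiguity codes) is ineligible (-1)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class PWMRecord:
    id: str
    pfm: np.ndarray                  # 4 x L nonnegative counts
    probs: np.ndarray                # 4 x L column-stochastic scores
    max_score: float
    min_score: float
    source_db: str = "custom"

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWMRecord":
        rc = self.probs[::-1, ::-1]
        return PWMRecord(id=self.id, pfm=self.pfm[::-1, ::-1], probs=rc,
                         max_score=self.max_score, min_score=self.min_score,
                         source_db=self.source_db)


def build_pwm(motif_id: str, pfm, pseudocount: float = 0.25,
              background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
              source_db: str = "custom") -> PWMRecord:
    """PWM from a position frequency matrix of counts.

    Column scores are (count + 4*pseudocount*background_b) normalized to sum
    to one, so with the uniform background each cell receives the classic
    +pseudocount.  Length validation (>= 4) belongs to dictionary assembly,
    not here, so short toy motifs remain constructible.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("pfm must be a 4 x L array (rows A, C, G, T)")
    if (pfm < 0).any():
        raise ValueError("pfm counts must be nonnegative")
    if (pfm.sum(axis=0) == 0).any():
        raise ValueError("every pfm column needs at least one positive count")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
        raise ValueError("background must be 4 probabilities summing to 1")
    probs = (pfm + 4.0 * pseudocount * bg[:, None]) / (pfm.sum(axis=0) + 4.0 * pseudocount)
    return PWMRecord(
        id=motif_id, pfm=pfm, probs=probs,
        max_score=float(probs.max(axis=0).sum()),
        min_score=float(probs.min(axis=0).sum()),
        source_db=source_db,
    )


@dataclass(frozen=True)
class ScanResult:
    gene: str | None
    count: int
    scanned_length: int              # eligible window start positions
    matches: tuple = ()              # (position 1-based, strand, score)

    def __post_init__(self):
        assert self.count == len(self.matches)


def _window_scores(codes: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows plus eligibility; vectorized over start positions."""
    L = probs.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_win)
    eligible = np.ones(n_win, dtype=bool)
    for j in range(L):
        col = codes[j:j + n_win]
        bad = col < 0
        eligible &= ~bad
        scores += probs[np.where(bad, 0, col), j]
    return scores, eligible


def scan_region(seq: str, pwm: PWMRecord, min_frac: float = 0.80,
                strands: str = "both", gene: str | None = None) -> ScanResult:
    """Count PWM matches in a masked sequence.

    A window matches iff its probability-sum score strictly exceeds
    ``min_frac * pwm.max_score``.  Minus-strand windows are scored with the
    reverse-complement matrix and reported at their forward-strand start.
    ``scanned_length`` counts eligible (fully unmasked) window starts on the
    region, which is identical for either strand.
    """
    if strands not in ("both", "forward", "reverse"):
        raise ValueError("strands must be 'both', 'forward' or 'reverse'")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    L = pwm.length
    if len(seq) < L:
        return ScanResult(gene=gene, count=0, scanned_length=0)
    threshold = min_frac * pwm.max_score
    matches = []
    scores, eligible = _window_scores(codes, pwm.probs)
    scanned = int(eligible.sum())
    if strands in ("both", "forward"):
        for i in np.nonzero(eligible & (scores > threshold))[0]:
            matches.append((int(i) + 1, "+", float(scores[i])))
    if strands in ("both", "reverse"):
        rc_scores, rc_eligible = _window_scores(codes, pwm.reverse_complement().probs)
        for i in np.nonzero(rc_eligible & (rc_scores > threshold))[0]:
            matches.append((int(i) + 1, "-", float(rc_scores[i])))
    matches.sort()
    return ScanResult(gene=gene, count=len(matches), scanned_length=scanned,
                      matches=tuple(matches))


def count_table(sequences, pwms: Sequence[PWMRecord], min_frac: float = 0.80,
                strands: str = "both") -> pd.DataFrame:
    """Long-format (gene, motif, count, scanned_length) table over all
    gene x motif pairs, in deterministic gene order."""
    if not pwms:
        raise ValueError("motif dictionary is empty")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    seen = set()
    for g, _ in items:
        if g in seen:
            raise ValueError(f"duplicate gene id {g!r}")
        seen.add(g)
    rows = []
    for gene, seq in items:
        for pwm in pwms:
            r = scan_region(seq, pwm, min_frac=min_frac, strands=strands, gene=gene)
            rows.append((gene, pwm.id, r.count, r.scanned_length))
    df = pd.DataFrame(rows, columns=["gene", "motif", "count", "scanned_length"])
    for m, tot in df.groupby("motif")["count"].sum().items():
        log.debug("motif %s: %d total matches", m, tot)
    return df


def _is_repetitive(pwm: PWMRecord) -> bool:
    """A homopolymer consensus (every column favouring the same base)."""
    return len(set(pwm.consensus)) == 1


def assemble_dictionary(sources: Mapping[str, Sequence[PWMRecord]]):
    """Pool motifs from several source databases.

    Returns (pooled, per_source_counts); ids must be unique across sources.
    """
    pooled: list[PWMRecord] = []
    counts = {}
    seen = set()
    for source, records in sources.items():
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate motif id {rec.id!r} across sources")
            seen.add(rec.id)
            pooled.append(PWMRecord(rec.id, rec.pfm, rec.probs, rec.max_score,
                                    rec.min_score, source_db=source))
        counts[source] = len(records)
    return pooled, counts


def filter_dictionary(records: Sequence[PWMRecord], min_length: int = MIN_MOTIF_LENGTH,
                      exclude_repetitive: bool = True):
    """Drop motifs shorter than ``min_length`` and (optionally) repetitive
    homopolymer motifs; returns (kept, removed)."""
    kept, removed = [], []
    for rec in records:
        if rec.length < min_length or (exclude_repetitive and _is_repetitive(rec)):
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed
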