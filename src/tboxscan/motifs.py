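"""PWM construction, double-stranded scanning, score scaling, and motif
coverage / positional summaries around peak summits.

The raw score of a window is the sum over positions of log10 likelihood
ratios against the background base composition (uniform by default). The
display convention clamps raw scores into [1.5, 5.0] and scales that range
onto the BED 0-1000 score field. Masked or ambiguous bases (N) score -inf,
so no window containing them can reach a reporting threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import FORWARD, REVERSE, Peak
from .simulate import reverse_complement

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: display score range: raw 1.5..5.0 maps onto BED 0..1000
MIN_REPORTABLE, MAX_SCORE = 1.5, 5.0


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix with additive per-position base weights."""

    motif_id: str
    weights: np.ndarray  # L x 4, log10 likelihood ratios
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("weights must be L x 4")
        if w.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def score_word(self, word: str) -> float:
        """Additive score of one window; N (or any non-ACGT base) gives -inf."""
        if len(word) != len(self):
            raise ValueError(f"word length {len(word)} != motif length "
                             f"{len(self)}")
        total = 0.0
        for pos, base in enumerate(word.upper()):
            i = _BASE_INDEX.get(base)
            if i is None:
                return -math.inf
            total += self.weights[pos, i]
        return total


@dataclass(frozen=True)
class MotifHit:
    """One PWM match in forward-strand coordinates of the window start."""

    scaffold: str
    position: int
    strand: int
    raw_score: float
    offset_from_summit: int | None = None

    @property
    def bed_score(self) -> int:
        return bed_score(self.raw_score)


def bed_score(raw: float) -> int:
    """Clamp a raw score into [1.5, 5.0] and scale onto 0-1000."""
    clamped = min(max(raw, MIN_REPORTABLE), MAX_SCORE)
    return round(1000.0 * (clamped - MIN_REPORTABLE)
                 / (MAX_SCORE - MIN_REPORTABLE))


def build_pwm(
    counts: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = 0.01,
    background: Sequence[float] | None = None,
    motif_id: str = "pwm",
) -> Pwm:
    """Counts -> log10-odds PWM.

    weight[pos, b] = log10(((count + pseudocount) / (rowsum + 4 pc)) / bg_b).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be L x 4")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rowsums = counts.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("all-zero count row")
    bg = np.full(4, 0.25) if background is None else np.asarray(background,
                                                                dtype=float)
    probs = (counts + pseudocount) / (rowsums[:, None] + 4.0 * pseudocount)
    return Pwm(motif_id=motif_id, weights=np.log10(probs / bg), background=bg)


def pwm_from_consensus(consensus: str, pseudocount: float = 0.01,
                       motif_id: str = "consensus") -> Pwm:
    """One-hot counts from a consensus word (convenience constructor)."""
    counts = np.zeros((len(consensus), 4))
    for pos, base in enumerate(consensus.upper()):
        counts[pos, _BASE_INDEX[base]] = 1.0
    return build_pwm(counts, pseudocount=pseudocount, motif_id=motif_id)


@dataclass(frozen=True)
class FlankRecord:
    """Summit-centred subsequence with genomic bookkeeping."""

    scaffold: str
    start: int  # genomic position of sequence[0]
    sequence: str
    summit: int
    truncated: bool


def extract_summit_flanks(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    width: int = 200,
) -> list[FlankRecord]:
    """Extract ``width``-bp sequence windows centred on peak summits.

    Windows reaching past a scaffold edge are truncated and flagged; the
    invariant ``hit offset + record start = genomic position`` always holds.
    """
    records: list[FlankRecord] = []
    half = width // 2
    for pk in peaks:
        seq = sequences[pk.scaffold]
        lo, hi = pk.summit - half, pk.summit + half
        start, end = max(0, lo), min(len(seq), hi)
        records.append(FlankRecord(
            scaffold=pk.scaffold, start=start, sequence=seq[start:end],
            summit=pk.summit, truncated=(start != lo or end != hi)))
    return records


def scan(
    pwm: Pwm,
    sequence: str,
    threshold: float,
    scaffold: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Score every window of both strands; report hits >= threshold.

    Reverse-complement hits are reported at the forward-strand window start.
    ``offset`` shifts reported positions into genomic coordinates when
    ``sequence`` is a subsequence starting there.
    """
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return []
    hits: list[MotifHit] = []
    seq = sequence.upper()
    for start in range(n - L + 1):
        window = seq[start:start + L]
        fwd = pwm.score_word(window)
        if fwd >= threshold:
            hits.append(MotifHit(scaffold=scaffold, position=offset + start,
                                 strand=FORWARD, raw_score=fwd))
        rev = pwm.score_word(reverse_complement(window))
        if rev >= threshold:
            hits.append(MotifHit(scaffold=scaffold, position=offset + start,
                                 strand=REVERSE, raw_score=rev))
    return hits


def scan_flanks(
    pwm: Pwm,
    flanks: Sequence[FlankRecord],
    threshold: float,
) -> list[MotifHit]:
    """Scan summit flanks, reporting genomic positions and summit offsets."""
    hits: list[MotifHit] = []
    for rec in flanks:
        for h in scan(pwm, rec.sequence, threshold, scaffold=rec.scaffold,
                      offset=rec.start):
            hits.append(MotifHit(
                scaffold=h.scaffold, position=h.position, strand=h.strand,
                raw_score=h.raw_score,
                offset_from_summit=h.position - rec.summit))
    return hits


def motif_coverage(
    peaks: Sequence[Peak],
    hits_by_pwm: Mapping[str, Sequence[MotifHit]],
    window_bp: int = 100,
) -> float:
    """Fraction of peaks with >= 1 hit (any PWM) within ``window_bp`` of the
    summit — union coverage when several PWMs are given."""
    if not peaks:
        raise ValueError("empty peak set")
    covered = 0
    for pk in peaks:
        found = any(
            h.scaffold == pk.scaffold and abs(h.position - pk.summit) <= window_bp
            for hits in hits_by_pwm.values() for h in hits
        )
        covered += found
    return covered / len(peaks)


def motif_position_histogram(
    hits: Sequence[MotifHit],
    limit_bp: int = 200,
    break_bp: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of hit-start offsets from summits over [-limit, +limit]."""
    edges = np.arange(-limit_bp, limit_bp + break_bp, break_bp)
    offsets = np.array([h.offset_from_summit for h in hits
                        if h.offset_from_summit is not None])
    if offsets.size == 0:
        return edges, np.zeros(edges.size - 1, dtype=int)
    counts, _ = np.histogram(
        offsets[(offsets >= -limit_bp) & (offsets < limit_bp)], bins=edges)
    return edges, counts
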