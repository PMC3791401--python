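"""Synthetic genomes, peak tracks, motif plants, expression tables and
binding curves with the statistical structure the downstream analyses assume.

Every generator is deterministic for a fixed :class:`SimConfig.seed`. The
root seed is expanded into fixed per-generator substreams, so adding or
re-running one generator never perturbs the draws of another.

What is emulated: promoter-proximal binding (peak summits scattered normally
around TSSs), long-tailed -log10 p peak scores, cofactor tracks sharing sites
with positional jitter, motif instances planted near summits on either
strand, knockdown expression shifts linked to promoter-proximal binding, and
noisy 1:1 binding isotherms. Background binding is uniform per scaffold — a
stand-in, not an inference about real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FORWARD, REVERSE, GeneModel, GenomicInterval, Peak

logger = logging.getLogger(__name__)

# fixed substream ids (root seed is paired with one of these)
_S_GENOME, _S_PEAKS, _S_COFACTOR, _S_MOTIFS, _S_EXPR, _S_CURVE = range(6)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    Distances and lengths are in bp; ``de_effect_size`` is in log2 units;
    ``score_distribution`` gives the (shape, scale) of the gamma draw for
    peak -log10 p scores.
    """

    seed: int = 0
    n_scaffolds: int = 4
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_000, 8_000)
    intergenic_mean: float = 6_000.0
    target_fraction: float = 0.5
    tss_peak_sd: float = 100.0
    score_distribution: tuple[float, float] = (1.5, 20.0)
    cofactor_jitter_sd: float = 10.0
    cofactor_shared_fraction: float = 0.8
    motif_plant_prob: float = 0.8
    de_effect_size: float = 2.0
    de_noise_sd: float = 0.5
    n_replicates: int = 3
    peak_halfwidth: int = 150
    n_background_peaks: int = 50
    up_fraction: float = 0.10
    de_bound_quantile: float = 0.5
    scaffold_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("target_fraction", "cofactor_shared_fraction",
                     "motif_plant_prob", "up_fraction", "de_bound_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("tss_peak_sd", "cofactor_jitter_sd", "de_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def simulate_genome(cfg: SimConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """Tile genes on scaffolds and draw i.i.d. uniform background sequence.

    Genes get random strands and 1-8 non-overlapping exons whose first/last
    edges coincide with the gene body; short 5'/3' UTR stubs are carved from
    the terminal exons in transcription orientation. Raises ``ValueError``
    when a fixed ``scaffold_length`` cannot hold the requested genes.
    """
    rng = cfg.rng(_S_GENOME)
    per_scaffold = [cfg.n_genes // cfg.n_scaffolds] * cfg.n_scaffolds
    for i in range(cfg.n_genes % cfg.n_scaffolds):
        per_scaffold[i] += 1

    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    gidx = 0
    for s in range(cfg.n_scaffolds):
        scaffold = f"scaffold_{s + 1}"
        pos = int(rng.exponential(cfg.intergenic_mean)) + 200
        for _ in range(per_scaffold[s]):
            length = int(rng.integers(cfg.gene_length_range[0],
                                      cfg.gene_length_range[1] + 1))
            start, end = pos, pos + length
            if cfg.scaffold_length is not None and end > cfg.scaffold_length:
                raise ValueError(
                    f"genes do not fit on {scaffold} "
                    f"(need > {end} bp, have {cfg.scaffold_length})"
                )
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            body = GenomicInterval(scaffold, start, end, strand)
            exons = _random_exons(rng, body)
            utr5, utr3 = _terminal_utrs(rng, exons, strand)
            gidx += 1
            genes.append(GeneModel(gene_id=f"gene_{gidx:04d}", body=body,
                                   exons=exons, utr5=utr5, utr3=utr3))
            pos = end + int(rng.exponential(cfg.intergenic_mean)) + 200
        seq_len = cfg.scaffold_length if cfg.scaffold_length is not None \
            else pos + 1_000
        sequences[scaffold] = "".join(
            _BASES[rng.integers(0, 4, size=seq_len)])
    return genes, sequences


def _random_exons(rng: np.random.Generator,
                  body: GenomicInterval) -> tuple[GenomicInterval, ...]:
    length = len(body)
    k = int(rng.integers(1, 9))
    # need 2k-1 non-empty alternating exon/intron segments
    while k > 1 and length < 2 * k - 1:
        k -= 1
    if k == 1:
        return (GenomicInterval(body.scaffold, body.start, body.end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * k - 2,
                              replace=False))
    bounds = np.concatenate([[0], cuts, [length]]) + body.start
    return tuple(
        GenomicInterval(body.scaffold, int(bounds[i]), int(bounds[i + 1]))
        for i in range(0, 2 * k - 1, 2)
    )


def _terminal_utrs(
    rng: np.random.Generator,
    exons: tuple[GenomicInterval, ...],
    strand: int,
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    first, last = exons[0], exons[-1]
    head_len = int(min(rng.integers(20, 80), len(first)))
    tail_len = int(min(rng.integers(20, 80), len(last)))
    head = GenomicInterval(first.scaffold, first.start, first.start + head_len)
    tail = GenomicInterval(last.scaffold, last.end - tail_len, last.end)
    if strand == FORWARD:
        return (head,), (tail,)
    return (tail,), (head,)


def _draw_scores(rng: np.random.Generator, cfg: SimConfig,
                 n: int) -> np.ndarray:
    shape, scale = cfg.score_distribution
    return rng.gamma(shape, scale, size=n) + 1e-6


def _scaffold_extents(genes: Sequence[GeneModel],
                      cfg: SimConfig) -> dict[str, int]:
    ext: dict[str, int] = {}
    for g in genes:
        ext[g.body.scaffold] = max(ext.get(g.body.scaffold, 0), g.body.end)
    return {s: (cfg.scaffold_length if cfg.scaffold_length is not None
                else e + 1_000) for s, e in ext.items()}


def simulate_peaks(
    genes: Sequence[GeneModel],
    cfg: SimConfig,
    label: str = "TF",
    scaffold_lengths: Mapping[str, int] | None = None,
) -> tuple[list[Peak], list[str | None]]:
    """Plant promoter-proximal peaks and uniform background peaks.

    A ``target_fraction`` of genes receives one peak whose summit is drawn
    from Normal(TSS, tss_peak_sd); ``n_background_peaks`` more are placed
    uniformly across scaffolds. Scores come from the configured gamma
    distribution. Returns the peaks and an aligned truth list holding the
    planted gene_id, or ``None`` for background peaks.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = cfg.rng(_S_PEAKS)
    lengths = dict(scaffold_lengths) if scaffold_lengths is not None \
        else _scaffold_extents(genes, cfg)
    peaks: list[Peak] = []
    truth: list[str | None] = []

    planted_mask = rng.random(len(genes)) < cfg.target_fraction
    n_planted = int(planted_mask.sum())
    scores = _draw_scores(rng, cfg, n_planted + cfg.n_background_peaks)
    si = 0
    for g, planted in zip(genes, planted_mask):
        if not planted:
            continue
        limit = lengths[g.body.scaffold]
        summit = int(round(rng.normal(g.tss, cfg.tss_peak_sd)))
        summit = min(max(summit, 0), limit - 1)
        peaks.append(_summit_peak(g.body.scaffold, summit, limit,
                                  float(scores[si]), cfg, label))
        truth.append(g.gene_id)
        si += 1

    scaffolds = sorted(lengths)
    weights = np.array([lengths[s] for s in scaffolds], dtype=float)
    weights /= weights.sum()
    for _ in range(cfg.n_background_peaks):
        scaffold = scaffolds[rng.choice(len(scaffolds), p=weights)]
        limit = lengths[scaffold]
        summit = int(rng.integers(0, limit))
        peaks.append(_summit_peak(scaffold, summit, limit,
                                  float(scores[si]), cfg, label))
        truth.append(None)
        si += 1
    return peaks, truth


def _summit_peak(scaffold: str, summit: int, limit: int, score: float,
                 cfg: SimConfig, label: str) -> Peak:
    start = max(0, summit - cfg.peak_halfwidth)
    end = min(limit, summit + cfg.peak_halfwidth + 1)
    end = max(end, summit + 1)
    return Peak(interval=GenomicInterval(scaffold, start, end),
                summit=summit, score=score, label=label)


def simulate_cofactor_track(
    peaks: Sequence[Peak],
    cfg: SimConfig,
    label: str = "cofactor",
    scaffold_lengths: Mapping[str, int] | None = None,
) -> tuple[list[Peak], list[int | None]]:
    """Duplicate a shared fraction of peaks with summit jitter.

    Shared peaks get summits jittered by Normal(0, cofactor_jitter_sd) and
    independently resampled scores; the remainder are placed uniformly on the
    same scaffolds. Returns the cofactor peaks and an aligned truth list
    holding the index of the source peak, or ``None`` for unshared peaks.
    """
    if not peaks:
        raise ValueError("peaks must be non-empty")
    rng = cfg.rng(_S_COFACTOR)
    if scaffold_lengths is None:
        lengths: dict[str, int] = {}
        for pk in peaks:
            lengths[pk.scaffold] = max(lengths.get(pk.scaffold, 0),
                                       pk.interval.end + 1_000)
    else:
        lengths = dict(scaffold_lengths)

    shared_mask = rng.random(len(peaks)) < cfg.cofactor_shared_fraction
    scores = _draw_scores(rng, cfg, len(peaks))
    out: list[Peak] = []
    truth: list[int | None] = []
    scaffolds = sorted(lengths)
    weights = np.array([lengths[s] for s in scaffolds], dtype=float)
    weights /= weights.sum()
    for i, (pk, shared) in enumerate(zip(peaks, shared_mask)):
        if shared:
            limit = lengths[pk.scaffold]
            summit = int(round(pk.summit + rng.normal(0.0,
                                                      cfg.cofactor_jitter_sd)))
            summit = min(max(summit, 0), limit - 1)
            out.append(_summit_peak(pk.scaffold, summit, limit,
                                    float(scores[i]), cfg, label))
            truth.append(i)
        else:
            scaffold = scaffolds[rng.choice(len(scaffolds), p=weights)]
            limit = lengths[scaffold]
            summit = int(rng.integers(0, limit))
            out.append(_summit_peak(scaffold, summit, limit,
                                    float(scores[i]), cfg, label))
            truth.append(None)
    return out, truth


def plant_motifs(
    sequences: Mapping[str, str],
    peaks: Sequence[Peak],
    consensus: str,
    cfg: SimConfig,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Write a consensus motif (or its reverse complement) near peak summits.

    With probability ``motif_plant_prob`` per peak, the consensus is written
    at a position uniform within +/-100 bp of the summit, on a random strand.
    Plants that would overrun the scaffold end are skipped with a warning.
    Returns the mutated sequences and a truth list of
    (scaffold, position, strand).
    """
    consensus = consensus.upper()
    L = len(consensus)
    for scaffold, seq in sequences.items():
        if L >= len(seq):
            raise ValueError(f"consensus longer than scaffold {scaffold}")
    rng = cfg.rng(_S_MOTIFS)
    mutable = {s: list(seq) for s, seq in sequences.items()}
    truth: list[tuple[str, int, int]] = []
    for pk in peaks:
        if rng.random() >= cfg.motif_plant_prob:
            continue
        pos = int(rng.integers(pk.summit - 100, pk.summit + 101)) - L // 2
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        seq = mutable[pk.scaffold]
        if pos < 0 or pos + L > len(seq):
            logger.warning("motif plant at %s:%d overruns scaffold; skipped",
                           pk.scaffold, pos)
            continue
        word = consensus if strand == FORWARD else reverse_complement(consensus)
        seq[pos:pos + L] = list(word)
        truth.append((pk.scaffold, pos, strand))
    return {s: "".join(chars) for s, chars in mutable.items()}, truth


def simulate_expression(
    genes: Sequence[GeneModel],
    proximal_occupancy: Mapping[str, float],
    cfg: SimConfig,
) -> pd.DataFrame:
    """Simulate replicate control/knockdown expression linked to binding.

    Baseline log2 expression is Normal(mu_g, de_noise_sd) per replicate.
    Genes whose promoter-proximal occupancy exceeds the
    ``de_bound_quantile`` quantile of the positive occupancies are shifted
    down by ``de_effect_size`` log2 units in the knockdown; an
    ``up_fraction`` of the remaining genes is shifted up by the same amount.
    Returns a DataFrame with gene_id, truth label ({down, up, unaffected}),
    and ctrl_i / kd_i replicate columns (log2 scale).
    """
    rng = cfg.rng(_S_EXPR)
    occ = np.array([proximal_occupancy.get(g.gene_id, 0.0) for g in genes])
    positive = occ[occ > 0]
    if positive.size and cfg.de_effect_size != 0:
        cut = float(np.quantile(positive, cfg.de_bound_quantile))
        down_mask = occ >= max(cut, 1e-12)
    else:
        down_mask = np.zeros(len(genes), dtype=bool)
    up_mask = (~down_mask) & (rng.random(len(genes)) < cfg.up_fraction) \
        if cfg.de_effect_size != 0 else np.zeros(len(genes), dtype=bool)

    mu = rng.normal(5.0, 1.0, size=len(genes))
    shift = np.where(down_mask, -cfg.de_effect_size,
                     np.where(up_mask, cfg.de_effect_size, 0.0))
    rows = []
    for i, g in enumerate(genes):
        ctrl = rng.normal(mu[i], cfg.de_noise_sd, size=cfg.n_replicates)
        kd = rng.normal(mu[i] + shift[i], cfg.de_noise_sd,
                        size=cfg.n_replicates)
        truth = "down" if down_mask[i] else ("up" if up_mask[i]
                                             else "unaffected")
        row = {"gene_id": g.gene_id, "truth": truth}
        row.update({f"ctrl_{r + 1}": ctrl[r] for r in range(cfg.n_replicates)})
        row.update({f"kd_{r + 1}": kd[r] for r in range(cfg.n_replicates)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_binding_curve(
    kd: float,
    rmax: float,
    concentrations: Sequence[float],
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy 1:1 binding isotherm: R_i = rmax * c_i / (kd + c_i) + noise."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng([int(seed), _S_CURVE])
    response = rmax * c / (kd + c)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=c.size)
    return c, response
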