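"""Peak-to-gene assignment, metagene region classification, and gene-level
occupancy summaries.

Distance is always measured summit-to-TSS; peak boundaries never enter the
assignment. Signed distance is oriented by the gene's strand: negative means
upstream of the TSS in the transcription direction. Two anchors coexist by
design: the upstream/downstream region bands (proximal/intermediate/distal)
are measured from the nearer gene-body edge, while the 400-bp occupancy bins
and the <1 kb / 1-5 kb / >5 kb window sums are TSS-anchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import FORWARD, GeneModel, Peak

REGION_CLASSES = (
    "distal_up", "intermediate_up", "proximal_up", "gene_body",
    "proximal_down", "intermediate_down", "distal_down",
)
SUBCLASSES = ("exon", "intron", "utr5", "utr3")

#: occupancy binning: 25 x 400 bp per side covering +/-10 kb, 2 overflow bins
N_FLANK_BINS = 25
BIN_BP = 400
N_BINS = 2 * N_FLANK_BINS + 2
UPSTREAM_OVERFLOW, DOWNSTREAM_OVERFLOW = 50, 51

#: TSS-anchored window bands in bp, half-open on the outer edge
WINDOW_BANDS = {
    "proximal_lt1kb": (0, 1_000),
    "intermediate_1to5kb": (1_000, 5_000),
    "distal_gt5kb": (5_000, math.inf),
}


@dataclass(frozen=True)
class PeakAssignment:
    """A peak attached to its nearest gene (by summit-to-TSS distance)."""

    peak: Peak
    gene_id: str
    signed_distance: int
    region_class: str
    subclass: str | None = None

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.subclass is not None and self.region_class != "gene_body":
            raise ValueError("subclass only valid for gene_body peaks")


@dataclass
class GeneOccupancy:
    """Per-gene binding summary: binned profile, window sums, total score."""

    gene_id: str
    bins: np.ndarray
    window_sums: dict[str, float]
    total: float


def tss_of(gene: GeneModel) -> int:
    """Transcription start: body.start on +, body.end - 1 on - strand."""
    return gene.tss


def tes_of(gene: GeneModel) -> int:
    return gene.tes


def signed_tss_distance(gene: GeneModel, summit: int) -> int:
    """Summit-to-TSS offset oriented by strand (negative = upstream)."""
    d = summit - gene.tss
    return d if gene.body.strand == FORWARD else -d


def assign_nearest_gene(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
) -> tuple[list[PeakAssignment], list[Peak]]:
    """Assign each peak to the gene with minimal |summit - TSS| on the same
    scaffold.

    Ties are broken by lexicographically smallest gene_id. Peaks on scaffolds
    without genes are returned separately as unassigned.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.body.scaffold, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for scaffold, glist in by_scaffold.items():
        # sort by (TSS, gene_id) so the first hit at minimal distance is the
        # lexicographic tie-winner among equal TSSs; ties across distinct
        # TSS positions are resolved explicitly below
        glist.sort(key=lambda g: (g.tss, g.gene_id))
        index[scaffold] = (np.array([g.tss for g in glist]), glist)

    assignments: list[PeakAssignment] = []
    unassigned: list[Peak] = []
    for pk in peaks:
        entry = index.get(pk.scaffold)
        if entry is None:
            unassigned.append(pk)
            continue
        tss_arr, glist = entry
        dist = np.abs(tss_arr - pk.summit)
        best = int(dist.min())
        candidates = [glist[i] for i in np.flatnonzero(dist == best)]
        gene = min(candidates, key=lambda g: g.gene_id)
        sd = signed_tss_distance(gene, pk.summit)
        region, sub = classify_region(gene, pk.summit)
        assignments.append(PeakAssignment(
            peak=pk, gene_id=gene.gene_id, signed_distance=sd,
            region_class=region, subclass=sub))
    return assignments, unassigned


def classify_region(gene: GeneModel, summit: int) -> tuple[str, str | None]:
    """Metagene class of a summit relative to its assigned gene.

    Inside the gene body the subclass is utr5/utr3 when inside a UTR (UTR
    takes precedence over plain exon), exon when inside any exon, intron
    otherwise. Outside, the band (proximal <=1 kb, intermediate 1-5 kb,
    distal >5 kb) is measured from the nearer body edge and oriented by the
    transcription direction.
    """
    body = gene.body
    if body.contains(summit):
        sub = "intron"
        if any(e.contains(summit) for e in gene.exons):
            sub = "exon"
        if any(u.contains(summit) for u in gene.utr5):
            sub = "utr5"
        elif any(u.contains(summit) for u in gene.utr3):
            sub = "utr3"
        return "gene_body", sub
    # distance to the nearer body edge
    if summit < body.start:
        edge_dist = body.start - summit
        before_body = True
    else:
        edge_dist = summit - (body.end - 1)
        before_body = False
    upstream = before_body if body.strand == FORWARD else not before_body
    if edge_dist <= 1_000:
        band = "proximal"
    elif edge_dist <= 5_000:
        band = "intermediate"
    else:
        band = "distal"
    return f"{band}_{'up' if upstream else 'down'}", None


def region_distribution(
    assignments: Iterable[PeakAssignment],
) -> dict[str, int]:
    """Counts per region class, plus exon/UTR counts and the intron count
    obtained by subtracting exonic peaks from gene-body peaks."""
    counts = {rc: 0 for rc in REGION_CLASSES}
    counts.update({sc: 0 for sc in SUBCLASSES})
    for a in assignments:
        counts[a.region_class] += 1
        if a.subclass is not None:
            counts[a.subclass] += 1
    # the subtraction rule: introns = gene body minus exonic (incl. UTR) peaks
    counts["intron"] = counts["gene_body"] - (
        counts["exon"] + counts["utr5"] + counts["utr3"])
    return counts


def bin_occupancy(
    gene: GeneModel,
    assignments: Sequence[PeakAssignment],
) -> GeneOccupancy:
    """Sum peak scores into 400-bp bins spanning +/-10 kb of the TSS.

    Bin index = floor(signed_distance / 400) remapped from [-25, 24] to
    [0, 49]; peaks beyond 10 kb fall into single overflow bins (50 upstream,
    51 downstream). The total equals the sum of all bins, overflow included.
    """
    bins = np.zeros(N_BINS)
    windows = {f"{band}_{side}": 0.0
               for band in WINDOW_BANDS for side in ("up", "down")}
    for a in assignments:
        if a.gene_id != gene.gene_id:
            raise ValueError(f"assignment for {a.gene_id}, expected "
                             f"{gene.gene_id}")
        d = a.signed_distance
        idx = math.floor(d / BIN_BP)
        if idx < -N_FLANK_BINS:
            bins[UPSTREAM_OVERFLOW] += a.peak.score
        elif idx >= N_FLANK_BINS:
            bins[DOWNSTREAM_OVERFLOW] += a.peak.score
        else:
            bins[idx + N_FLANK_BINS] += a.peak.score
        side = "up" if d < 0 else "down"
        for band, (lo, hi) in WINDOW_BANDS.items():
            if lo <= abs(d) < hi:
                windows[f"{band}_{side}"] += a.peak.score
                break
    return GeneOccupancy(gene_id=gene.gene_id, bins=bins,
                         window_sums=windows, total=float(bins.sum()))


def window_sum(occupancy: GeneOccupancy, band: str, side: str) -> float:
    """Windowed score sum for one TSS-anchored band and side.

    Computed from raw assignments at build time (1 kb and 5 kb are not
    multiples of the 400-bp bin width, so re-summing bins would misallocate
    band edges).
    """
    if band not in WINDOW_BANDS:
        raise KeyError(f"unknown band {band!r}; expected one of "
                       f"{sorted(WINDOW_BANDS)}")
    if side not in ("up", "down"):
        raise KeyError(f"side must be 'up' or 'down', got {side!r}")
    return occupancy.window_sums[f"{band}_{side}"]


def gene_occupancies(
    genes: Sequence[GeneModel],
    assignments: Sequence[PeakAssignment],
) -> dict[str, GeneOccupancy]:
    """Build a GeneOccupancy for every gene (zero profile when unbound)."""
    by_gene: dict[str, list[PeakAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a)
    return {g.gene_id: bin_occupancy(g, by_gene.get(g.gene_id, ()))
            for g in genes}


def distance_histogram(
    assignments: Sequence[PeakAssignment],
    limit_bp: int = 20_000,
    break_bp: int = 200,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of signed summit-to-TSS distances in fixed-width bins.

    Returns (bin_edges, counts, n_out_of_range) over [-limit, +limit];
    out-of-range assignments are counted, not dropped, so that
    sum(counts) + out_of_range == len(assignments).
    """
    edges = np.arange(-limit_bp, limit_bp + break_bp, break_bp)
    d = np.array([a.signed_distance for a in assignments])
    if d.size == 0:
        return edges, np.zeros(edges.size - 1, dtype=int), 0
    in_range = (d >= -limit_bp) & (d < limit_bp)
    counts, _ = np.histogram(d[in_range], bins=edges)
    return edges, counts, int((~in_range).sum())


def heatmap_value(score: float) -> float:
    """Heat-map display transform of a -log10 p score: ln(score + 1)."""
    if score < 0:
        raise ValueError(f"negative score {score}")
    return math.log(score + 1.0)
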