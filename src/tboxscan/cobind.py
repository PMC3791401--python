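"""Co-occupancy between peak tracks and shared-target calling.

Peak-level sharing (summit distances, colocalization fractions) and
gene-level sharing (two-tier shared-target calls) are deliberately separate
operations; nothing mixes them silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import Peak

#: two-tier stringency on gene-level sum[-log10 p] occupancy:
#: strong = p <= 1e-25, relaxed = p <= 0.1
STRONG_CUT = 25.0
RELAXED_CUT = 1.0


@dataclass
class CoBindingResult:
    """Nearest-summit distances of a query track against a reference."""

    distances: np.ndarray
    colocalization_fraction: float
    threshold_bp: int
    n_query: int
    n_reference: int
    n_excluded: int  # query peaks on reference-free scaffolds


@dataclass
class TargetCall:
    """Gene-level occupancy of several TFs with per-TF stringency tiers."""

    gene_id: str
    occupancy_by_tf: dict[str, float]
    tier_by_tf: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.tier_by_tf = {
            tf: tier_of(occ) for tf, occ in self.occupancy_by_tf.items()
        }


def tier_of(occupancy: float,
            strong_cut: float = STRONG_CUT,
            relaxed_cut: float = RELAXED_CUT) -> str:
    if occupancy >= strong_cut:
        return "strong"
    if occupancy >= relaxed_cut:
        return "relaxed"
    return "absent"


def nearest_summit_distances(
    query: Sequence[Peak],
    reference: Sequence[Peak],
) -> tuple[list[int], int]:
    """Minimal |summit - summit| to the reference, per query peak.

    Query peaks on scaffolds absent from the reference are excluded and
    counted. Returns (distances, n_excluded).
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    ref_by_scaffold: dict[str, np.ndarray] = {}
    for pk in reference:
        ref_by_scaffold.setdefault(pk.scaffold, []).append(pk.summit)  # type: ignore[arg-type]
    ref_by_scaffold = {s: np.sort(np.array(v))
                       for s, v in ref_by_scaffold.items()}
    distances: list[int] = []
    excluded = 0
    for pk in query:
        summits = ref_by_scaffold.get(pk.scaffold)
        if summits is None:
            excluded += 1
            continue
        i = int(np.searchsorted(summits, pk.summit))
        best = min(
            (int(abs(int(summits[j]) - pk.summit))
             for j in (i - 1, i) if 0 <= j < summits.size),
        )
        distances.append(best)
    return distances, excluded


def colocalization_fraction(
    query: Sequence[Peak],
    reference: Sequence[Peak],
    threshold_bp: int = 100,
) -> CoBindingResult:
    """Fraction of query peaks whose nearest reference summit is within
    ``threshold_bp``.

    Not symmetric in its arguments: the denominator is the query track.
    Excluded query peaks (reference-free scaffolds) count as non-colocalized.
    """
    if not query:
        raise ValueError("query must be non-empty")
    distances, excluded = nearest_summit_distances(query, reference)
    arr = np.array(distances)
    frac = float((arr <= threshold_bp).sum()) / len(query)
    return CoBindingResult(
        distances=arr, colocalization_fraction=frac,
        threshold_bp=threshold_bp, n_query=len(query),
        n_reference=len(reference), n_excluded=excluded)


def shared_target_venn(
    calls: Sequence[TargetCall],
    tf_names: Sequence[str],
) -> dict[frozenset[str], set[str]]:
    """Two-tier shared-target Venn regions over >= 2 TFs.

    A gene enters a TF's universe when its occupancy is strong
    (sum[-log10 p] >= 25). It counts as shared between X and Y when it is
    strong for one and at least relaxed (>= 1, i.e. p <= 0.1) for the other.
    The returned mapping sends each Venn region (a frozenset of TF names) to
    its gene set; each gene appears in exactly one region.
    """
    if len(tf_names) < 2:
        raise ValueError("need >= 2 TFs")
    regions: dict[frozenset[str], set[str]] = {}
    for call in calls:
        for tf in tf_names:
            if tf not in call.occupancy_by_tf:
                raise KeyError(
                    f"gene {call.gene_id}: no occupancy for TF {tf!r}")
        strong = {tf for tf in tf_names if call.tier_by_tf[tf] == "strong"}
        if not strong:
            continue
        # relaxed-rescue: a gene strong somewhere joins every TF where it is
        # at least relaxed
        members = frozenset(
            tf for tf in tf_names if call.tier_by_tf[tf] != "absent")
        regions.setdefault(members, set()).add(call.gene_id)
    return regions


def venn_tf_totals(
    calls: Sequence[TargetCall],
    tf_names: Sequence[str],
) -> dict[str, tuple[int, int, int]]:
    """Per-TF (strong, relaxed_rescued, total) bookkeeping.

    ``relaxed_rescued`` counts genes below the strong cut for this TF but at
    least relaxed for it and strong for some other TF — the
    "strict + rescued = total" decomposition of the two-tier rule.
    """
    totals: dict[str, tuple[int, int, int]] = {}
    for tf in tf_names:
        strong = rescued = 0
        for call in calls:
            tier = call.tier_by_tf[tf]
            if tier == "strong":
                strong += 1
            elif tier == "relaxed" and any(
                    call.tier_by_tf[o] == "strong"
                    for o in tf_names if o != tf):
                rescued += 1
        totals[tf] = (strong, rescued, strong + rescued)
    return totals


def occupancy_correlation(
    levels_a: Mapping[str, float],
    levels_b: Mapping[str, float],
) -> float:
    """Pearson r of gene-level occupancies over the shared gene set."""
    common = sorted(set(levels_a) & set(levels_b))
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared genes, have {len(common)}")
    a = np.array([levels_a[g] for g in common])
    b = np.array([levels_b[g] for g in common])
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero variance in occupancy levels")
    return float(stats.pearsonr(a, b).statistic)
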