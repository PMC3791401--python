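"""Misregulation calling from replicate expression data and statistics
linking binding to regulation: Fisher overlap with expected counts, the
one-tailed two-group Mann-Whitney binding-enrichment test (with and without
zero occupancies), and qPCR standard-curve / ChIP-enrichment utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: combined sample size at or below which the Mann-Whitney branch is exact
EXACT_CUTOVER = 20


@dataclass
class MisregulationCall:
    gene_id: str
    direction: str  # down / up / unaffected
    fold_change: float
    p_value: float
    fdr: float


@dataclass
class OverlapTest:
    """Hypergeometric overlap of two gene sets drawn from a universe of N."""

    n_universe: int
    set_a_size: int
    set_b_size: int
    observed_overlap: int
    expected_overlap: float
    p_value: float


@dataclass
class BindingEnrichmentTest:
    """One-tailed Mann-Whitney U on two sets of gene-level binding sums."""

    n1: int
    n2: int
    include_zeros: bool
    u_statistic: float
    p_value: float
    exact: bool


def signed_fold(ratio: float) -> float:
    """Linear expression ratio -> signed convention (magnitude >= 1;
    a minus sign marks downregulation)."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def fold_change_test(
    control_reps: Sequence[float],
    kd_reps: Sequence[float],
    log_scale: bool = True,
) -> tuple[float, float]:
    """Signed fold change and two-tailed Student's t p-value.

    When ``log_scale`` is true the replicate values are already log2
    expression; the fold is 2**(mean difference) and the t-test runs on the
    values as given. Otherwise values are linear, the fold is the ratio of
    means, and the test runs on log2-transformed replicates (fold-change
    symmetry).
    """
    ctrl = np.asarray(control_reps, dtype=float)
    kd = np.asarray(kd_reps, dtype=float)
    if ctrl.size < 2 or kd.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if log_scale:
        ratio = 2.0 ** (kd.mean() - ctrl.mean())
        t_ctrl, t_kd = ctrl, kd
    else:
        if ctrl.mean() <= 0:
            raise ValueError("zero or negative mean control expression")
        if np.any(ctrl <= 0) or np.any(kd <= 0):
            raise ValueError("linear replicate values must be positive")
        ratio = kd.mean() / ctrl.mean()
        t_ctrl, t_kd = np.log2(ctrl), np.log2(kd)
    if np.ptp(t_ctrl) == 0 and np.ptp(t_kd) == 0:
        p = 1.0 if t_ctrl.mean() == t_kd.mean() else 0.0
    else:
        p = float(stats.ttest_ind(t_kd, t_ctrl).pvalue)
    return signed_fold(ratio), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def call_misregulated(
    records: Iterable[tuple[str, float, float, float]],
    fold_cut: float = 1.5,
    fdr_cut: float = 0.10,
) -> list[MisregulationCall]:
    """Call down/up/unaffected from (gene_id, signed_fold, p, fdr) records.

    down: fold <= -fold_cut and fdr < fdr_cut; up: fold >= +fold_cut and
    fdr < fdr_cut; everything else unaffected.
    """
    calls = []
    for gene_id, fold, p, fdr in records:
        if fold <= -fold_cut and fdr < fdr_cut:
            direction = "down"
        elif fold >= fold_cut and fdr < fdr_cut:
            direction = "up"
        else:
            direction = "unaffected"
        calls.append(MisregulationCall(gene_id=gene_id, direction=direction,
                                       fold_change=fold, p_value=p, fdr=fdr))
    return calls


def fisher_overlap(set_a: set, set_b: set, universe_n: int) -> OverlapTest:
    """One-sided (enrichment) hypergeometric test of gene-set overlap.

    expected = |A| |B| / N; p = P(X >= observed) under random draws from the
    universe.
    """
    a, b = len(set_a), len(set_b)
    if a > universe_n or b > universe_n:
        raise ValueError("set larger than universe")
    observed = len(set_a & set_b)
    if observed > min(a, b):  # unreachable for true sets; guards raw counts
        raise ValueError("overlap exceeds smaller set")
    expected = a * b / universe_n if universe_n else 0.0
    # P(X >= k) for X ~ Hypergeom(N, a, b)
    p = float(stats.hypergeom.sf(observed - 1, universe_n, a, b))
    return OverlapTest(n_universe=universe_n, set_a_size=a, set_b_size=b,
                       observed_overlap=observed, expected_overlap=expected,
                       p_value=min(p, 1.0))


def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray,
                         u_observed: float) -> float:
    """One-tailed exact p by enumerating all group assignments of the pooled
    values (tie-aware: ranks are recomputed per assignment on the fixed
    pooled multiset, so tied values contribute mid-ranks throughout)."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = stats.rankdata(pooled)  # mid-ranks; fixed for all assignments
    n = pooled.size
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        if u >= u_observed - 1e-12:
            count += 1
        total += 1
    return count / total


def mannwhitney_binding(
    set1_levels: Sequence[float],
    set2_levels: Sequence[float],
    include_zeros: bool = True,
) -> BindingEnrichmentTest:
    """One-tailed two-group Mann-Whitney U: is set 1 stochastically greater?

    Zeros are dropped from both sets when ``include_zeros`` is false (the
    with/without-zero-occupancy variants of the binding-enrichment
    comparison). Exact enumeration when n1 + n2 <= 20, normal approximation
    with tie correction otherwise.
    """
    x = np.asarray(set1_levels, dtype=float)
    y = np.asarray(set2_levels, dtype=float)
    if not include_zeros:
        x, y = x[x != 0], y[y != 0]
        if x.size == 0:
            raise ValueError("set 1 empty after zero removal")
        if y.size == 0:
            raise ValueError("set 2 empty after zero removal")
    if x.size == 0 or y.size == 0:
        raise ValueError("both sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = float(ranks[:x.size].sum() - x.size * (x.size + 1) / 2.0)
    if x.size + y.size <= EXACT_CUTOVER:
        p = _exact_mannwhitney_p(x, y, u)
        exact = True
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="greater",
                                     method="asymptotic").pvalue)
        exact = False
    return BindingEnrichmentTest(n1=int(x.size), n2=int(y.size),
                                 include_zeros=include_zeros,
                                 u_statistic=u, p_value=p, exact=exact)


def quantify_from_standard_curve(
    ct: float,
    curve_points: Sequence[tuple[float, float]],
) -> float:
    """Invert a qPCR standard curve ct = a log10(q) + b at an observed ct."""
    if len(curve_points) < 2 or len(set(curve_points)) < 2:
        raise ValueError("need >= 2 distinct curve points")
    logq = np.array([p[0] for p in curve_points], dtype=float)
    cts = np.array([p[1] for p in curve_points], dtype=float)
    if np.ptp(logq) == 0:
        raise ValueError("degenerate standard curve (single quantity)")
    fit = stats.linregress(logq, cts)
    if fit.slope >= 0:
        raise ValueError(f"invalid standard curve: slope {fit.slope:.3g} >= 0")
    return float(10.0 ** ((ct - fit.intercept) / fit.slope))


def chip_enrichment(
    q_ab: float,
    q_control: float,
    mode: str = "vs_igg",
    input_fraction: float = 1.0,
) -> float:
    """ChIP-qPCR enrichment: antibody vs IgG ratio, or percent input.

    percent input scales the measured input quantity by the aliquot fraction
    it represents: 100 * q_ab / (q_input / input_fraction).
    """
    if q_ab <= 0 or q_control <= 0:
        raise ValueError("quantities must be positive")
    if mode == "vs_igg":
        return q_ab / q_control
    if mode == "percent_input":
        if not 0.0 < input_fraction <= 1.0:
            raise ValueError("input_fraction must be in (0, 1]")
        return 100.0 * q_ab / (q_control / input_fraction)
    raise ValueError(f"unknown mode {mode!r}")
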